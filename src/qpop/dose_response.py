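"""Single-drug dose-response fitting: 4PL curves and median-effect lines.

Two curve families are supported, because both are used downstream:

* the four-parameter logistic (4PL, "sigmoidal dose-response"),
  ``y = bottom + (top - bottom) / (1 + (D / ic50)^hill)``, fitted by
  nonlinear least squares with multi-start initialization — this is the
  standard IC50 workhorse and the source of the IC10/IC20 panel doses;
* the median-effect line, ``log(fa / (1 - fa)) = m log D - m log Dm``,
  a linear fit on logit-transformed affected fractions that underlies
  Chou-Talalay combination-index analysis.

``fa`` (fraction affected) is 1 - NCV.  IC0 is operationalized as dose 0
when building panels — a 0% effect has no finite inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DoseResponseFit4PL",
    "MedianEffectFit",
    "fit_4pl",
    "invert_4pl",
    "fit_median_effect",
    "dx_from_median_effect",
    "four_pl",
]

# Fitting bounds; viability is control-anchored so asymptotes live near
# [0, 1] with slack for assay noise.
BOUNDS_4PL = {
    "bottom": (-0.1, 0.5),
    "top": (0.5, 1.2),
    "hill": (0.1, 10.0),
}
FA_EPS = 1e-6


def four_pl(dose: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


@dataclass(frozen=True)
class DoseResponseFit4PL:
    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool

    def predict(self, dose: np.ndarray) -> np.ndarray:
        return four_pl(dose, self.top, self.bottom, self.ic50, self.hill)


@dataclass(frozen=True)
class MedianEffectFit:
    m: float
    dm: float
    r_squared: float
    n_used: int
    n_excluded: int = 0


def fit_4pl(doses: Sequence[float], viability: Sequence[float]) -> DoseResponseFit4PL:
    """Fit a 4PL curve by least squares with a multi-start grid.

    Starts span hill slopes {0.5, 1, 2, 4} crossed with IC50 values at
    every half-decade of the tested dose range; the best converged start
    wins.  Raises ``ValueError`` for unidentifiable (flat) data or if no
    start converges.
    """
    D = np.asarray(doses, dtype=float)
    y = np.asarray(viability, dtype=float)
    if D.shape != y.shape:
        raise ValueError("doses and viability must have equal length")
    if (D <= 0).any():
        raise ValueError("doses must be strictly positive")
    if len(np.unique(D)) < 4:
        raise ValueError("need >= 4 distinct doses to fit a 4PL curve")
    if np.ptp(y) < 1e-3:
        raise ValueError(
            "viability is flat across doses: IC50 unidentifiable from these data"
        )
    lo = [BOUNDS_4PL["top"][0], BOUNDS_4PL["bottom"][0], D.min() / 100, BOUNDS_4PL["hill"][0]]
    hi = [BOUNDS_4PL["top"][1], BOUNDS_4PL["bottom"][1], D.max() * 100, BOUNDS_4PL["hill"][1]]
    log_lo, log_hi = np.log10(D.min() / 10), np.log10(D.max() * 10)
    ic50_starts = 10 ** np.arange(log_lo, log_hi + 0.25, 0.5)
    best = None
    for hill0 in (0.5, 1.0, 2.0, 4.0):
        for ic0 in ic50_starts:
            p0 = [min(max(y.max(), lo[0]), hi[0]), min(max(y.min(), lo[1]), hi[1]), ic0, hill0]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", optimize.OptimizeWarning)
                    popt, _ = optimize.curve_fit(
                        lambda d, t, b, i, h: four_pl(d, t, b, i, h),
                        D, y, p0=p0, bounds=(lo, hi), maxfev=5000,
                    )
            except RuntimeError:
                continue
            rss = float(np.sum((four_pl(D, *popt) - y) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        raise ValueError(
            "4PL fit failed to converge from any start "
            f"(n={len(D)} points, dose range {D.min():g}-{D.max():g} uM)"
        )
    (top, bottom, ic50, hill), rss = best
    return DoseResponseFit4PL(
        top=float(top), bottom=float(bottom), ic50=float(ic50), hill=float(hill),
        rss=rss, converged=True,
    )


def invert_4pl(fit: DoseResponseFit4PL, effect: float) -> float:
    """Dose producing the given fractional effect on the top-bottom span.

    ``effect`` is the inhibited fraction relative to the asymptote span:
    the returned dose D satisfies
    ``(top - y(D)) / (top - bottom) = effect``, i.e.
    ``D = ic50 * (effect / (1 - effect))^(1 / hill)`` — the closed form
    holds for any top/bottom.
    """
    if not 0.0 < effect < 1.0:
        raise ValueError(f"effect must be in (0, 1) exclusive, got {effect}")
    return float(fit.ic50 * (effect / (1.0 - effect)) ** (1.0 / fit.hill))


def fit_median_effect(doses: Sequence[float], fa: Sequence[float]) -> MedianEffectFit:
    """Linear median-effect fit of log10(fa/(1-fa)) on log10(dose).

    Points with fa exactly 0 or 1 carry no logit information and are
    excluded with a warning; fa within FA_EPS of a boundary is clamped
    into the open interval.  Requires >= 3 usable points.
    """
    D = np.asarray(doses, dtype=float)
    f = np.asarray(fa, dtype=float)
    if D.shape != f.shape:
        raise ValueError("doses and fa must have equal length")
    if (D <= 0).any():
        raise ValueError("doses must be strictly positive")
    usable = (f > 0.0) & (f < 1.0)
    n_excluded = int((~usable).sum())
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} point(s) with fa in {{0, 1}} from median-effect fit",
            stacklevel=2,
        )
    D, f = D[usable], np.clip(f[usable], FA_EPS, 1.0 - FA_EPS)
    if len(D) < 3:
        raise ValueError(f"median-effect fit needs >= 3 usable points, have {len(D)}")
    res = stats.linregress(np.log10(D), np.log10(f / (1.0 - f)))
    m = float(res.slope)
    dm = float(10 ** (-res.intercept / m))
    return MedianEffectFit(
        m=m, dm=dm, r_squared=float(res.rvalue**2), n_used=len(D), n_excluded=n_excluded
    )


def dx_from_median_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose required for affected fraction ``fa``: Dx = Dm (fa/(1-fa))^(1/m)."""
    if not 0.0 < fa < 1.0:
        raise ValueError(f"fa must be in (0, 1) exclusive, got {fa}")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))
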