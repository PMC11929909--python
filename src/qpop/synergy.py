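"""Drug-pair interaction scoring: Chou-Talalay CI and Bliss independence.

Combination index (CI): from median-effect fits of each single agent and
of the constant-ratio combination (fitted on total dose), the CI at
affected fraction fa is

    CI(fa) = d1 / Dx_A(fa) + d2 / Dx_B(fa),

where (d1, d2) split the combination dose required for fa according to
the fixed dose ratio, and Dx_A, Dx_B are the single-agent doses required
for the same fa.  CI < 1 indicates synergy, CI = 1 additivity, CI > 1
antagonism.  The mutually-exclusive form (no third product term) is
used, matching common practice.

Bliss independence: expected combined inhibition from monotherapy
margins is ``iA + iB - iA*iB``; the summary score is the mean excess
(observed - expected, in percentage points) over all cells with both
doses nonzero.  Scores > 10 classify as synergistic, < -10 as
antagonistic, otherwise additive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import MedianEffectFit, dx_from_median_effect

__all__ = [
    "CombinationIndexCurve",
    "BlissResult",
    "combination_index",
    "bliss_matrix",
    "classify_bliss",
]

BLISS_SYNERGY_THRESHOLD = 10.0  # percentage points of excess inhibition


@dataclass(frozen=True)
class CombinationIndexCurve:
    fa: np.ndarray
    ci: np.ndarray
    ratio: tuple[float, float]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"fa": self.fa, "ci": self.ci}).to_csv(path, index=False)


@dataclass(frozen=True)
class BlissResult:
    doses_a: np.ndarray
    doses_b: np.ndarray
    observed_inhibition: np.ndarray  # percent, (len A, len B)
    expected_inhibition: np.ndarray  # percent
    excess: np.ndarray  # observed - expected, percentage points
    score: float
    classification: str
    n_clamped: int


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_ab: MedianEffectFit,
    ratio: tuple[float, float],
    fa_grid: Sequence[float],
) -> CombinationIndexCurve:
    """Chou-Talalay CI over an fa grid for a constant-ratio combination.

    ``fit_ab`` must be a median-effect fit of the combination response
    against *total* dose (d1 + d2) at the fixed ratio ``ratio`` =
    (r1, r2), the same ratio used when treating (taken from the panel
    doses of the two drugs).
    """
    r1, r2 = ratio
    if r1 <= 0 or r2 <= 0:
        raise ValueError(f"ratio components must be positive, got {ratio}")
    fa = np.asarray(fa_grid, dtype=float)
    if fa.size == 0 or (fa <= 0).any() or (fa >= 1).any():
        raise ValueError("fa grid values must lie strictly in (0, 1)")
    if np.any(np.diff(fa) <= 0):
        raise ValueError("fa grid must be strictly increasing")
    ci = np.empty_like(fa)
    for k, f in enumerate(fa):
        d_total = dx_from_median_effect(fit_ab, float(f))
        d1 = d_total * r1 / (r1 + r2)
        d2 = d_total * r2 / (r1 + r2)
        ci[k] = d1 / dx_from_median_effect(fit_a, float(f)) + d2 / dx_from_median_effect(
            fit_b, float(f)
        )
    return CombinationIndexCurve(fa=fa, ci=ci, ratio=(float(r1), float(r2)))


def bliss_matrix(
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    viability: np.ndarray,
) -> BlissResult:
    """Bliss excess scoring of a dose-matrix viability measurement.

    ``viability[i, j]`` is the (normalized) viability at dose
    ``doses_a[i]`` of drug A and ``doses_b[j]`` of drug B; both dose
    lists must start with 0 so the monotherapy margins are available.
    Inhibition is clamped to [0, 1] before the Bliss algebra; the number
    of clamped cells is recorded.
    """
    da = np.asarray(doses_a, dtype=float)
    db = np.asarray(doses_b, dtype=float)
    V = np.asarray(viability, dtype=float)
    if V.shape != (da.size, db.size):
        raise ValueError(
            f"viability matrix shape {V.shape} does not match dose lists "
            f"({da.size} x {db.size})"
        )
    if da[0] != 0 or db[0] != 0:
        raise ValueError("dose lists must include the zero-dose monotherapy margins first")
    inhibition_raw = 1.0 - V
    n_clamped = int(((inhibition_raw < 0) | (inhibition_raw > 1)).sum())
    inh = np.clip(inhibition_raw, 0.0, 1.0)
    i_a = inh[:, 0]  # drug A alone (B at dose 0)
    i_b = inh[0, :]  # drug B alone
    expected = i_a[:, None] + i_b[None, :] - i_a[:, None] * i_b[None, :]
    excess = (inh - expected) * 100.0
    both_active = (da[:, None] > 0) & (db[None, :] > 0)
    score = float(excess[both_active].mean())
    return BlissResult(
        doses_a=da,
        doses_b=db,
        observed_inhibition=inh * 100.0,
        expected_inhibition=expected * 100.0,
        excess=excess,
        score=score,
        classification=classify_bliss(score),
        n_clamped=n_clamped,
    )


def classify_bliss(score: float) -> str:
    """Classify a Bliss summary score: >10 synergistic, <-10 antagonistic."""
    if score > BLISS_SYNERGY_THRESHOLD:
        return "synergistic"
    if score < -BLISS_SYNERGY_THRESHOLD:
        return "antagonistic"
    return "additive"
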