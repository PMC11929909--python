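"""Plate reading, viability normalization and assay quality control.

Raw CellTiter-Glo-style luminescence is rescaled to normalized cell
viability (NCV) against on-plate controls,

    NCV = (raw - mean_neg) / (mean_pos - mean_neg),

so vehicle-treated (positive) controls read 1 and background (negative)
controls read 0; lower NCV means greater cell killing.  Assay quality is
gated on the Z'-factor, with the strictly standardized mean difference
(SSMD) reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlateReadout",
    "ViabilityTable",
    "QCReport",
    "QCGateResult",
    "read_plate",
    "normalize",
    "zprime",
    "ssmd",
    "qc_gate",
]

ROLES = ("treatment", "pos_ctrl", "neg_ctrl")
PLATE_COLUMNS = ("well", "run_id", "replicate", "role", "raw")

# NCV outside this window is retained for regression but flagged as
# suspicious (far beyond what control-anchored noise should produce).
NCV_FLAG_RANGE = (-0.2, 1.5)


@dataclass(frozen=True)
class PlateReadout:
    """Validated plate table with columns well, run_id, replicate, role, raw."""

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.wells
        missing = set(PLATE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        bad_roles = set(df["role"].unique()) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown well roles: {sorted(bad_roles)}; expected {ROLES}")
        raw = df["raw"].to_numpy(dtype=float)
        if not np.isfinite(raw).all():
            raise ValueError("raw luminescence contains non-finite values")
        if (raw < 0).any():
            raise ValueError("raw luminescence must be >= 0")
        for role, label in (("pos_ctrl", "positive"), ("neg_ctrl", "negative")):
            if not (df["role"] == role).any():
                raise ValueError(f"no {label} controls on plate")
        trt = df[df["role"] == "treatment"]
        dup = trt.duplicated(subset=["run_id", "replicate"])
        if dup.any():
            pairs = trt.loc[dup, ["run_id", "replicate"]].to_records(index=False).tolist()
            raise ValueError(f"duplicated (run_id, replicate) treatment rows: {pairs[:5]}")

    def control_values(self, role: str) -> np.ndarray:
        return self.wells.loc[self.wells["role"] == role, "raw"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.wells.to_csv(path, index=False)


@dataclass(frozen=True)
class ViabilityTable:
    """Replicate-level NCVs plus per-run mean and SD.

    ``replicates``: columns run_id, replicate, ncv.
    ``summary``: columns run_id, mean_ncv, sd_ncv, n_rep.
    ``n_flagged``: replicate NCVs outside the plausibility window.
    """

    replicates: pd.DataFrame
    summary: pd.DataFrame
    n_flagged: int


@dataclass(frozen=True)
class QCReport:
    sample_id: str
    zprime: float
    ssmd: float
    zprime_min: float = 0.5

    @property
    def passed(self) -> bool:
        return self.zprime >= self.zprime_min


def read_plate(path: str | Path) -> PlateReadout:
    """Read and validate a plate CSV (well, run_id, replicate, role, raw)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return PlateReadout(wells=df)


def normalize(readout: PlateReadout) -> ViabilityTable:
    """Normalize raw luminescence to NCV against plate control means.

    Replicate NCVs are retained; per-run mean and sample SD (ddof=1, NaN
    for a single replicate) are computed for downstream fitting and
    reporting.  Raises on inverted controls (mean_pos <= mean_neg).
    """
    pos = readout.control_values("pos_ctrl")
    neg = readout.control_values("neg_ctrl")
    mean_pos, mean_neg = float(pos.mean()), float(neg.mean())
    if mean_pos <= mean_neg:
        raise ValueError(
            f"inverted controls: mean positive {mean_pos:g} <= mean negative {mean_neg:g}"
        )
    span = mean_pos - mean_neg
    trt = readout.wells[readout.wells["role"] == "treatment"]
    reps = pd.DataFrame(
        {
            "run_id": trt["run_id"].to_numpy(dtype=int),
            "replicate": trt["replicate"].to_numpy(dtype=int),
            "ncv": (trt["raw"].to_numpy(dtype=float) - mean_neg) / span,
        }
    ).sort_values(["run_id", "replicate"], ignore_index=True)
    lo, hi = NCV_FLAG_RANGE
    n_flagged = int(((reps["ncv"] < lo) | (reps["ncv"] > hi)).sum())
    grouped = reps.groupby("run_id", sort=True)["ncv"]
    summary = pd.DataFrame(
        {
            "run_id": np.fromiter(grouped.groups.keys(), dtype=int),
            "mean_ncv": grouped.mean().to_numpy(),
            "sd_ncv": grouped.std(ddof=1).to_numpy(),
            "n_rep": grouped.size().to_numpy(),
        }
    )
    return ViabilityTable(replicates=reps, summary=summary, n_flagged=n_flagged)


def zprime(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Z'-factor: 1 - 3(sd_pos + sd_neg)/|mean_pos - mean_neg| (sample SDs)."""
    p = np.asarray(pos, dtype=float)
    n = np.asarray(neg, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ValueError("Z' requires at least 2 replicates per control group")
    sep = abs(p.mean() - n.mean())
    if sep == 0:
        raise ValueError("Z' undefined: control means are equal")
    return float(1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / sep)


def ssmd(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Strictly standardized mean difference: (mu_pos - mu_neg)/sqrt(var_pos + var_neg)."""
    p = np.asarray(pos, dtype=float)
    n = np.asarray(neg, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ValueError("SSMD requires at least 2 replicates per control group")
    denom = np.sqrt(p.var(ddof=1) + n.var(ddof=1))
    if denom == 0:
        raise ValueError("SSMD undefined: both control variances are zero")
    return float((p.mean() - n.mean()) / denom)


@dataclass(frozen=True)
class QCGateResult:
    """Per-sample pass flags plus cohort accounting.

    ``report_yield_pct`` = 100 * reported / collected, where collected
    defaults to (pre-excluded + gated samples) when not given explicitly.
    """

    passed: dict[str, bool]
    n_collected: int
    n_pre_excluded: int
    n_qc_failed: int
    n_reported: int

    @property
    def report_yield_pct(self) -> float:
        return 100.0 * self.n_reported / self.n_collected


def qc_gate(
    reports: Sequence[QCReport],
    zprime_min: float = 0.5,
    n_collected: int | None = None,
    n_pre_excluded: int = 0,
) -> QCGateResult:
    """Gate samples on Z' and account for cohort attrition.

    ``n_pre_excluded`` counts samples dropped before assay (e.g.
    insufficient material); they never reach QC.  A sample passes when
    its Z' meets ``zprime_min`` (inclusive).
    """
    passed = {r.sample_id: r.zprime >= zprime_min for r in reports}
    n_qc_failed = sum(not ok for ok in passed.values())
    n_reported = sum(passed.values())
    if n_collected is None:
        n_collected = n_pre_excluded + len(reports)
    return QCGateResult(
        passed=passed,
        n_collected=n_collected,
        n_pre_excluded=n_pre_excluded,
        n_qc_failed=n_qc_failed,
        n_reported=n_reported,
    )
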