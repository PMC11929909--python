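"""Orthogonal array composite design (OACD) for three-level drug panels.

The screening design concatenates

* a resolution-IV ``2^(12-5)`` fractional factorial (128 runs) placed at
  the extreme coded levels {0, 2}, which carries main-effect and
  two-factor-interaction information, and
* the ``L27(3^13)`` orthogonal array restricted to the first 12 columns
  (27 runs) on levels {0, 1, 2}, which adds the mid-level runs needed to
  separate pure-quadratic curvature from linear effects,

for 155 runs in total.  The expanded second-order basis on these runs
has full column rank (91 terms for 12 factors), so the quadratic
viability model is estimable from a single plate.

Coded levels 0/1/2 correspond to the IC0/IC10/IC20 doses of each drug;
level 0 may be exactly 0 uM (drug absent).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DrugPanel",
    "DesignMatrix",
    "DesignValidation",
    "build_oacd",
    "map_levels_to_doses",
    "doses_to_levels",
    "validate_design",
    "FF_GENERATORS_12",
]

PORTION_FACTORIAL = "two_level_factorial"
PORTION_OA = "three_level_oa"

# Generator words for the 2^(12-5) fractional factorial: factors 8..12 are
# products of the listed base factors (indices into the 7 base columns).
# This set is resolution IV with minimum aberration (one length-4 word in
# the defining contrast subgroup), found by exhaustive search over
# 4-letter generator words and frozen here.
FF_GENERATORS_12: tuple[tuple[int, ...], ...] = (
    (0, 1, 2, 3),
    (0, 1, 2, 4),
    (0, 1, 5, 6),
    (0, 3, 4, 5),
    (2, 3, 4, 6),
)


@dataclass(frozen=True)
class DrugPanel:
    """Ordered drug panel with the three tested doses per drug (uM).

    ``doses[i]`` is ``(dose_level0, dose_level1, dose_level2)`` for drug
    ``names[i]`` — the IC0, IC10 and IC20 doses.  Doses must be strictly
    increasing within a drug; the level-0 dose may be exactly 0.
    """

    names: tuple[str, ...]
    doses: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.doses):
            raise ValueError("names and doses must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("drug names must be unique")
        for name, (d0, d1, d2) in zip(self.names, self.doses):
            if not (0 <= d0 < d1 < d2):
                raise ValueError(
                    f"doses for {name!r} must satisfy 0 <= level0 < level1 < level2, "
                    f"got {(d0, d1, d2)}"
                )

    @property
    def n_drugs(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown drug {name!r}; panel has {list(self.names)}") from None

    def dose(self, name: str, level: int) -> float:
        return self.doses[self.index(name)][level]

    def dose_table(self) -> np.ndarray:
        """``(F, 3)`` array of doses, rows in panel order."""
        return np.asarray(self.doses, dtype=float)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "drugs": [
                {"name": n, "dose_level0_uM": d[0], "dose_level1_uM": d[1], "dose_level2_uM": d[2]}
                for n, d in zip(self.names, self.doses)
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DrugPanel":
        payload = json.loads(Path(path).read_text())
        drugs = payload["drugs"]
        return cls(
            names=tuple(d["name"] for d in drugs),
            doses=tuple(
                (float(d["dose_level0_uM"]), float(d["dose_level1_uM"]), float(d["dose_level2_uM"]))
                for d in drugs
            ),
        )


@dataclass(frozen=True)
class DesignMatrix:
    """Coded experimental design: ``levels`` is an ``(R, F)`` int array in {0,1,2}.

    ``portion`` tags each run as coming from the two-level factorial or
    the three-level orthogonal array.  Run ids are the row indices.
    """

    levels: np.ndarray
    portion: tuple[str, ...]

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=int)
        object.__setattr__(self, "levels", lv)
        if lv.ndim != 2:
            raise ValueError("levels must be a 2-D array")
        if len(self.portion) != lv.shape[0]:
            raise ValueError("portion tags must match the number of runs")
        if lv.size and (lv.min() < 0 or lv.max() > 2):
            raise ValueError("coded levels must lie in {0, 1, 2}")

    @property
    def n_runs(self) -> int:
        return self.levels.shape[0]

    @property
    def n_factors(self) -> int:
        return self.levels.shape[1]

    def to_frame(self, drug_names: list[str] | None = None) -> pd.DataFrame:
        names = drug_names or [f"x{i}" for i in range(self.n_factors)]
        df = pd.DataFrame(self.levels, columns=names)
        df.insert(0, "run_id", np.arange(self.n_runs))
        df.insert(1, "portion", list(self.portion))
        return df

    def to_csv(self, path: str | Path, drug_names: list[str] | None = None) -> None:
        self.to_frame(drug_names).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DesignMatrix":
        df = pd.read_csv(path)
        factor_cols = [c for c in df.columns if c not in ("run_id", "portion")]
        return cls(
            levels=df[factor_cols].to_numpy(dtype=int),
            portion=tuple(df["portion"].tolist()),
        )


def _fractional_factorial_128() -> np.ndarray:
    """128-run 2^(12-5) fractional factorial on coded levels {0, 2}."""
    base = np.array(list(itertools.product([-1, 1], repeat=7)), dtype=int)
    cols = [base[:, i] for i in range(7)]
    cols += [np.prod(base[:, list(g)], axis=1) for g in FF_GENERATORS_12]
    pm = np.stack(cols, axis=1)
    return np.where(pm == -1, 0, 2)


def _l27_columns() -> np.ndarray:
    """Canonical L27(3^13): 27 runs x 13 balanced three-level columns.

    Runs are the points of GF(3)^3 in lexicographic order; columns are
    the linear forms a.x with coefficient vectors a having leading
    nonzero coefficient 1, in lexicographic order.
    """
    runs = np.array(list(itertools.product([0, 1, 2], repeat=3)), dtype=int)
    vecs = sorted(
        v
        for v in itertools.product([0, 1, 2], repeat=3)
        if any(v) and v[next(i for i, x in enumerate(v) if x)] == 1
    )
    return np.stack([(runs @ np.array(v)) % 3 for v in vecs], axis=1)


def build_oacd(n_factors: int = 12) -> DesignMatrix:
    """Build the orthogonal array composite design for ``n_factors`` drugs.

    Only the 12-factor configuration (128 factorial + 27 OA = 155 runs)
    is registered; other factor counts would need a suitable fractional
    factorial / orthogonal array pairing and raise ``ValueError``.
    """
    if n_factors != 12:
        raise ValueError(
            f"no registered OACD for {n_factors} factors; "
            "supported configurations: 12 factors (2^(12-5) + L27, 155 runs)"
        )
    fact = _fractional_factorial_128()
    oa = _l27_columns()[:, :12]
    levels = np.vstack([fact, oa])
    portion = (PORTION_FACTORIAL,) * fact.shape[0] + (PORTION_OA,) * oa.shape[0]
    return DesignMatrix(levels=levels, portion=portion)


def map_levels_to_doses(design: DesignMatrix, panel: DrugPanel) -> pd.DataFrame:
    """Dosing plan: per-run uM dose of each drug, by table lookup.

    Rows follow design run order; columns are ``run_id`` plus one column
    per drug name.
    """
    if design.n_factors != panel.n_drugs:
        raise ValueError(
            f"design has {design.n_factors} factors but panel has {panel.n_drugs} drugs"
        )
    dose_tab = panel.dose_table()  # (F, 3)
    doses = np.take_along_axis(
        dose_tab.T[None, :, :],  # (1, 3, F)
        design.levels[:, None, :],  # (R, 1, F)
        axis=1,
    )[:, 0, :]
    df = pd.DataFrame(doses, columns=list(panel.names))
    df.insert(0, "run_id", np.arange(design.n_runs))
    return df


def doses_to_levels(dosing: pd.DataFrame, panel: DrugPanel) -> np.ndarray:
    """Invert a dosing plan back to coded levels (exact table lookup)."""
    levels = np.empty((len(dosing), panel.n_drugs), dtype=int)
    for j, name in enumerate(panel.names):
        col = dosing[name].to_numpy(dtype=float)
        table = np.asarray(panel.doses[panel.index(name)])
        match = col[:, None] == table[None, :]
        if not match.any(axis=1).all():
            bad = col[~match.any(axis=1)][0]
            raise ValueError(f"dose {bad} uM for {name!r} is not one of its panel doses")
        levels[:, j] = match.argmax(axis=1)
    return levels


@dataclass(frozen=True)
class DesignValidation:
    """Report-only summary of design health used to gate model fitting."""

    n_runs: int
    portion_counts: dict[str, int]
    level_counts: np.ndarray  # (F, 3) occurrences of each level per column
    n_terms: int
    basis_rank: int
    n_duplicate_runs: int
    passed: bool


def validate_design(design: DesignMatrix) -> DesignValidation:
    """Check run counts, level balance and estimability of the quadratic model.

    ``passed`` is False when the expanded second-order basis is
    rank-deficient on the design (the quadratic model would not be
    identifiable).
    """
    if design.n_runs == 0:
        raise ValueError("design has zero runs")
    from .model import n_quadratic_terms, quadratic_basis

    levels = design.levels
    level_counts = np.stack(
        [np.bincount(levels[:, j], minlength=3) for j in range(design.n_factors)]
    )
    B = quadratic_basis(levels.astype(float))
    rank = int(np.linalg.matrix_rank(B))
    n_terms = n_quadratic_terms(design.n_factors)
    portion_counts: dict[str, int] = {}
    for p in design.portion:
        portion_counts[p] = portion_counts.get(p, 0) + 1
    n_dup = design.n_runs - len(np.unique(levels, axis=0))
    return DesignValidation(
        n_runs=design.n_runs,
        portion_counts=portion_counts,
        level_counts=level_counts,
        n_terms=n_terms,
        basis_rank=rank,
        n_duplicate_runs=int(n_dup),
        passed=rank == n_terms,
    )
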