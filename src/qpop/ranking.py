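"""Enumeration and ranking of drug-dose therapies from a fitted model.

A *therapy* is a set of 1-3 active drugs; a *permutation* of a therapy
assigns each active drug a nonzero coded level in {1, 2} while every
other drug sits at level 0 (absent).  The model predicts NCV for every
permutation; a therapy is summarized by the mean and SD of its
permutation predictions (2 values for one drug, 4 for a pair, 8 for a
triple) and therapies are ranked ascending by mean NCV — rank 1 is the
greatest predicted cell killing.  Ties break lexicographically on drug
indices, so rankings are deterministic.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DrugPanel
from .model import QuadraticModel
from .plates import QCReport

__all__ = [
    "CombinationRanking",
    "RSMGrid",
    "rank_combinations",
    "therapy_summary",
    "rsm_grid",
    "sample_report",
]

ACTIVE_LEVELS = (1, 2)


@dataclass(frozen=True)
class CombinationRanking:
    """All enumerated permutations plus the per-therapy summary.

    ``entries``: one row per permutation — therapy (tuple of drug
    indices), levels (tuple), predicted_ncv.
    ``summary``: one row per unique therapy — therapy, mean_ncv, sd_ncv,
    best_ncv, rank (by mean), best_rank (by best permutation).
    """

    order: int
    entries: pd.DataFrame
    summary: pd.DataFrame

    def top(self, k: int) -> pd.DataFrame:
        return self.summary.nsmallest(k, "rank")

    def therapy_row(self, therapy: tuple[int, ...]) -> pd.Series:
        key = tuple(sorted(therapy))
        match = self.summary[self.summary["therapy"] == key]
        if match.empty:
            raise KeyError(f"therapy {key} not in ranking")
        return match.iloc[0]


def _enumerate_order(model: QuadraticModel, order: int) -> pd.DataFrame:
    F = model.n_factors
    combos = list(itertools.combinations(range(F), order))
    assignments = list(itertools.product(ACTIVE_LEVELS, repeat=order))
    rows = []
    vectors = []
    for combo in combos:
        for levels in assignments:
            vec = np.zeros(F)
            vec[list(combo)] = levels
            vectors.append(vec)
            rows.append((combo, levels))
    preds = model.predict(np.array(vectors))
    return pd.DataFrame(
        {
            "therapy": [r[0] for r in rows],
            "levels": [r[1] for r in rows],
            "predicted_ncv": preds,
        }
    )


def rank_combinations(model: QuadraticModel, order: int = 2) -> CombinationRanking:
    """Enumerate every therapy of the given order and rank by mean NCV.

    SD over a therapy's permutations is the sample SD (ddof=1), matching
    the mean +/- SD convention of per-sample reports.
    """
    if not 1 <= order <= model.n_factors:
        raise ValueError(f"order must be in 1..{model.n_factors}, got {order}")
    entries = _enumerate_order(model, order)
    grouped = entries.groupby("therapy", sort=True)["predicted_ncv"]
    summary = pd.DataFrame(
        {
            "therapy": list(grouped.groups.keys()),
            "mean_ncv": grouped.mean().to_numpy(),
            "sd_ncv": grouped.std(ddof=1).to_numpy(),
            "best_ncv": grouped.min().to_numpy(),
        }
    )
    # ascending mean NCV, deterministic lexicographic tie-break on indices
    order_idx = sorted(
        range(len(summary)),
        key=lambda i: (summary["mean_ncv"].iat[i], summary["therapy"].iat[i]),
    )
    rank = np.empty(len(summary), dtype=int)
    rank[order_idx] = np.arange(1, len(summary) + 1)
    summary["rank"] = rank
    best_idx = sorted(
        range(len(summary)),
        key=lambda i: (summary["best_ncv"].iat[i], summary["therapy"].iat[i]),
    )
    best_rank = np.empty(len(summary), dtype=int)
    best_rank[best_idx] = np.arange(1, len(summary) + 1)
    summary["best_rank"] = best_rank
    summary = summary.sort_values("rank", ignore_index=True)
    return CombinationRanking(order=order, entries=entries, summary=summary)


def therapy_summary(
    model: QuadraticModel,
    therapies: dict[str, tuple[str, ...]],
    panel: DrugPanel,
) -> pd.DataFrame:
    """Mean and SD of predicted NCV for named therapies of 1-3 drugs.

    ``therapies`` maps a display name (e.g. a standard-of-care label) to
    the tuple of its drug names.  Averages run over the therapy's
    nonzero dose permutations only.
    """
    rows = []
    for label, drug_names in therapies.items():
        idx = tuple(panel.index(d) for d in drug_names)
        if len(set(idx)) != len(idx):
            raise ValueError(f"therapy {label!r} repeats a drug")
        if not 1 <= len(idx) <= 3:
            raise ValueError(f"therapy {label!r} must have 1-3 drugs")
        vectors = []
        for levels in itertools.product(ACTIVE_LEVELS, repeat=len(idx)):
            vec = np.zeros(model.n_factors)
            vec[list(idx)] = levels
            vectors.append(vec)
        preds = np.asarray(model.predict(np.array(vectors)))
        rows.append(
            {
                "therapy": label,
                "drugs": tuple(drug_names),
                "mean_ncv": float(preds.mean()),
                "sd_ncv": float(preds.std(ddof=1)),
                "n_permutations": len(preds),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RSMGrid:
    """Response-surface map for one drug pair, all other drugs at level 0."""

    pair: tuple[int, int]
    x_levels: np.ndarray  # coded levels of the first drug (grid axis)
    y_levels: np.ndarray
    ncv: np.ndarray  # (grid_n, grid_n), rows indexed by x, cols by y

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.ncv, index=self.x_levels, columns=self.y_levels)
        df.to_csv(path, index_label="level_drug_a")


def rsm_grid(model: QuadraticModel, pair: tuple[int, int], grid_n: int = 41) -> RSMGrid:
    """Predicted-NCV surface over coded levels [0, 2]^2 for a drug pair.

    The parabolic surface visualizes the pairwise interaction; with a
    negative interaction coefficient the surface bends down along the
    rising-dose diagonal.
    """
    i, j = pair
    if i == j:
        raise ValueError("response surface requires two distinct drugs")
    axis = np.linspace(0.0, 2.0, grid_n)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    vectors = np.zeros((grid_n * grid_n, model.n_factors))
    vectors[:, i] = gx.ravel()
    vectors[:, j] = gy.ravel()
    ncv = np.asarray(model.predict(vectors)).reshape(grid_n, grid_n)
    return RSMGrid(pair=(i, j), x_levels=axis, y_levels=axis, ncv=ncv)


def sample_report(
    pair_ranking: CombinationRanking,
    single_ranking: CombinationRanking,
    qc: QCReport,
    panel: DrugPanel,
    top_k: int = 10,
    named_therapies: dict[str, tuple[str, ...]] | None = None,
    model: QuadraticModel | None = None,
) -> dict:
    """Assemble the per-sample report: QC block, top-k pairs, one-drug table.

    The report is a plain JSON-serializable dict; regenerating it from
    the same inputs yields byte-identical JSON.  ``named_therapies``
    (e.g. the standard of care) are summarized through the model when
    one is provided.
    """
    if pair_ranking.order != 2 or single_ranking.order != 1:
        raise ValueError("expected a pair ranking (order 2) and a single-drug ranking (order 1)")
    top = pair_ranking.top(top_k)
    top_block = [
        {
            "rank": int(r["rank"]),
            "drugs": [panel.names[d] for d in r["therapy"]],
            "mean_ncv": round(float(r["mean_ncv"]), 6),
            "sd_ncv": round(float(r["sd_ncv"]), 6),
            "extrapolated_below_zero": bool(r["mean_ncv"] < 0),
        }
        for _, r in top.iterrows()
    ]
    singles = [
        {
            "rank": int(r["rank"]),
            "drug": panel.names[r["therapy"][0]],
            "mean_ncv": round(float(r["mean_ncv"]), 6),
            "sd_ncv": round(float(r["sd_ncv"]), 6),
        }
        for _, r in single_ranking.summary.sort_values("rank").iterrows()
    ]
    named_block = []
    if named_therapies:
        if model is None:
            raise ValueError("named_therapies requires the fitted model")
        tbl = therapy_summary(model, named_therapies, panel)
        named_block = [
            {
                "therapy": r["therapy"],
                "drugs": list(r["drugs"]),
                "mean_ncv": round(float(r["mean_ncv"]), 6),
                "sd_ncv": round(float(r["sd_ncv"]), 6),
            }
            for _, r in tbl.iterrows()
        ]
    return {
        "sample_id": qc.sample_id,
        "qc": {
            "zprime": round(qc.zprime, 6),
            "ssmd": round(qc.ssmd, 6),
            "zprime_min": qc.zprime_min,
            "passed": qc.passed,
        },
        "top_two_drug_therapies": top_block,
        "one_drug_table": singles,
        "named_therapies": named_block,
        "rsm_pairs": [
            [panel.names[d] for d in r["therapy"]] for _, r in top.iterrows()
        ],
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
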