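"""Synthetic data generation for end-to-end pipeline testing.

Emulates everything a screening campaign produces, with known ground
truth so every downstream stage has a parameter-recovery oracle:

* quadratic ground-truth viability surfaces with planted synergistic
  drug pairs (strongly negative interaction coefficients);
* CellTiter-Glo-style luminescence plates for an experimental design,
  with positive/negative control wells, technical replicates, and
  additive Gaussian readout noise on the NCV scale;
* logistic outcome-linked cohorts (mean NCV -> RECIST label) for
  concordance analysis;
* four-parameter-logistic dose-response tables.

Noise is additive Gaussian on the NCV scale (luminescence truncated at
zero); the luminescence scale is arbitrary, with configurable control
means whose default 1e6 / 1e4 separation mimics a healthy assay window.
Defaults mirror the screening protocol the package analyzes: 12 drugs
at three dose levels, 155-run composite design, technical duplicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import DesignMatrix, DrugPanel
from .model import quadratic_basis
from .plates import PlateReadout

__all__ = [
    "GroundTruthSurface",
    "SimulatedCohort",
    "gen_ground_truth",
    "simulate_plate",
    "simulate_cohort",
    "simulate_dose_response",
    "default_panel",
]

# Generated surfaces allocate a total "kill budget" so that viability
# stays in [~0, 1] over the whole coded-level cube: a quadratic surface
# that dips far below zero at high-dose corners could not have been fit
# to control-anchored viability data, and negative true viability would
# make simulated luminescence unphysical.  Planted interactions claim
# their share first; per-drug top-dose inhibitions split the remainder
# unevenly (Dirichlet) so samples differ in which drugs are potent;
# non-planted interactions stay small so a planted synergy is
# identifiable at the documented noise level.
TOTAL_KILL_BUDGET = 0.95
SINGLES_BUDGET_FRACTION = 0.85
MID_DOSE_FRACTION = (0.55, 0.8)  # level-1 inhibition as a share of level-2
NONPLANTED_INT_HALF_WIDTH = 0.01
SURFACE_MIN_NCV = 0.01
DEFAULT_NOISE_SD = 0.02
DEFAULT_POS_MEAN = 1e6
DEFAULT_NEG_MEAN = 1e4


@dataclass(frozen=True)
class GroundTruthSurface:
    """Known quadratic viability surface used to generate plates.

    Coefficients follow the shared basis order (intercept, linear,
    quadratic, pairwise interactions with i < j).
    """

    n_drugs: int
    beta0: float
    beta_lin: np.ndarray
    beta_quad: np.ndarray
    beta_int: np.ndarray
    noise_sd: float
    planted_pairs: tuple[tuple[int, int], ...]
    seed: int

    def __post_init__(self) -> None:
        F = self.n_drugs
        if self.beta_lin.shape != (F,) or self.beta_quad.shape != (F,):
            raise ValueError("linear/quadratic coefficient vectors must have length n_drugs")
        if self.beta_int.shape != (F * (F - 1) // 2,):
            raise ValueError("interaction vector must have length n_drugs*(n_drugs-1)/2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def coefficients(self) -> np.ndarray:
        """Full coefficient vector in quadratic_basis order."""
        return np.concatenate([[self.beta0], self.beta_lin, self.beta_quad, self.beta_int])

    def evaluate(self, levels: np.ndarray) -> np.ndarray:
        """Noise-free NCV at coded level vector(s)."""
        out = quadratic_basis(np.asarray(levels, dtype=float)) @ self.coefficients
        return out if np.ndim(levels) > 1 else float(out[0])

    def interaction(self, i: int, j: int) -> float:
        if i == j:
            raise ValueError("need two distinct drug indices")
        i, j = min(i, j), max(i, j)
        iu, ju = np.triu_indices(self.n_drugs, k=1)
        k = int(np.flatnonzero((iu == i) & (ju == j))[0])
        return float(self.beta_int[k])


def gen_ground_truth(
    n_drugs: int,
    planted_pairs: Sequence[tuple[int, int]] = (),
    effect_scale: float = 0.15,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> GroundTruthSurface:
    """Draw a random quadratic surface with planted synergistic pairs.

    Baseline viability is 1 at all-zero levels; each planted pair gets
    an interaction coefficient at or below ``-effect_scale`` (drawn in
    ``[-1.1, -1.0] * effect_scale``).  Single-drug profiles are built
    from a top-dose inhibition and a saturating mid-dose fraction, with
    the total kill budget shared so the surface stays nonnegative over
    the coded cube [0, 2]^F (exact corner check; non-planted
    interactions shrink if needed, planted ones never do).  Fixed seed
    gives an identical surface on every call.
    """
    if n_drugs < 2:
        raise ValueError("need at least 2 drugs")
    if effect_scale <= 0:
        raise ValueError("effect_scale must be positive")
    norm_pairs = []
    for pair in planted_pairs:
        i, j = pair
        if i == j or not (0 <= i < n_drugs) or not (0 <= j < n_drugs):
            raise ValueError(f"invalid planted pair {pair} for {n_drugs} drugs")
        norm_pairs.append((min(i, j), max(i, j)))
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_drugs, k=1)
    planted_coef = -effect_scale * rng.uniform(1.0, 1.1, size=len(norm_pairs))
    planted_budget = 4.0 * float(np.abs(planted_coef).sum())
    if planted_budget > 0.9:
        raise ValueError(
            f"planted effects consume {planted_budget:.2f} of the viability range; "
            "reduce effect_scale or the number of planted pairs"
        )
    remaining = TOTAL_KILL_BUDGET - planted_budget
    # per-drug top-dose inhibition b_i and mid-dose inhibition a_i = u_i b_i
    b = SINGLES_BUDGET_FRACTION * remaining * rng.dirichlet(np.ones(n_drugs))
    u = rng.uniform(*MID_DOSE_FRACTION, size=n_drugs)
    a = u * b
    # solve beta_lin*x + beta_quad*x^2 = -inhibition at x = 1 (a) and x = 2 (b)
    beta_lin = (b - 4.0 * a) / 2.0
    beta_quad = (2.0 * a - b) / 2.0
    beta_int = rng.uniform(
        -NONPLANTED_INT_HALF_WIDTH, NONPLANTED_INT_HALF_WIDTH, size=iu.size
    )
    planted_idx = []
    for (i, j), coef in zip(norm_pairs, planted_coef):
        k = int(np.flatnonzero((iu == i) & (ju == j))[0])
        beta_int[k] = coef
        planted_idx.append(k)
    # exact nonnegativity guard: pure-quadratic terms are convex in each
    # coordinate, so the minimum over [0, 2]^F sits at a corner of
    # {0, 2}^F; shrink non-planted interactions until it clears the floor
    nonplanted = np.setdiff1d(np.arange(iu.size), planted_idx)
    corners = np.array(list(itertools.product([0.0, 2.0], repeat=n_drugs)))
    B = quadratic_basis(corners)
    for _ in range(60):
        coef_vec = np.concatenate([[1.0], beta_lin, beta_quad, beta_int])
        if float((B @ coef_vec).min()) >= SURFACE_MIN_NCV:
            break
        beta_int[nonplanted] *= 0.6
    return GroundTruthSurface(
        n_drugs=n_drugs,
        beta0=1.0,
        beta_lin=beta_lin,
        beta_quad=beta_quad,
        beta_int=beta_int,
        noise_sd=noise_sd,
        planted_pairs=tuple(norm_pairs),
        seed=seed,
    )


def simulate_plate(
    truth: GroundTruthSurface,
    design: DesignMatrix,
    replicates: int = 2,
    n_pos_controls: int = 8,
    n_neg_controls: int = 8,
    pos_mean: float = DEFAULT_POS_MEAN,
    neg_mean: float = DEFAULT_NEG_MEAN,
    seed: int = 0,
) -> PlateReadout:
    """Simulate raw luminescence for every design run plus control wells.

    Treatment wells read ``neg_mean + NCV * (pos_mean - neg_mean)`` plus
    Gaussian noise of SD ``truth.noise_sd`` on the NCV scale; control
    wells scatter around their means with the same noise.  Raw values
    are truncated at zero (a luminometer reports nonnegative counts).
    """
    if design.n_factors != truth.n_drugs:
        raise ValueError(
            f"design has {design.n_factors} factors but surface has {truth.n_drugs} drugs"
        )
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if pos_mean <= neg_mean:
        raise ValueError(
            f"positive control mean {pos_mean:g} must exceed negative control mean {neg_mean:g}"
        )
    rng = np.random.default_rng(seed)
    span = pos_mean - neg_mean
    ncv_true = truth.evaluate(design.levels.astype(float))
    rows = []
    well = 0
    for rep in range(1, replicates + 1):
        noise = rng.normal(0.0, truth.noise_sd, size=design.n_runs) if truth.noise_sd else 0.0
        raw = neg_mean + (ncv_true + noise) * span
        for run_id, value in enumerate(raw):
            rows.append((f"W{well:04d}", run_id, rep, "treatment", max(value, 0.0)))
            well += 1
    for role, mean, count in (
        ("pos_ctrl", pos_mean, n_pos_controls),
        ("neg_ctrl", neg_mean, n_neg_controls),
    ):
        noise = rng.normal(0.0, truth.noise_sd, size=count) if truth.noise_sd else np.zeros(count)
        for value in mean + noise * span:
            rows.append((f"W{well:04d}", -1, 0, role, max(value, 0.0)))
            well += 1
    wells = pd.DataFrame(rows, columns=["well", "run_id", "replicate", "role", "raw"])
    return PlateReadout(wells=wells)


@dataclass(frozen=True)
class SimulatedCohort:
    """Per-sample surfaces and plates plus outcome-linked clinical labels.

    ``outcomes`` columns: case_id, therapy (drug names joined with '+'),
    mean_ncv (true surface value), recist.
    """

    samples: tuple[tuple[str, GroundTruthSurface, PlateReadout], ...]
    outcomes: pd.DataFrame
    link: tuple[float, float, float]  # (c, k, label_noise)
    panel: DrugPanel = field(repr=False, default=None)

    def write(self, directory: str | Path) -> None:
        """Serialize to the pipeline's CSV/JSON formats (deterministic)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for sample_id, _, plate in self.samples:
            if plate is not None:
                plate.to_csv(directory / f"plate_{sample_id}.csv")
        self.outcomes.to_csv(directory / "outcomes.csv", index=False)
        if self.panel is not None:
            self.panel.to_json(directory / "panel.json")


def _therapy_mean_ncv(truth: GroundTruthSurface, drugs: tuple[int, ...]) -> float:
    """True mean NCV of a therapy: average over its nonzero dose permutations."""
    vectors = []
    for levels in itertools.product((1, 2), repeat=len(drugs)):
        vec = np.zeros(truth.n_drugs)
        vec[list(drugs)] = levels
        vectors.append(vec)
    return float(np.mean(truth.evaluate(np.array(vectors))))


def simulate_cohort(
    n_samples: int,
    panel: DrugPanel,
    design: DesignMatrix,
    outcome_link: tuple[float, float, float] = (0.8, 25.0, 0.05),
    n_outcomes: int = 27,
    planted_pairs: Sequence[tuple[int, int]] = ((0, 1),),
    effect_scale: float = 0.2,
    noise_sd: float = DEFAULT_NOISE_SD,
    with_plates: bool = True,
    seed: int = 0,
) -> SimulatedCohort:
    """Simulate a screening cohort with outcome labels tied to mean NCV.

    Each sample gets its own ground-truth surface (same planted pairs,
    sample-specific coefficients) and a noisy plate on ``design``.
    Treatment outcomes pick a random case and a therapy of one or two
    drugs, drawn with probability proportional to each drug's top-dose
    inhibition in that sample — mirroring that clinically evaluated
    therapies skew toward drugs the screen finds active, and giving
    outcome NCVs that spread across the responder cutoff instead of
    piling up near 1.  The outcome is labeled responder (PR or SD,
    split at random) with probability
    ``1 / (1 + exp(k * (mean_ncv - c)))`` — low viability favors
    response — then the responder call flips with probability
    ``label_noise``.  ``k = inf`` gives a hard threshold at ``c``.

    ``with_plates=False`` skips plate simulation (surfaces and outcomes
    only) for analyses that never touch raw luminescence.
    """
    c, k, label_noise = outcome_link
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0 <= label_noise < 0.5:
        raise ValueError("label_noise must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    samples = []
    surfaces = []
    for s in range(n_samples):
        truth = gen_ground_truth(
            panel.n_drugs,
            planted_pairs=planted_pairs,
            effect_scale=effect_scale,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        plate_seed = int(rng.integers(0, 2**31 - 1))
        plate = simulate_plate(truth, design, seed=plate_seed) if with_plates else None
        samples.append((f"S{s:03d}", truth, plate))
        surfaces.append(truth)
    rows = []
    for o in range(n_outcomes):
        s = int(rng.integers(0, n_samples))
        truth = surfaces[s]
        n_drugs_in_therapy = int(rng.integers(1, 3))  # single agent or pair
        potency = -(2.0 * truth.beta_lin + 4.0 * truth.beta_quad)  # top-dose inhibition
        potency = np.clip(potency, 0.0, None)
        weights = potency / potency.sum() if potency.sum() > 0 else None
        drugs = tuple(
            sorted(rng.choice(panel.n_drugs, size=n_drugs_in_therapy, replace=False, p=weights))
        )
        mean_ncv = _therapy_mean_ncv(truth, drugs)
        if np.isinf(k):
            p_resp = 1.0 if mean_ncv < c else (0.5 if mean_ncv == c else 0.0)
        else:
            p_resp = 1.0 / (1.0 + np.exp(k * (mean_ncv - c)))
        responder = rng.random() < p_resp
        if label_noise and rng.random() < label_noise:
            responder = not responder
        if responder:
            recist = "PR" if rng.random() < 0.5 else "SD"
        else:
            recist = "PD"
        rows.append(
            {
                "case_id": f"C{o:03d}",
                "therapy": "+".join(panel.names[d] for d in drugs),
                "mean_ncv": mean_ncv,
                "recist": recist,
            }
        )
    outcomes = pd.DataFrame(rows)
    return SimulatedCohort(
        samples=tuple(samples), outcomes=outcomes, link=(c, k, label_noise), panel=panel
    )


def simulate_dose_response(
    top: float,
    bottom: float,
    ic50: float,
    hill: float,
    doses: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Four-parameter-logistic viability table with additive Gaussian noise."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    D = np.asarray(doses, dtype=float)
    if (D <= 0).any():
        raise ValueError("doses must be strictly positive")
    rng = np.random.default_rng(seed)
    viability = bottom + (top - bottom) / (1.0 + (D / ic50) ** hill)
    if noise_sd:
        viability = viability + rng.normal(0.0, noise_sd, size=D.size)
    return pd.DataFrame({"dose_uM": D, "viability": viability})


def default_panel() -> DrugPanel:
    """Representative 12-drug soft-tissue-sarcoma panel (synthetic doses).

    Drug names follow the screening panel the package models
    (chemotherapies, epigenetic agents, CDK and multi-kinase
    inhibitors); the IC10/IC20 doses are synthetic round-number
    placeholders in uM, since per-sample doses are derived from each
    sample's own dose-response curves in practice.  Level 0 is dose 0
    (drug absent).
    """
    drugs = [
        ("ifosfamide", 20.0, 50.0),
        ("doxorubicin", 0.05, 0.2),
        ("gemcitabine", 0.05, 0.2),
        ("paclitaxel", 0.005, 0.02),
        ("eribulin", 0.002, 0.01),
        ("trabectedin", 0.001, 0.005),
        ("ricolinostat", 1.0, 4.0),
        ("azacitidine", 2.0, 8.0),
        ("AZD5153", 0.5, 2.0),
        ("palbociclib", 1.0, 4.0),
        ("pazopanib", 5.0, 20.0),
        ("ponatinib", 0.1, 0.5),
    ]
    return DrugPanel(
        names=tuple(name for name, _, _ in drugs),
        doses=tuple((0.0, d1, d2) for _, d1, d2 in drugs),
    )
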