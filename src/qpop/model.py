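"""Second-order (quadratic) viability model on coded dose levels.

The core of the platform is an ordinary least-squares fit of normalized
cell viability (NCV) on the full second-order polynomial basis of coded
dose levels,

    NCV = b0 + sum_i b_i x_i + sum_i b_ii x_i^2 + sum_{i<j} b_ij x_i x_j,

where ``x_i`` in {0, 1, 2} codes the three tested doses of drug ``i``
(absent / low / high).  For ``F`` drugs the basis has
``1 + 2F + F(F-1)/2`` terms (91 for the standard 12-drug panel).
Regression operates on coded levels, not micromolar doses, so unequal
dose spacing across drugs is absorbed by the coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .design import DesignMatrix
from .plates import ViabilityTable

__all__ = [
    "QuadraticModel",
    "quadratic_basis",
    "basis_term_names",
    "n_quadratic_terms",
    "fit_quadratic",
    "predict_ncv",
]


def n_quadratic_terms(n_factors: int) -> int:
    """Number of terms in the full second-order basis for ``n_factors`` drugs."""
    return 1 + 2 * n_factors + n_factors * (n_factors - 1) // 2


def quadratic_basis(levels: np.ndarray) -> np.ndarray:
    """Expand an ``(n, F)`` array of coded levels into the second-order basis.

    Column order: intercept, F linear terms, F pure-quadratic terms, then
    the F(F-1)/2 pairwise products in lexicographic (i, j) order with
    i < j.  This order is shared by every consumer of the coefficient
    vector in the package.
    """
    X = np.asarray(levels, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n, F = X.shape
    iu, ju = np.triu_indices(F, k=1)
    cols = np.empty((n, n_quadratic_terms(F)))
    cols[:, 0] = 1.0
    cols[:, 1 : 1 + F] = X
    cols[:, 1 + F : 1 + 2 * F] = X**2
    cols[:, 1 + 2 * F :] = X[:, iu] * X[:, ju]
    return cols


def basis_term_names(drug_names: list[str] | None, n_factors: int) -> list[str]:
    """Human-readable names for the basis columns, aligned with quadratic_basis."""
    if drug_names is None:
        drug_names = [f"x{i}" for i in range(n_factors)]
    names = ["intercept"]
    names += list(drug_names)
    names += [f"{d}^2" for d in drug_names]
    iu, ju = np.triu_indices(n_factors, k=1)
    names += [f"{drug_names[i]}:{drug_names[j]}" for i, j in zip(iu, ju)]
    return names


@dataclass
class QuadraticModel:
    """Fitted second-order viability model.

    ``coef`` holds the full coefficient vector in quadratic_basis order;
    the intercept / linear / quadratic / interaction views are slices of
    it.  ``interaction(i, j)`` returns the pairwise coefficient for any
    ordering of the two drug indices.
    """

    n_factors: int
    coef: np.ndarray
    r_squared: float
    resid_sd: float
    n_obs: int
    level_coding: tuple[float, float, float] = (0.0, 1.0, 2.0)
    drug_names: list[str] | None = None
    _pair_index: dict[tuple[int, int], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        expected = n_quadratic_terms(self.n_factors)
        if self.coef.shape != (expected,):
            raise ValueError(
                f"coefficient vector must have length {expected} for "
                f"{self.n_factors} factors, got {self.coef.shape}"
            )
        iu, ju = np.triu_indices(self.n_factors, k=1)
        off = 1 + 2 * self.n_factors
        self._pair_index = {
            (int(i), int(j)): off + k for k, (i, j) in enumerate(zip(iu, ju))
        }

    @property
    def beta0(self) -> float:
        return float(self.coef[0])

    @property
    def beta_lin(self) -> np.ndarray:
        return self.coef[1 : 1 + self.n_factors]

    @property
    def beta_quad(self) -> np.ndarray:
        return self.coef[1 + self.n_factors : 1 + 2 * self.n_factors]

    @property
    def beta_int(self) -> np.ndarray:
        return self.coef[1 + 2 * self.n_factors :]

    def interaction(self, i: int, j: int) -> float:
        if i == j:
            raise ValueError("interaction requires two distinct drug indices")
        key = (min(i, j), max(i, j))
        return float(self.coef[self._pair_index[key]])

    def predict(self, levels: np.ndarray) -> np.ndarray | float:
        """Predicted NCV for one level vector or an ``(n, F)`` array of them."""
        arr = np.asarray(levels, dtype=float)
        single = arr.ndim == 1
        out = quadratic_basis(arr) @ self.coef
        return float(out[0]) if single else out


def fit_quadratic(viability: ViabilityTable, design: DesignMatrix) -> QuadraticModel:
    """OLS fit of replicate-level NCV on the second-order basis of the design.

    Every run in the viability table must map to a design row by run id;
    replicates enter as individual observations (unweighted OLS, so
    balanced duplication is equivalent to fitting run means).

    Raises ``ValueError`` if the expanded basis is rank-deficient on the
    observed runs — validate the design with
    :func:`qpop.design.validate_design` in that case.
    """
    reps = viability.replicates
    run_ids = reps["run_id"].to_numpy()
    unknown = set(run_ids) - set(range(design.n_runs))
    if unknown:
        raise ValueError(f"viability table references unknown run ids: {sorted(unknown)}")
    X = quadratic_basis(design.levels[run_ids])
    y = reps["ncv"].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"quadratic basis is rank-deficient on the observed runs "
            f"(rank {rank} < {X.shape[1]} terms); run validate_design on the design"
        )
    res = sm.OLS(y, X).fit()
    return QuadraticModel(
        n_factors=design.n_factors,
        coef=np.asarray(res.params),
        r_squared=float(res.rsquared),
        resid_sd=float(np.sqrt(res.scale)),
        n_obs=int(res.nobs),
    )


def predict_ncv(model: QuadraticModel, levels: np.ndarray) -> np.ndarray | float:
    """Evaluate the fitted polynomial at coded level vector(s)."""
    return model.predict(levels)
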