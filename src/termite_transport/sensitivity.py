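"""Sampling-based sensitivity analysis: CC, PCC, PRCC and Latin hypercube
designs over the four control levels (k1, k2, k3, k4).

The partial rank correlation coefficient (PRCC) between an input column and a
response is the Pearson correlation between the residuals of two ordinary
least-squares fits on the *ranked* data: the ranked input regressed on all
other ranked inputs, and the ranked response regressed on the same covariates.
It measures monotone association in [-1, 1] while controlling for the other
inputs, and is invariant under strictly monotone transformations of the
response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc, rankdata

VARIABLE_NAMES = ("k1", "k2", "k3", "k4")
LEVEL_RANGE = (1, 11)


class DegenerateDesignError(ValueError):
    """Raised for rank-deficient covariates or zero-variance vectors."""


def correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient.

    Computed from the centered cross- and auto-sums; raises
    :class:`DegenerateDesignError` if either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors of length >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.sum(dx * dx))
    sy = np.sqrt(np.sum(dy * dy))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateDesignError("correlation undefined for zero-variance input")
    return float(np.sum(dx * dy) / (sx * sy))


def _ols_residuals(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of v regressed on covariates plus an intercept."""
    X = np.column_stack([np.ones(len(v)), covariates])
    coef, _, rank, _ = np.linalg.lstsq(X, v, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateDesignError("covariate matrix is rank deficient")
    return v - X @ coef


def partial_correlation(
    xj: np.ndarray, y: np.ndarray, others: np.ndarray
) -> float:
    """Partial correlation of xj and y controlling for the ``others`` columns.

    Both xj and y are regressed (OLS with intercept) on the remaining input
    columns; the PCC is the Pearson correlation of the two residual vectors.
    """
    xj = np.asarray(xj, dtype=float)
    y = np.asarray(y, dtype=float)
    others = np.atleast_2d(np.asarray(others, dtype=float))
    if others.shape[0] != xj.size:
        others = others.T
    if xj.size <= others.shape[1] + 2:
        raise ValueError("need N > number of covariates + 2")
    return correlation(_ols_residuals(xj, others), _ols_residuals(y, others))


@dataclass(frozen=True)
class SampleDesign:
    """A sensitivity-analysis input design: N rows of k integer levels."""

    rows: np.ndarray                       # shape (N, k)
    scheme: str                            # "FULL_FACTORIAL" | "LHS"
    replicates: int = 1
    names: tuple[str, ...] = VARIABLE_NAMES

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def n_runs(self) -> int:
        """Total simulations the design accounts for (rows x replicates)."""
        return self.n_rows * self.replicates


@dataclass(frozen=True)
class SensitivityResult:
    """PRCC per input variable with the design size that produced it."""

    prcc: dict
    n_samples: int
    notes: str = "average-rank transform; OLS residual partial correlation"

    def to_json(self) -> str:
        import json

        return json.dumps(
            {"prcc": self.prcc, "n_samples": self.n_samples, "notes": self.notes}
        )


def prcc(
    design: SampleDesign | np.ndarray,
    responses: np.ndarray,
    names: tuple[str, ...] | None = None,
) -> SensitivityResult:
    """Partial rank correlation of each design column with the response.

    Every column and the response are rank-transformed (ties get average
    ranks) before the residual partial correlation is computed per variable.
    """
    if isinstance(design, SampleDesign):
        X = np.asarray(design.rows, dtype=float)
        names = names or design.names
    else:
        X = np.asarray(design, dtype=float)
        names = names or tuple(f"x{j + 1}" for j in range(X.shape[1]))
    y = np.asarray(responses, dtype=float)
    if y.ndim != 1 or y.size != X.shape[0]:
        raise ValueError("responses must align with design rows")
    if np.ptp(y) == 0.0:
        raise DegenerateDesignError("constant response vector")
    R = np.column_stack([rankdata(X[:, j]) for j in range(X.shape[1])])
    ry = rankdata(y)
    out = {}
    for j, name in enumerate(names):
        others = np.delete(R, j, axis=1)
        out[name] = partial_correlation(R[:, j], ry, others)
    return SensitivityResult(prcc=out, n_samples=y.size)


def prcc_null_band(
    design: SampleDesign | np.ndarray,
    responses: np.ndarray,
    rng: np.random.Generator,
    n_permutations: int = 1000,
    alpha: float = 0.05,
) -> float:
    """Two-sided permutation null band half-width for |PRCC|.

    Returns the (1 - alpha) quantile of max_j |PRCC_j| over response
    permutations; observed magnitudes above it are unlikely under independence.
    """
    y = np.asarray(responses, dtype=float)
    maxima = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = prcc(design, rng.permutation(y))
        maxima[i] = max(abs(v) for v in perm.prcc.values())
    return float(np.quantile(maxima, 1.0 - alpha))


def full_factorial(
    levels: tuple[int, ...] = tuple(range(LEVEL_RANGE[0], LEVEL_RANGE[1] + 1)),
    k: int = 4,
    replicates: int = 1,
    names: tuple[str, ...] = VARIABLE_NAMES,
) -> SampleDesign:
    """All level combinations in k variables (11^4 = 14,641 rows by default)."""
    grids = np.meshgrid(*([np.asarray(levels)] * k), indexing="ij")
    rows = np.column_stack([g.ravel() for g in grids])
    return SampleDesign(
        rows=rows, scheme="FULL_FACTORIAL", replicates=replicates, names=names[:k]
    )


def lhs_sample(
    n: int,
    k: int,
    rng: np.random.Generator,
    replicates: int = 1,
    names: tuple[str, ...] = VARIABLE_NAMES,
) -> SampleDesign:
    """Latin hypercube design over the integer levels 1..11.

    One sample per stratum per dimension (n strata), independently permuted
    across dimensions; the continuous draws on [0.5, 11.5] are rounded to the
    nearest integer level.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    u = qmc.LatinHypercube(d=k, seed=rng).random(n)        # in [0, 1)
    lo, hi = LEVEL_RANGE
    rows = np.floor(lo + (hi - lo + 1) * u).astype(np.int64)  # levels 1..11
    return SampleDesign(rows=rows, scheme="LHS", replicates=replicates, names=names[:k])
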