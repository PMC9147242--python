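"""Regularized MANOVA with Ledoit-Wolf shrinkage.

The pooled within-group covariance ``S`` is shrunk toward the scaled
identity ``gamma * I`` (``gamma = trace(S)/p``) with intensity ``delta``
in [0, 1]:

    S_reg = (1 - delta) * S + delta * gamma * I

``delta = 0`` recovers classical MANOVA (the Lawley-Hotelling trace of
``S^-1 H``), which requires more samples than variables; ``delta = 1``
collapses the within-structure to a multiple of the identity so the trace
statistic becomes a strictly increasing transform of the effect-matrix
SSQ, i.e. the ASCA statistic — permutation p-values then coincide
seed-for-seed with ASCA's.  The shrinkage intensity is estimated with the
Ledoit-Wolf (2004) well-conditioned-estimator formula applied to the
within-group-centered rows, following Engel et al. (2015).

Canonical loadings are the leading eigenvectors of ``S_reg^-1 H``,
computed through the symmetrized (whitened) form for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .asca import ComponentModel, PermutationResult, fix_sign, permutation_test
from .decompose import decompose
from .exceptions import ConfigurationError, DesignError, SingularWithinError
from .io import DesignTable

__all__ = [
    "RegularizedModel",
    "estimate_delta",
    "fit_rmanova",
    "rmanova_significance",
    "trace_statistic",
]


@dataclass
class RegularizedModel:
    """Scatter matrices, trace statistic and canonical model of one term."""

    term: str
    delta: float
    within_scatter: np.ndarray  # S, pooled within covariance (df = n - k)
    between_scatter: np.ndarray  # H = E'E
    regularized_within: np.ndarray
    statistic: float
    canonical: ComponentModel


def _within_rows(X, design: DesignTable, term: str):
    """Within-group-centered rows, residual df and effect matrix."""
    if term not in design.factors:
        raise DesignError(f"rMANOVA requires a plain factor term, got {term!r}")
    dec = decompose(X, design, [term])
    k = dec.n_levels[term]
    n = X.shape[0]
    if dec.residual_df < 1:
        raise DesignError("no residual degrees of freedom (n <= number of levels)")
    counts = np.bincount(design.codes(term), minlength=k)
    if np.any(counts < 2):
        raise DesignError(
            f"every level of {term!r} needs >= 2 samples to estimate the "
            "within-group covariance"
        )
    return dec.residuals, n - k, dec.effect_matrices[term]


def ledoit_wolf_intensity(rows: np.ndarray) -> float:
    """Ledoit-Wolf shrinkage intensity toward ``gamma * I``.

    ``rows`` are observations already centered at zero (here: within their
    group); the sample covariance uses the 1/n convention of the original
    estimator.  Returns the optimal intensity clipped into [0, 1].
    """
    rows = np.asarray(rows, dtype=float)
    n, p = rows.shape
    S = rows.T @ rows / n
    mu = float(np.trace(S)) / p
    d2 = float(np.sum((S - mu * np.eye(p)) ** 2)) / p
    if d2 <= 0:
        return 0.0
    sq_norms = np.sum(rows**2, axis=1)
    b_bar2 = (float(np.sum(sq_norms**2)) / n - float(np.sum(S**2))) / (n * p)
    b2 = min(max(b_bar2, 0.0), d2)
    return float(b2 / d2)


def estimate_delta(X, design: DesignTable, term: str) -> float:
    """Shrinkage intensity for the pooled within-group covariance.

    Requires at least 2 samples per level of ``term``.  Close to 1 in the
    p >> n regime (heavy shrinkage), close to 0 when n >> p.
    """
    X = np.asarray(X, dtype=float)
    residuals, _, _ = _within_rows(X, design, term)
    return ledoit_wolf_intensity(residuals)


def _scatter(X, design, term, delta):
    X = np.asarray(X, dtype=float)
    residuals, df, effect = _within_rows(X, design, term)
    if delta == "auto":
        delta = ledoit_wolf_intensity(residuals)
    delta = float(delta)
    if not 0 <= delta <= 1:
        raise ConfigurationError("delta must lie in [0, 1] or be 'auto'")
    p = X.shape[1]
    S = residuals.T @ residuals / df
    gamma = float(np.trace(S)) / p
    if delta == 0 and p >= df:
        raise SingularWithinError(
            f"within covariance is singular at delta=0 with p={p} >= "
            f"residual df={df}; use delta > 0"
        )
    if gamma == 0 and delta > 0:
        raise SingularWithinError("within covariance is identically zero")
    S_reg = (1 - delta) * S
    S_reg[np.diag_indices(p)] += delta * gamma
    return S, S_reg, effect, delta, residuals


def trace_statistic(X, design: DesignTable, term: str, delta="auto") -> float:
    """Lawley-Hotelling-type statistic trace(S_reg^-1 H), H = E'E.

    Computed as trace(E S_reg^-1 E') to keep the cost at one Cholesky of
    the p x p regularized within matrix plus triangular solves.
    """
    _, S_reg, effect, _, _ = _scatter(X, design, term, delta)
    cf = linalg.cho_factor(S_reg, lower=True, check_finite=False)
    Y = linalg.cho_solve(cf, effect.T, check_finite=False)  # p x n
    return float(np.sum(effect * Y.T))


def fit_rmanova(
    X,
    design: DesignTable,
    term: str,
    delta="auto",
    n_components: int | None = None,
) -> RegularizedModel:
    """Fit the regularized MANOVA model for one factor term.

    ``delta`` may be a number in [0, 1] or ``"auto"`` (Ledoit-Wolf
    estimate).  Canonical loadings are unit-norm leading eigenvectors of
    ``S_reg^-1 H``; canonical scores are the centered data projected onto
    them.
    """
    X = np.asarray(X, dtype=float)
    S, S_reg, effect, delta_val, _ = _scatter(X, design, term, delta)
    cf = linalg.cho_factor(S_reg, lower=True, check_finite=False)
    Y = linalg.cho_solve(cf, effect.T, check_finite=False)
    statistic = float(np.sum(effect * Y.T))

    # Whitened symmetric eigenproblem: W^-1/2 H W^-1/2.
    evals_w, evecs_w = linalg.eigh(S_reg, check_finite=False)
    if np.any(evals_w <= 0):
        raise SingularWithinError("regularized within matrix is not positive definite")
    inv_sqrt = (evecs_w / np.sqrt(evals_w)) @ evecs_w.T
    H = effect.T @ effect
    M = inv_sqrt @ H @ inv_sqrt
    M = (M + M.T) / 2
    evals, evecs = linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    k = len(design.levels(term))
    max_comp = int(min(k - 1, X.shape[1]))
    if n_components is None:
        n_components = max_comp
    if not 1 <= n_components <= max_comp:
        raise ConfigurationError(
            f"n_components must be between 1 and {max_comp}, got {n_components}"
        )
    a = inv_sqrt @ evecs[:, :n_components]
    a /= np.linalg.norm(a, axis=0, keepdims=True)
    scores = (X - X.mean(axis=0)) @ a
    a, scores = fix_sign(a, scores)
    total = float(evals.sum()) if evals.sum() > 0 else 1.0
    canonical = ComponentModel(
        method="canonical",
        scores=scores,
        loadings=a,
        explained=evals[:n_components] / total,
    )
    return RegularizedModel(
        term=term,
        delta=delta_val,
        within_scatter=S,
        between_scatter=H,
        regularized_within=S_reg,
        statistic=statistic,
        canonical=canonical,
    )


def rmanova_significance(
    X,
    design: DesignTable,
    term: str,
    delta="auto",
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> PermutationResult:
    """Permutation test of ``term`` with the regularized trace statistic.

    Under ``delta="auto"`` the shrinkage intensity is re-estimated inside
    every permutation, keeping the estimator part of the tested procedure.
    """
    return permutation_test(
        X,
        design,
        term,
        n_permutations=n_permutations,
        seed=seed,
        statistic="rmanova_trace",
        delta=delta,
    )
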