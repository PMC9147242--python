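"""Group-wise ASCA: sparse components restricted to correlated groups.

Groups of related variables are found as connected components of the
thresholded absolute-correlation graph of the data columns (a
deterministic proxy for group identification; threshold configurable,
default 0.7).  ``fit_gasca`` then extracts components from an effect
matrix greedily: at each step the candidate group whose restricted
leading singular vector explains the most SSQ wins, the loading is that
vector embedded in full space (zeros outside the group), and the rank-1
fit is deflated before the next step.  Every loading is therefore
supported on exactly one group.

The permutation statistic is the SSQ explained by the first group-wise
component, which makes the test sensitive to group-sparse structure and
stricter than the plain ASCA SSQ test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .asca import ComponentModel, PermutationResult, fix_sign, permutation_test
from .decompose import decompose
from .exceptions import ConfigurationError, NoEffectVarianceError
from .io import DesignTable

__all__ = [
    "VariableGroups",
    "find_groups",
    "fit_gasca",
    "gasca_significance",
    "first_component_ssq",
]


@dataclass
class VariableGroups:
    """Groups of variable indices used to constrain loadings."""

    groups: list[np.ndarray]
    threshold: float | None = None
    source: str = "correlation"

    def __post_init__(self):
        if not self.groups:
            raise ConfigurationError("groups must be non-empty")
        self.groups = [np.asarray(g, dtype=int) for g in self.groups]
        for g in self.groups:
            if g.size == 0:
                raise ConfigurationError("empty variable group")


def find_groups(X, threshold: float = 0.7) -> VariableGroups:
    """Connected components of the |Pearson r| >= threshold graph.

    Constant columns have undefined correlations; they are isolated as
    singleton groups with a warning.  Deterministic: groups are ordered
    by their smallest member index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("find_groups requires a matrix with >= 2 rows")
    if not 0 < threshold <= 1:
        raise ConfigurationError("threshold must lie in (0, 1]")
    p = X.shape[1]
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s) isolated as singleton groups",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[~np.isfinite(corr)] = 0.0
    adj = np.abs(corr) >= threshold
    np.fill_diagonal(adj, False)
    adj[constant, :] = False
    adj[:, constant] = False
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [np.flatnonzero(labels == c) for c in range(n_comp)]
    groups.sort(key=lambda g: int(g[0]))
    return VariableGroups(groups=groups, threshold=threshold, source="correlation")


def _best_group_fit(effect: np.ndarray, groups: list[np.ndarray]):
    """(group index, u, s, v) of the group explaining the most SSQ."""
    singles = [i for i, g in enumerate(groups) if g.size == 1]
    multis = [i for i, g in enumerate(groups) if g.size > 1]
    best = (-1.0, None)
    if singles:
        cols = np.array([groups[i][0] for i in singles])
        col_ssq = np.sum(effect[:, cols] ** 2, axis=0)
        j = int(np.argmax(col_ssq))
        s2 = float(col_ssq[j])
        if s2 > best[0]:
            gi = singles[j]
            col = effect[:, groups[gi][0]]
            norm = np.sqrt(s2)
            u = col / norm if norm > 0 else col
            best = (s2, (gi, u, norm, np.array([1.0])))
    for gi in multis:
        sub = effect[:, groups[gi]]
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        s2 = float(s[0] ** 2)
        if s2 > best[0]:
            best = (s2, (gi, u[:, 0], float(s[0]), vt[0]))
    return best[1]


def fit_gasca(
    effect: np.ndarray, groups: VariableGroups, n_components: int = 1
) -> ComponentModel:
    """Group-wise components of an effect matrix by greedy deflation.

    Each component's loading is the leading right singular vector of the
    effect submatrix of the winning group, embedded in full space;
    explained fractions are squared singular values over the original
    effect SSQ.
    """
    effect = np.asarray(effect, dtype=float)
    total = float(np.sum(effect**2))
    if total == 0:
        raise NoEffectVarianceError("no effect variance: the effect matrix is zero")
    if n_components < 1:
        raise ConfigurationError("n_components must be >= 1")
    n, p = effect.shape
    work = effect.copy()
    loadings = np.zeros((p, n_components))
    scores = np.zeros((n, n_components))
    explained = np.zeros(n_components)
    for a in range(n_components):
        fit = _best_group_fit(work, groups.groups)
        if fit is None or fit[2] ** 2 <= total * 1e-12:
            raise ConfigurationError(
                f"only {a} non-trivial group-wise component(s) are extractable"
            )
        gi, u, s, v = fit
        loadings[groups.groups[gi], a] = v
        scores[:, a] = u * s
        explained[a] = s**2 / total
        work[:, groups.groups[gi]] -= np.outer(u * s, v)
    loadings, scores = fix_sign(loadings, scores)
    return ComponentModel(
        method="gpca", scores=scores, loadings=loadings, explained=explained
    )


def first_component_ssq(
    X,
    design: DesignTable,
    term: str,
    threshold: float = 0.7,
    groups: VariableGroups | None = None,
) -> float:
    """SSQ explained by the first group-wise component of a term's effect
    matrix; the GASCA permutation statistic.

    When ``groups`` is None they are recomputed from ``X`` (column
    correlations are invariant under row permutation, so recomputation
    inside a permutation loop reproduces the observed grouping).
    """
    X = np.asarray(X, dtype=float)
    if groups is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups = find_groups(X, threshold=threshold)
    factors = [f for f in term.split(":")] if ":" in term else [term]
    terms = factors + ([term] if ":" in term else [])
    effect = decompose(X, design, terms).effect_matrices[term]
    fit = _best_group_fit(effect, groups.groups)
    if fit is None:
        return 0.0
    return float(fit[2] ** 2)


def gasca_significance(
    X,
    design: DesignTable,
    term: str,
    threshold: float = 0.7,
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> PermutationResult:
    """Permutation test of ``term`` with the first-component GASCA SSQ."""
    return permutation_test(
        X,
        design,
        term,
        n_permutations=n_permutations,
        seed=seed,
        statistic="gasca_ssq",
        threshold=threshold,
    )
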