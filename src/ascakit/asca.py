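"""ASCA: simultaneous component analysis of effect matrices and the
shared SSQ permutation engine.

The ANOVA decomposition step (see :mod:`ascakit.decompose`) yields one
effect matrix per design term.  ``fit_sca`` extracts PCA-like components
from such an effect matrix by singular value decomposition; residuals can
be projected onto the fitted loadings to obtain "augmented" scores that
show the within-group spread around the pure effect.

``permutation_test`` assesses a term's significance: the observed
statistic (by default the effect-matrix SSQ) is compared against the
statistics of row-shuffled data, and the p-value follows the
(exceedances + 1) / (n_permutations + 1) convention, so the smallest
attainable p at 10,000 permutations is 1/10001 ~ 0.0001.  The same
engine drives the regularized-MANOVA trace and group-wise statistics via
statistic tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decompose import decompose
from .exceptions import ConfigurationError, NoEffectVarianceError
from .io import DesignTable

__all__ = [
    "ComponentModel",
    "PermutationResult",
    "fit_sca",
    "permutation_test",
    "fix_sign",
]


@dataclass
class ComponentModel:
    """Scores/loadings/explained variance of a bilinear factor model.

    ``method`` tags the origin: ``sca``, ``gpca``, ``canonical``, ``pca``
    or ``pls``.  Loadings columns have unit Euclidean norm, with the sign
    convention that each column's largest-magnitude entry is positive.
    """

    method: str
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # variables x components
    explained: np.ndarray  # fraction per component
    augmented_scores: np.ndarray | None = None


@dataclass
class PermutationResult:
    """Observed statistic, permutation null and p-value for one term."""

    term: str
    statistic_observed: float
    statistic_permuted: np.ndarray
    n_permutations: int
    p_value: float
    seed: int | None
    statistic: str = "asca_ssq"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "statistic": self.statistic,
            "statistic_observed": self.statistic_observed,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "seed": self.seed,
        }


def fix_sign(loadings: np.ndarray, *score_blocks):
    """Flip component signs so each loading column's largest-|.| entry is
    positive; score columns are flipped consistently.  Returns the flipped
    (loadings, *score_blocks)."""
    loadings = loadings.copy()
    blocks = [b.copy() if b is not None else None for b in score_blocks]
    for a in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            for b in blocks:
                if b is not None:
                    b[:, a] *= -1
    return (loadings, *blocks)


def fit_sca(
    effect: np.ndarray,
    residuals: np.ndarray | None = None,
    n_components: int | None = None,
) -> ComponentModel:
    """SCA of an effect matrix via singular value decomposition.

    ``explained`` holds squared singular values over the effect SSQ.  If
    ``residuals`` is given, ``augmented_scores`` projects effect plus
    residuals onto the fitted loadings (no refit).
    """
    effect = np.asarray(effect, dtype=float)
    total = float(np.sum(effect**2))
    if total == 0:
        raise NoEffectVarianceError("no effect variance: the effect matrix is zero")
    u, s, vt = np.linalg.svd(effect, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12))
    if n_components is None:
        n_components = rank
    if not 1 <= n_components <= rank:
        raise ConfigurationError(
            f"n_components must be between 1 and rank {rank}, got {n_components}"
        )
    k = n_components
    loadings = vt[:k].T
    scores = u[:, :k] * s[:k]
    explained = (s[:k] ** 2) / total
    augmented = None
    if residuals is not None:
        augmented = (effect + np.asarray(residuals, dtype=float)) @ loadings
    loadings, scores, augmented = fix_sign(loadings, scores, augmented)
    return ComponentModel(
        method="sca",
        scores=scores,
        loadings=loadings,
        explained=explained,
        augmented_scores=augmented,
    )


# ---------------------------------------------------------------------------
# Permutation engine
# ---------------------------------------------------------------------------

def _stat_asca_ssq(X, design, term):
    factors = sorted({f for f in term.split(":")}) if ":" in term else [term]
    terms = factors + ([term] if ":" in term else [])
    return decompose(X, design, terms).ssq[term]


def _stat_rmanova_trace(X, design, term, delta="auto"):
    from .rmanova import trace_statistic

    return trace_statistic(X, design, term, delta=delta)


def _stat_gasca_ssq(X, design, term, threshold=0.7, groups=None):
    from .gasca import first_component_ssq

    return first_component_ssq(X, design, term, threshold=threshold, groups=groups)


_STATISTICS = {
    "asca_ssq": _stat_asca_ssq,
    "rmanova_trace": _stat_rmanova_trace,
    "gasca_ssq": _stat_gasca_ssq,
}


def _multiset_permutations(labels):
    """All distinct orderings of ``labels`` (lexicographic)."""
    labels = sorted(labels)
    n = len(labels)
    while True:
        yield tuple(labels)
        i = n - 2
        while i >= 0 and labels[i] >= labels[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while labels[j] <= labels[i]:
            j -= 1
        labels[i], labels[j] = labels[j], labels[i]
        labels[i + 1 :] = labels[: i : -1]


def permutation_test(
    X,
    design: DesignTable,
    term: str,
    n_permutations: int = 10_000,
    seed: int | None = 0,
    statistic="asca_ssq",
    method: str = "random",
    **statistic_kwargs,
) -> PermutationResult:
    """SSQ-style permutation test of a design term.

    Parameters
    ----------
    statistic : one of ``"asca_ssq"``, ``"rmanova_trace"``, ``"gasca_ssq"``
        or a callable ``f(X, design, term, **kwargs) -> float``.
    method : ``"random"`` shuffles the rows of ``X`` uniformly at random
        ``n_permutations`` times; ``"exhaustive"`` (single-factor designs)
        enumerates every distinct reassignment of the level labels except
        the observed one, giving the exact enumeration p-value.

    The p-value is ``(larger + 1) / (n_permutations + 1)`` where
    ``larger`` counts permuted statistics strictly greater than the
    observed one (numerically tied values, e.g. from permutations that
    reproduce the observed grouping, are not counted as larger; a 1e-9
    relative tolerance absorbs floating-point noise).  p is never zero
    and is floored at 1/(n_permutations + 1).
    """
    X = np.asarray(X, dtype=float)
    if method not in ("random", "exhaustive"):
        raise ConfigurationError(f"unknown permutation method {method!r}")
    if method == "random" and n_permutations < 1:
        raise ConfigurationError("n_permutations must be >= 1")
    stat = _STATISTICS[statistic] if isinstance(statistic, str) else statistic
    tag = statistic if isinstance(statistic, str) else getattr(
        statistic, "__name__", "custom"
    )

    observed = float(stat(X, design, term, **statistic_kwargs))
    permuted: list[float] = []
    if method == "random":
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            permuted.append(float(stat(X[perm], design, term, **statistic_kwargs)))
    else:
        if ":" in term or term not in design.factors:
            raise ConfigurationError(
                "exhaustive enumeration is limited to single factors"
            )
        labels = list(design.factors[term])
        for ordering in _multiset_permutations(labels):
            if list(ordering) == labels:
                continue
            permuted.append(
                float(
                    stat(
                        X,
                        design.replace_factor(term, ordering),
                        term,
                        **statistic_kwargs,
                    )
                )
            )
        n_permutations = len(permuted)
        if n_permutations < 1:
            raise ConfigurationError("design admits no non-identity relabeling")

    permuted_arr = np.array(permuted)
    tol = 1e-9 * abs(observed)
    exceed = int(np.sum(permuted_arr > observed + tol))
    p_value = (exceed + 1) / (n_permutations + 1)
    return PermutationResult(
        term=term,
        statistic_observed=observed,
        statistic_permuted=permuted_arr,
        n_permutations=n_permutations,
        p_value=p_value,
        seed=seed if method == "random" else None,
        statistic=tag,
        extra=dict(statistic_kwargs),
    )
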