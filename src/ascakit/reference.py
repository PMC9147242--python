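"""Reference/baseline methods: PCA, PLS-DA (VIP, selectivity ratio,
stability replicates) and univariate tests with Benjamini-Hochberg FDR.

These are the comparison baselines against which the ANOVA-based methods
are judged.  The PLS implementation is a NIPALS-style PLS2 with explicit
X/Y deflation; VIP scores follow the standard weighted-sum-of-squared-
weights definition (so the squared VIPs average to exactly 1), and the
selectivity ratio is the per-variable explained-to-residual variance
ratio along the target-projection of the regression vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .asca import ComponentModel, fix_sign
from .exceptions import ConfigurationError, DesignError
from .io import DesignTable, autoscale, center

__all__ = [
    "PlsModel",
    "SelectionResult",
    "fit_pca",
    "fit_plsda",
    "vip_scores",
    "selectivity_ratio",
    "stability_replicates",
    "univariate_tests",
    "bh_adjust",
]

#: Cap applied to selectivity ratios with numerically zero residuals.
SR_CAP = 1e12


@dataclass
class PlsModel:
    """A fitted PLS2 discriminant model.

    ``weights`` (p x A) are unit-norm; ``x_loadings`` (p x A),
    ``y_loadings`` (q x A) and ``scores`` (n x A) come from NIPALS
    deflation.  ``class_encoding`` maps each class level to its indicator
    column (two classes share a single 0/1 column).
    """

    n_latent: int
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    class_encoding: dict[str, int]
    classes: list[str]
    explained_y: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    ssy_per_lv: np.ndarray = field(default=None)

    @property
    def n_variables(self) -> int:
        return self.weights.shape[0]

    def regression_vector(self) -> np.ndarray:
        """B = W (P'W)^-1 Q' mapped to a single direction.

        For a one-column response this is the usual regression vector;
        for multi-class models the dominant y-space direction of B is
        used (leading right singular vector).
        """
        B = self.weights @ np.linalg.solve(
            self.x_loadings.T @ self.weights, self.y_loadings.T
        )
        if B.shape[1] == 1:
            return B[:, 0]
        _, _, vt = np.linalg.svd(B, full_matrices=False)
        return B @ vt[0]

    def predict(self, X) -> np.ndarray:
        """Predicted (continuous) class indicators for rows of ``X``."""
        B = self.weights @ np.linalg.solve(
            self.x_loadings.T @ self.weights, self.y_loadings.T
        )
        return (np.asarray(X, dtype=float) - self.x_mean) @ B + self.y_mean

    def predict_classes(self, X) -> list[str]:
        yhat = self.predict(X)
        if yhat.shape[1] == 1:
            return [self.classes[int(v >= 0.5)] for v in yhat[:, 0]]
        return [self.classes[int(i)] for i in np.argmax(yhat, axis=1)]


@dataclass
class SelectionResult:
    """A ranked variable-relevance result with its top-k set."""

    method: str
    ranking: list[str]  # variable ids, decreasing relevance
    scores: dict[str, float]
    top_k: set[str]
    k: int


def fit_pca(X, scaling: str = "center", n_components: int | None = None) -> ComponentModel:
    """PCA after mean-centering (``scaling="center"``) or autoscaling."""
    if scaling == "center":
        Xs = center(X)
    elif scaling == "autoscale":
        Xs = autoscale(X)
    else:
        raise ConfigurationError(f"scaling must be 'center' or 'autoscale', got {scaling!r}")
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ConfigurationError("PCA of an all-zero centered matrix")
    rank = int(np.sum(s > s[0] * 1e-12))
    k = rank if n_components is None else n_components
    if not 1 <= k <= rank:
        raise ConfigurationError(f"n_components must be between 1 and rank {rank}")
    loadings = vt[:k].T
    scores = u[:, :k] * s[:k]
    loadings, scores = fix_sign(loadings, scores)
    return ComponentModel(
        method="pca", scores=scores, loadings=loadings, explained=(s[:k] ** 2) / total
    )


def _encode_classes(classes) -> tuple[np.ndarray, list[str], dict[str, int]]:
    labels = [str(c) for c in classes]
    levels: list[str] = []
    for l in labels:
        if l not in levels:
            levels.append(l)
    if not 2 <= len(levels) <= 3:
        raise DesignError(f"PLS-DA requires 2 or 3 classes, got {len(levels)}")
    counts = {l: labels.count(l) for l in levels}
    small = [l for l, c in counts.items() if c < 2]
    if small:
        raise DesignError(f"class {small[0]!r} has fewer than 2 samples")
    if len(levels) == 2:
        # first class -> 0, second -> 1, single indicator column
        y = np.array([[float(l == levels[1])] for l in labels])
        encoding = {levels[0]: 0, levels[1]: 0}
    else:
        y = np.array([[float(l == lev) for lev in levels] for l in labels])
        encoding = {lev: j for j, lev in enumerate(levels)}
    return y, levels, encoding


def fit_plsda(X, classes, n_latent: int = 2) -> PlsModel:
    """NIPALS PLS2 regression of ``X`` on class indicators.

    ``X`` should already be scaled as desired (mean-centered TICs,
    autoscaled features); both ``X`` and the indicator matrix are
    mean-centered internally.  Deterministic: weights are leading
    singular vectors of the X'Y cross-product at each deflation step.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ConfigurationError("X must be a 2-D matrix")
    Y, levels, encoding = _encode_classes(classes)
    if len(classes) != X.shape[0]:
        raise DesignError("one class label per sample row is required")
    if n_latent < 1:
        raise ConfigurationError("n_latent must be >= 1")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    E = X - x_mean
    F = Y - y_mean
    ssy_total = float(np.sum(F**2))
    p, q = X.shape[1], Y.shape[1]
    W = np.zeros((p, n_latent))
    P = np.zeros((p, n_latent))
    Q = np.zeros((q, n_latent))
    T = np.zeros((X.shape[0], n_latent))
    ssy = np.zeros(n_latent)
    for a in range(n_latent):
        C = E.T @ F  # p x q
        if q == 1:
            w = C[:, 0]
        else:
            u_, s_, vt_ = np.linalg.svd(C, full_matrices=False)
            w = u_[:, 0]
        norm = np.linalg.norm(w)
        if norm <= 0:
            raise ConfigurationError(
                f"no residual X/Y covariance left at latent variable {a + 1}"
            )
        w = w / norm
        t = E @ w
        tt = float(t @ t)
        if tt <= 0:
            raise ConfigurationError(
                f"degenerate score vector at latent variable {a + 1}"
            )
        p_a = E.T @ t / tt
        q_a = F.T @ t / tt
        E = E - np.outer(t, p_a)
        F = F - np.outer(t, q_a)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q_a, t
        ssy[a] = tt * float(q_a @ q_a)
    explained_y = ssy / ssy_total if ssy_total > 0 else np.zeros(n_latent)
    return PlsModel(
        n_latent=n_latent,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        class_encoding=encoding,
        classes=levels,
        explained_y=explained_y,
        x_mean=x_mean,
        y_mean=y_mean,
        ssy_per_lv=ssy,
    )


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable Influence on Projection scores.

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ) with unit-norm
    weight columns, so the squared VIPs average to exactly one.
    """
    W = model.weights
    ssy = model.ssy_per_lv
    denom = float(ssy.sum())
    if denom <= 0:
        return np.zeros(W.shape[0])
    p = W.shape[0]
    w2 = W**2 / np.sum(W**2, axis=0, keepdims=True)
    return np.sqrt(p * (w2 @ ssy) / denom)


def selectivity_ratio(model: PlsModel, X) -> np.ndarray:
    """Per-variable explained/residual variance ratio along the target
    projection of the regression vector.

    ``X`` must be the matrix the model was fitted on (same scaling).
    Ratios with numerically zero residual variance are capped at
    ``SR_CAP``.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - model.x_mean
    b = model.regression_vector()
    nb = np.linalg.norm(b)
    if nb == 0:
        return np.zeros(X.shape[1])
    t = Xc @ (b / nb)
    tt = float(t @ t)
    if tt == 0:
        return np.zeros(X.shape[1])
    p_tp = Xc.T @ t / tt
    explained = np.outer(t, p_tp)
    residual = Xc - explained
    num = np.sum(explained**2, axis=0)
    den = np.sum(residual**2, axis=0)
    out = np.empty_like(num)
    tiny = den <= num / SR_CAP
    out[tiny] = np.where(num[tiny] > 0, SR_CAP, 0.0)
    nz = ~tiny
    out[nz] = num[nz] / den[nz]
    return out


def stability_replicates(
    X,
    classes,
    n_models: int = 1000,
    removal_range: tuple[float, float] = (0.01, 0.10),
    selector: str = "vip",
    k: int = 50,
    n_latent: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Selection frequency per variable over replicate PLS-DA models.

    Each replicate removes a uniform-random fraction of variables in
    ``removal_range``, refits, and records membership of the replicate's
    selection: top-``k`` by VIP (``selector="vip"``) or selectivity ratio
    (``"sr"``), or the conventional VIP > 1 rule (``"vip_gt1"``).
    Removed variables cannot be selected in that replicate.
    """
    X = np.asarray(X, dtype=float)
    lo, hi = removal_range
    if not (0 <= lo <= hi < 1):
        raise ConfigurationError("removal_range must satisfy 0 <= lo <= hi < 1")
    if n_models < 1:
        raise ConfigurationError("n_models must be >= 1")
    if selector not in ("vip", "sr", "vip_gt1"):
        raise ConfigurationError(f"unknown selector {selector!r}")
    p = X.shape[1]
    rng = np.random.default_rng(seed)
    counts = np.zeros(p)
    for _ in range(n_models):
        frac = rng.uniform(lo, hi)
        n_remove = min(max(int(round(frac * p)), 1), p - 2)
        removed = rng.choice(p, size=n_remove, replace=False)
        keep = np.setdiff1d(np.arange(p), removed)
        sub = fit_plsda(X[:, keep], classes, n_latent=n_latent)
        score = vip_scores(sub) if selector != "sr" else selectivity_ratio(sub, X[:, keep])
        if selector == "vip_gt1":
            chosen = keep[score > 1.0]
        else:
            order = np.lexsort((np.arange(len(keep)), -score))
            chosen = keep[order[: min(k, len(keep))]]
        counts[chosen] += 1
    return counts / n_models


def univariate_tests(X, design: DesignTable, term: str) -> np.ndarray:
    """Per-variable raw p-values for a factor.

    Two levels: two-sided equal-variance t-test; three levels: one-way
    ANOVA F-test.  Variables constant within every group yield p = 1
    (degenerate convention, warned about).  Any level with fewer than two
    samples is an error.
    """
    X = np.asarray(X, dtype=float)
    codes = design.codes(term)
    levels = design.levels(term)
    groups = [X[codes == g] for g in range(len(levels))]
    if any(len(g) < 2 for g in groups):
        raise DesignError(f"every level of {term!r} needs >= 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        if len(levels) == 2:
            res = stats.ttest_ind(groups[0], groups[1], axis=0, equal_var=True)
        elif len(levels) == 3:
            res = stats.f_oneway(*groups, axis=0)
        else:
            raise DesignError("univariate tests support 2 or 3 levels")
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} variable(s) constant within all groups; "
            "their p-value is set to 1",
            stacklevel=2,
        )
        p[degenerate] = 1.0
    return np.clip(p, np.nextafter(0, 1), 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; order-preserving in
    the input p-values.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ConfigurationError("p must be a 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
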