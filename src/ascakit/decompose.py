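"""ANOVA decomposition of a data matrix by experimental design.

``decompose`` splits a samples x variables matrix into a grand-mean term,
one effect matrix per design factor (replicated level-mean deviations),
an optional two-factor interaction and a residual matrix, together with
the sum of squared elements (SSQ) of each part.  For balanced designs the
non-mean SSQs add up to the SSQ of the centered matrix; this additivity
is what makes the SSQ a meaningful per-factor variance share and the
natural permutation statistic.

Unbalanced designs are supported for single-factor models only; for
multi-factor models use :func:`balance_by_removal` first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import DesignError, UnbalancedDesignError
from .io import DesignTable, FeatureTable

__all__ = ["EffectDecomposition", "decompose", "balance_by_removal", "BalanceResult"]

_TOL = 1e-9


@dataclass
class EffectDecomposition:
    """Effect matrices, residuals and sums of squares of one model fit."""

    terms: list[str]  # includes "mean" first
    effect_matrices: dict[str, np.ndarray]
    residuals: np.ndarray
    ssq: dict[str, float]  # non-mean terms
    ssq_residual: float
    ssq_centered: float
    percent_variance: dict[str, float]
    balanced: bool
    residual_df: int
    n_levels: dict[str, int]

    def reconstruct_centered(self) -> np.ndarray:
        """Sum of non-mean effect matrices plus residuals."""
        out = self.residuals.copy()
        for term in self.terms:
            if term != "mean":
                out = out + self.effect_matrices[term]
        return out

    def export(self, directory) -> None:
        """One CSV per term plus a JSON SSQ summary."""
        import json
        from pathlib import Path

        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for term, mat in self.effect_matrices.items():
            pd.DataFrame(mat).to_csv(
                directory / f"effect_{term.replace(':', 'x')}.csv", index=False
            )
        pd.DataFrame(self.residuals).to_csv(directory / "residuals.csv", index=False)
        summary = {
            "ssq": self.ssq,
            "ssq_residual": self.ssq_residual,
            "ssq_centered": self.ssq_centered,
            "percent_variance": self.percent_variance,
            "balanced": self.balanced,
            "residual_df": self.residual_df,
        }
        with open(directory / "ssq_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)


def _parse_terms(terms, design: DesignTable):
    factors, interactions = [], []
    for t in terms:
        if ":" in t:
            interactions.append(t)
        else:
            factors.append(t)
    if len(interactions) > 1:
        raise DesignError("at most one two-factor interaction is supported")
    for f in factors:
        if f not in design.factors:
            raise DesignError(f"unknown factor {f!r}")
    for t in interactions:
        parts = t.split(":")
        if len(parts) != 2:
            raise DesignError(f"interaction term {t!r} must name two factors")
        for f in parts:
            if f not in factors:
                raise DesignError(
                    f"interaction {t!r} requires both main effects in terms"
                )
    return factors, interactions


def _level_means(X, codes, n_levels):
    """Per-level column means and level counts."""
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    if np.any(counts == 0):
        raise DesignError("design contains an empty level")
    sums = np.zeros((n_levels, X.shape[1]))
    np.add.at(sums, codes, X)
    return sums / counts[:, None], counts


def decompose(X, design: DesignTable, terms) -> EffectDecomposition:
    """ANOVA-decompose ``X`` according to ``design``.

    Parameters
    ----------
    X : (n, p) matrix, rows aligned with ``design.sample_ids``.
    design : the design table.
    terms : factor names, optionally plus one interaction ``"f1:f2"``.

    The grand mean is removed first; each factor's effect row is the
    level mean minus the grand mean, the interaction row is the cell mean
    minus both level means plus the grand mean, and residuals are the
    remainder.  ``ssq`` holds the sum of squared elements per matrix.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DesignError("X must be a 2-D matrix")
    n, p = X.shape
    if n != design.n_samples:
        raise DesignError(
            f"X has {n} rows but the design describes {design.n_samples} samples"
        )
    factors, interactions = _parse_terms(terms, design)
    if not factors:
        raise DesignError("at least one factor term is required")

    codes = {f: design.codes(f) for f in factors}
    n_levels = {f: len(design.levels(f)) for f in factors}
    for f in factors:
        if n_levels[f] < 2:
            raise DesignError(f"factor {f!r} has a single level")

    # Balance check over the cells of the crossed factors.
    cell_codes = np.zeros(n, dtype=int)
    n_cells = 1
    for f in factors:
        cell_codes = cell_codes * n_levels[f] + codes[f]
        n_cells *= n_levels[f]
    cell_counts = np.bincount(cell_codes, minlength=n_cells)
    balanced = bool(np.all(cell_counts == cell_counts[0]) and cell_counts[0] > 0)
    if len(factors) >= 2 and not balanced:
        raise UnbalancedDesignError(
            "multi-factor decomposition requires a balanced design; "
            "consider balance_by_removal()"
        )
    if interactions and np.any(cell_counts == 0):
        raise DesignError("empty design cell: interaction is not estimable")

    grand = X.mean(axis=0)
    Xc = X - grand
    effect_matrices: dict[str, np.ndarray] = {"mean": np.tile(grand, (n, 1))}
    level_mean_cache = {}
    for f in factors:
        means, _ = _level_means(X, codes[f], n_levels[f])
        level_mean_cache[f] = means
        effect_matrices[f] = means[codes[f]] - grand
    for t in interactions:
        f1, f2 = t.split(":")
        cmeans, _ = _level_means(X, cell_codes, n_cells)
        cell_effect = cmeans[cell_codes]
        effect_matrices[t] = (
            cell_effect
            - level_mean_cache[f1][codes[f1]]
            - level_mean_cache[f2][codes[f2]]
            + grand
        )

    residuals = Xc.copy()
    for term in factors + interactions:
        residuals -= effect_matrices[term]

    ssq = {t: float(np.sum(effect_matrices[t] ** 2)) for t in factors + interactions}
    ssq_residual = float(np.sum(residuals**2))
    ssq_centered = float(np.sum(Xc**2))
    denom = ssq_centered if ssq_centered > 0 else 1.0
    percent = {t: 100.0 * v / denom for t, v in ssq.items()}
    percent["residual"] = 100.0 * ssq_residual / denom

    model_df = sum(n_levels[f] - 1 for f in factors)
    if interactions:
        f1, f2 = interactions[0].split(":")
        model_df += (n_levels[f1] - 1) * (n_levels[f2] - 1)
    return EffectDecomposition(
        terms=["mean"] + factors + interactions,
        effect_matrices=effect_matrices,
        residuals=residuals,
        ssq=ssq,
        ssq_residual=ssq_residual,
        ssq_centered=ssq_centered,
        percent_variance=percent,
        balanced=balanced,
        residual_df=n - 1 - model_df,
        n_levels=n_levels,
    )


class BalanceResult(NamedTuple):
    features: FeatureTable
    design: DesignTable
    removed_ids: list[str]


def balance_by_removal(
    table: FeatureTable, design: DesignTable, factor: str, seed: int = 0
) -> BalanceResult:
    """Randomly remove samples from over-represented levels of ``factor``
    until all levels hold the minimum level count.

    Deterministic for a fixed seed; the removed sample ids are reported.
    A level with zero samples is an error.
    """
    aligned = design.aligned_to(table)
    codes = aligned.codes(factor)
    levels = aligned.levels(factor)
    counts = np.bincount(codes, minlength=len(levels))
    if np.any(counts == 0):
        raise DesignError(f"factor {factor!r} has a level with zero samples")
    target = int(counts.min())
    rng = np.random.default_rng(seed)
    removed: list[str] = []
    keep = np.ones(len(codes), dtype=bool)
    for g, count in enumerate(counts):
        if count > target:
            members = np.flatnonzero(codes == g)
            drop = rng.choice(members, size=count - target, replace=False)
            keep[drop] = False
            removed.extend(table.sample_ids[i] for i in sorted(drop))
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    new_table = FeatureTable(
        sample_ids=kept_ids,
        variable_ids=list(table.variable_ids),
        values=table.values[keep],
        variable_kind=table.variable_kind,
        is_internal_standard=table.is_internal_standard.copy(),
    )
    return BalanceResult(new_table, aligned.subset(kept_ids), removed)
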