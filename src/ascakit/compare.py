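"""Concordance analysis across variable-selection methods and the
end-to-end workflow.

Each method contributes a per-variable relevance profile: ANOVA-based
methods the absolute first-component loading (SCA for ASCA, canonical
for rMANOVA, group-wise for GASCA), PLS-DA the VIP or selectivity-ratio
score, univariate testing 1 - adjusted p.  The module selects the top-k
variables per method (default k = 50), partitions their union into Venn
regions, correlates the profiles pairwise and counts coincidences with a
reference method (PLS-DA VIP by default).

``run_workflow`` wires the whole pipeline together from a YAML/JSON
config: load or synthesize data -> normalize -> scale -> decompose ->
{ASCA, rMANOVA, GASCA, PLS-DA, univariate} -> concordance report, with a
deterministic JSON report and CSV tables as output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference
from .asca import fit_sca, permutation_test
from .decompose import decompose
from .exceptions import ConfigurationError
from .gasca import find_groups, fit_gasca, gasca_significance
from .io import (
    DesignTable,
    FeatureTable,
    autoscale,
    center,
    normalize,
    read_design,
    read_feature_table,
)
from .reference import SelectionResult, bh_adjust, fit_plsda
from .rmanova import fit_rmanova, rmanova_significance
from .synthetic import _config_from_dict, generate_feature_dataset

__all__ = [
    "ComparisonReport",
    "select_top_k",
    "venn_partition",
    "profile_correlation",
    "coincidence_with_reference",
    "run_workflow",
]

#: Methods whose profiles are signed loadings (compared in absolute value).
LOADING_METHODS = {"asca", "rmanova", "gasca", "pca"}


@dataclass
class ComparisonReport:
    """Concordance summary across methods."""

    methods: list[str]
    k: int
    reference: str
    top_k_sets: dict[str, set[str]]
    venn_partition: dict[frozenset, int]
    profile_correlations: pd.DataFrame
    coincidence_with_reference: dict[str, int]


def select_top_k(scores, variable_ids, method: str, k: int = 50) -> SelectionResult:
    """Rank variables and keep the top k.

    Loading-type methods (``asca``, ``rmanova``, ``gasca``, ``pca``) are
    ranked by absolute value; VIP/SR/frequency profiles by raw value.
    Ties are broken by ascending variable index, so the result is
    deterministic.  If k exceeds the number of variables the whole set is
    returned with a warning.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    scores = np.asarray(scores, dtype=float)
    variable_ids = [str(v) for v in variable_ids]
    if len(scores) != len(variable_ids):
        raise ConfigurationError("one score per variable id is required")
    key = np.abs(scores) if method in LOADING_METHODS else scores
    order = np.lexsort((np.arange(len(key)), -key))
    if k > len(variable_ids):
        warnings.warn(
            f"k={k} exceeds the {len(variable_ids)} available variables",
            stacklevel=2,
        )
    kk = min(k, len(variable_ids))
    ranking = [variable_ids[i] for i in order]
    return SelectionResult(
        method=method,
        ranking=ranking,
        scores={variable_ids[i]: float(key[i]) for i in range(len(key))},
        top_k=set(ranking[:kk]),
        k=kk,
    )


def venn_partition(sets: dict[str, set]) -> dict[frozenset, int]:
    """Exact element counts of every non-empty region signature.

    Returns a map from ``frozenset(method names)`` (the methods that
    contain the region's elements) to the region's element count; counts
    over all 2^m - 1 signatures sum to the size of the union.
    """
    names = list(sets)
    if not 2 <= len(names) <= 5:
        raise ConfigurationError("venn_partition supports 2-5 sets")
    regions = {
        frozenset(c): 0
        for r in range(1, len(names) + 1)
        for c in combinations(names, r)
    }
    for element in set().union(*sets.values()):
        signature = frozenset(n for n in names if element in sets[n])
        regions[signature] += 1
    return regions


def profile_correlation(profiles: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson correlation of equal-length method profiles.

    Zero-variance profiles produce NaN entries with a warning.  Signed
    loading profiles should be passed in absolute value (the workflow
    does this) so they are comparable with the non-negative VIP/SR
    profiles.
    """
    names = list(profiles)
    vectors = [np.asarray(profiles[n], dtype=float) for n in names]
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ConfigurationError("profiles must have equal length")
    mat = np.eye(len(names))
    for i, j in combinations(range(len(names)), 2):
        a, b = vectors[i], vectors[j]
        if a.std() == 0 or b.std() == 0:
            warnings.warn(
                f"zero-variance profile in pair ({names[i]}, {names[j]})",
                stacklevel=2,
            )
            r = np.nan
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)


def coincidence_with_reference(
    top_k_sets: dict[str, set], reference_tag: str = "plsda_vip"
) -> dict[str, int]:
    """|top_k(method) & top_k(reference)| for every non-reference method."""
    if reference_tag not in top_k_sets:
        raise ConfigurationError(f"reference method {reference_tag!r} missing")
    ref = top_k_sets[reference_tag]
    return {
        m: len(s & ref) for m, s in top_k_sets.items() if m != reference_tag
    }


# ---------------------------------------------------------------------------
# End-to-end workflow
# ---------------------------------------------------------------------------

_DEFAULT_METHODS = ["asca", "rmanova", "gasca", "plsda_vip", "plsda_sr", "univariate"]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping or a path to one")
    return config


def _load_data(cfg) -> tuple[FeatureTable, DesignTable]:
    if "synthetic" in cfg:
        dataset = generate_feature_dataset(_config_from_dict(cfg["synthetic"]))
        return dataset.features, dataset.design
    if "inputs" not in cfg:
        raise ConfigurationError("config needs either 'synthetic' or 'inputs'")
    inputs = cfg["inputs"]
    table = read_feature_table(inputs["features"])
    design = read_design(inputs["design"])
    return table, design


def _scaled_matrix(table: FeatureTable, scaling: str) -> np.ndarray:
    if scaling == "center":
        return center(table.values)
    if scaling == "autoscale":
        return autoscale(table.values)
    raise ConfigurationError(f"scaling must be 'center' or 'autoscale', got {scaling!r}")


def run_workflow(config, output_dir=None) -> dict:
    """Execute the full analysis pipeline described by ``config``.

    Config keys: ``factor`` (required), ``synthetic`` or ``inputs``
    (features/design CSV paths), ``scaling`` (center|autoscale, default
    autoscale), ``normalize`` (default: on when IS channels exist),
    ``methods`` (default all), ``k`` (default 50), ``n_permutations``
    (default 10000), ``n_latent`` (default 2), ``gasca_threshold``
    (default 0.7), ``delta`` (default "auto"), ``seed``, ``output_dir``.

    Returns the report dict; when an output directory is configured the
    report (JSON), rankings/scores/loadings (CSV) and a parameter log are
    written there.  The report is byte-reproducible for a fixed config.
    """
    cfg = _load_config(config)
    if "factor" not in cfg:
        raise ConfigurationError("config is missing the required key 'factor'")
    factor = cfg["factor"]
    k = int(cfg.get("k", 50))
    seed = int(cfg.get("seed", 0))
    n_perm = int(cfg.get("n_permutations", 10_000))
    n_latent = int(cfg.get("n_latent", 2))
    threshold = float(cfg.get("gasca_threshold", 0.7))
    delta = cfg.get("delta", "auto")
    methods = list(cfg.get("methods", _DEFAULT_METHODS))
    scaling = cfg.get("scaling", "autoscale")
    output_dir = output_dir or cfg.get("output_dir")

    table, design = _load_data(cfg)
    design = design.aligned_to(table)
    if factor not in design.factors:
        raise ConfigurationError(f"factor {factor!r} not present in the design")

    do_normalize = cfg.get("normalize", bool(table.is_internal_standard.any()))
    if do_normalize:
        table = normalize(table, design)
    analysis = table.drop_internal_standards()
    X = _scaled_matrix(analysis, scaling)
    var_ids = analysis.variable_ids
    classes = design.factors[factor]

    dec = decompose(X, design, [factor])
    p_values: dict[str, float] = {}
    profiles: dict[str, np.ndarray] = {}
    selections: dict[str, SelectionResult] = {}
    extras: dict = {}
    pls_model = None

    for method in methods:
        if method == "asca":
            sca = fit_sca(dec.effect_matrices[factor], dec.residuals, n_components=1)
            profiles[method] = sca.loadings[:, 0]
            extras["asca_scores"] = sca.scores[:, 0]
            extras["asca_augmented_scores"] = sca.augmented_scores[:, 0]
            p_values[method] = permutation_test(
                X, design, factor, n_permutations=n_perm, seed=seed
            ).p_value
        elif method == "rmanova":
            model = fit_rmanova(X, design, factor, delta=delta, n_components=1)
            profiles[method] = model.canonical.loadings[:, 0]
            extras["rmanova_delta"] = model.delta
            extras["rmanova_scores"] = model.canonical.scores[:, 0]
            p_values[method] = rmanova_significance(
                X, design, factor, delta=delta, n_permutations=n_perm, seed=seed
            ).p_value
        elif method == "gasca":
            groups = find_groups(X, threshold=threshold)
            gpca = fit_gasca(dec.effect_matrices[factor], groups, n_components=1)
            profiles[method] = gpca.loadings[:, 0]
            extras["gasca_n_groups"] = len(groups.groups)
            extras["gasca_scores"] = gpca.scores[:, 0]
            p_values[method] = gasca_significance(
                X, design, factor, threshold=threshold,
                n_permutations=n_perm, seed=seed,
            ).p_value
        elif method in ("plsda_vip", "plsda_sr"):
            if pls_model is None:
                pls_model = fit_plsda(X, classes, n_latent=n_latent)
            if method == "plsda_vip":
                profiles[method] = reference.vip_scores(pls_model)
            else:
                profiles[method] = reference.selectivity_ratio(pls_model, X)
        elif method == "univariate":
            raw = reference.univariate_tests(X, design, factor)
            adjusted = bh_adjust(raw)
            profiles[method] = 1.0 - adjusted
            extras["univariate_n_significant"] = int(np.sum(adjusted < 0.05))
        else:
            raise ConfigurationError(f"unknown method {method!r}")
        tag = method if method not in LOADING_METHODS else method
        selections[method] = select_top_k(profiles[method], var_ids, tag, k=k)

    top_k_sets = {m: s.top_k for m, s in selections.items()}
    # the Venn comparison covers the multivariate selections (max 5 sets);
    # univariate stays in the correlation/coincidence summaries
    venn_sets = dict(top_k_sets)
    if len(venn_sets) > 5:
        venn_sets.pop("univariate", None)
    venn = venn_partition(venn_sets) if 2 <= len(venn_sets) <= 5 else {}
    corr_profiles = {
        m: (np.abs(v) if m in LOADING_METHODS else v) for m, v in profiles.items()
    }
    correlations = (
        profile_correlation(corr_profiles) if len(corr_profiles) >= 2 else None
    )
    ref_tag = cfg.get("reference", "plsda_vip")
    coincidence = (
        coincidence_with_reference(top_k_sets, ref_tag)
        if ref_tag in top_k_sets
        else {}
    )

    report = {
        "factor": factor,
        "k": k,
        "seed": seed,
        "n_permutations": n_perm,
        "scaling": scaling,
        "reference": ref_tag,
        "methods": methods,
        "p_values": p_values,
        "top_k_sets": {m: sorted(s) for m, s in top_k_sets.items()},
        "venn": {"+".join(sorted(sig)): n for sig, n in venn.items()},
        "profile_correlations": (
            {
                a: {b: (None if np.isnan(correlations.loc[a, b]) else float(correlations.loc[a, b]))
                    for b in correlations.columns}
                for a in correlations.index
            }
            if correlations is not None
            else {}
        ),
        "coincidence_with_reference": coincidence,
        "extras": {
            key: (
                float(value)
                if isinstance(value, (float, np.floating))
                else int(value)
                if isinstance(value, (int, np.integer))
                else None
            )
            for key, value in extras.items()
        },
    }

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        for m, sel in selections.items():
            pd.DataFrame(
                {
                    "variable_id": sel.ranking,
                    "score": [sel.scores[v] for v in sel.ranking],
                    "selected": [v in sel.top_k for v in sel.ranking],
                }
            ).to_csv(out / f"ranking_{m}.csv", index=False)
        for key, value in extras.items():
            if isinstance(value, np.ndarray):
                pd.DataFrame({key: value}, index=design.sample_ids).to_csv(
                    out / f"{key}.csv", index_label="sample_id"
                )
        with open(out / "log.txt", "w", encoding="utf-8") as fh:
            fh.write("ascakit workflow\n")
            for key in ("factor", "k", "seed", "n_permutations", "scaling"):
                fh.write(f"{key} = {report[key]}\n")
            fh.write(f"methods = {','.join(methods)}\n")
    return report
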