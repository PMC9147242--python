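"""Synthetic designed-metabolomics data with known ground truth.

Feature matrices mimic the p >> n structure typical of LC-MS studies:
log-normal baseline intensities, a sparse set of marker variables with
level-ordered group offsets on the log scale, correlated variable blocks,
zero inflation, internal-standard channels and a per-sample multiplicative
drift shared by all variables (so that internal-standard normalization
undoes it exactly).  A TIC generator builds chromatogram-like rows from
Gaussian peaks, and a centroid-scan generator emits (scan, rt, m/z,
intensity) records for the simplified ROI stage.

All generators are deterministic for a fixed seed; per-stage substreams
are derived from the configured seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .io import SCAN_COLUMNS, DesignTable, FeatureTable

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_feature_dataset",
    "generate_tic_dataset",
    "generate_centroid_scans",
    "write_truth",
]

#: Name of the single design factor produced by the generators.
FACTOR = "group"


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of a synthetic designed dataset.

    ``effect_size`` is the planted group-mean shift in within-group
    standard-deviation units (on the log-intensity scale for feature
    matrices).  With three group levels the shifts are monotone in level
    order: 0, +e, +2e.  ``block_spec`` plants correlated variable blocks
    on the leading variables; markers are also the leading variables, so
    markers and blocks may deliberately overlap.
    """

    n_per_group: int = 8
    group_levels: tuple[str, ...] = ("A", "B")
    n_variables: int = 200
    n_markers: int = 20
    effect_size: float = 2.0
    block_spec: tuple[tuple[int, float], ...] = ()
    zero_inflation: float = 0.0
    baseline_log_mean: float = 7.0
    baseline_log_sd: float = 0.5
    n_internal_standards: int = 2
    drift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be a positive integer")
        if len(self.group_levels) not in (2, 3):
            raise ConfigurationError("group_levels must have length 2 or 3")
        if len(set(self.group_levels)) != len(self.group_levels):
            raise ConfigurationError("group_levels must be distinct")
        if self.n_variables < 1:
            raise ConfigurationError("n_variables must be a positive integer")
        if not 0 <= self.n_markers <= self.n_variables:
            raise ConfigurationError("n_markers must satisfy 0 <= n_markers <= n_variables")
        total_block = sum(b[0] for b in self.block_spec)
        if total_block > self.n_variables:
            raise ConfigurationError("block_spec sizes exceed n_variables")
        for size, rho in self.block_spec:
            if size < 1:
                raise ConfigurationError("block_spec block sizes must be >= 1")
            if not 0 <= rho <= 1:
                raise ConfigurationError("block_spec correlations must lie in [0, 1]")
        if not 0 <= self.zero_inflation <= 1:
            raise ConfigurationError("zero_inflation must lie in [0, 1]")
        if self.baseline_log_sd < 0:
            raise ConfigurationError("baseline_log_sd must be non-negative")
        if self.n_internal_standards < 0:
            raise ConfigurationError("n_internal_standards must be non-negative")
        if self.drift_sd < 0:
            raise ConfigurationError("drift_sd must be non-negative")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its planted ground truth."""

    features: FeatureTable
    design: DesignTable
    truth_markers: set[str]
    truth_blocks: list[set[str]] = field(default_factory=list)
    truth_effect: np.ndarray | None = None  # groups x variables, log scale
    config: SyntheticConfig | None = None


def _design(config: SyntheticConfig) -> tuple[DesignTable, np.ndarray]:
    levels = list(config.group_levels)
    labels = [l for l in levels for _ in range(config.n_per_group)]
    sample_ids = [f"S{i + 1:02d}" for i in range(len(labels))]
    design = DesignTable(sample_ids=sample_ids, factors={FACTOR: labels})
    codes = np.repeat(np.arange(len(levels)), config.n_per_group)
    return design, codes


def _drift(config: SyntheticConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if config.drift_sd > 0:
        return np.exp(rng.normal(0.0, config.drift_sd, size=n))
    return np.ones(n)


def generate_feature_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a feature matrix with planted markers, blocks and drift.

    Variables ``V0001..`` are ordinary features; markers occupy the first
    ``n_markers`` indices and receive log-scale offsets of
    ``level_index * effect_size * baseline_log_sd``.  Correlated blocks
    from ``block_spec`` occupy leading indices as well.  Internal-standard
    channels ``IS1..`` are appended after the ordinary variables; they are
    noiseless (value = exp(baseline_log_mean) x sample drift) so that
    normalization removes the drift exactly.  Zeros are injected at rate
    ``zero_inflation`` on non-IS variables after effect injection.
    """
    n_groups = len(config.group_levels)
    n = config.n_per_group * n_groups
    p = config.n_variables
    ss = np.random.SeedSequence(config.seed)
    rng_base, rng_block, rng_drift, rng_zero = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    design, codes = _design(config)

    z = rng_base.standard_normal((n, p))
    blocks: list[np.ndarray] = []
    start = 0
    for size, rho in config.block_spec:
        idx = np.arange(start, start + size)
        blocks.append(idx)
        if rho > 0:
            shared = rng_block.standard_normal(n)
            z[:, idx] = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * z[:, idx]
        start += size

    log_x = config.baseline_log_mean + config.baseline_log_sd * z

    # Planted group effect: monotone in level order, log-scale shift in
    # units of the within-group (log) standard deviation.
    truth_effect = np.zeros((n_groups, p))
    if config.n_markers > 0 and config.effect_size != 0:
        shift = config.effect_size * config.baseline_log_sd
        for g in range(n_groups):
            truth_effect[g, : config.n_markers] = g * shift
    log_x += truth_effect[codes]

    drift = _drift(config, rng_drift, n)
    values = np.exp(log_x) * drift[:, None]

    if config.zero_inflation > 0:
        mask = rng_zero.random((n, p)) < config.zero_inflation
        values[mask] = 0.0

    var_ids = [f"V{j + 1:04d}" for j in range(p)]
    is_flags = np.zeros(p + config.n_internal_standards, dtype=bool)
    if config.n_internal_standards > 0:
        is_values = np.exp(config.baseline_log_mean) * drift[:, None] * np.ones(
            (n, config.n_internal_standards)
        )
        values = np.hstack([values, is_values])
        var_ids += [f"IS{j + 1}" for j in range(config.n_internal_standards)]
        is_flags[p:] = True
        truth_effect = np.hstack(
            [truth_effect, np.zeros((n_groups, config.n_internal_standards))]
        )

    features = FeatureTable(
        sample_ids=design.sample_ids,
        variable_ids=var_ids,
        values=values,
        variable_kind="feature",
        is_internal_standard=is_flags,
    )
    return SyntheticDataset(
        features=features,
        design=design,
        truth_markers={var_ids[j] for j in range(config.n_markers)},
        truth_blocks=[{var_ids[j] for j in idx} for idx in blocks],
        truth_effect=truth_effect,
        config=config,
    )


def generate_tic_dataset(
    config: SyntheticConfig,
    n_timepoints: int,
    n_peaks: int,
    noise_sd: float = 0.0,
    peak_centers=None,
    peak_sigmas=None,
) -> SyntheticDataset:
    """Generate TIC-like chromatograms built from Gaussian peaks.

    The first ``min(n_markers, n_peaks)`` peaks are differential: their
    height for group level ``g`` is the base height times
    ``1 + effect_size * g``.  Ground-truth marker channels are all integer
    time channels within +-2 sigma of a differential peak apex.  Peak
    centers/widths may be fixed explicitly for deterministic tests.
    """
    if n_peaks < 0:
        raise ConfigurationError("n_peaks must be non-negative")
    if n_timepoints < max(10 * n_peaks, 2):
        raise ConfigurationError("n_timepoints must be >= 10 * n_peaks")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be non-negative")

    n_groups = len(config.group_levels)
    n = config.n_per_group * n_groups
    ss = np.random.SeedSequence(config.seed)
    rng_peaks, rng_noise, rng_drift = (np.random.default_rng(s) for s in ss.spawn(3))
    design, codes = _design(config)

    if peak_centers is None:
        peak_centers = rng_peaks.uniform(15, n_timepoints - 15, size=n_peaks)
    peak_centers = np.asarray(peak_centers, dtype=float)
    if peak_sigmas is None:
        peak_sigmas = rng_peaks.uniform(2.0, 5.0, size=n_peaks)
    peak_sigmas = np.asarray(peak_sigmas, dtype=float)
    if len(peak_centers) != n_peaks or len(peak_sigmas) != n_peaks:
        raise ConfigurationError("peak_centers/peak_sigmas must have length n_peaks")
    heights = np.exp(
        rng_peaks.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_peaks)
    )

    n_diff = min(config.n_markers, n_peaks)
    t = np.arange(n_timepoints)
    values = np.zeros((n, n_timepoints))
    for k in range(n_peaks):
        shape = np.exp(-0.5 * ((t - peak_centers[k]) / peak_sigmas[k]) ** 2)
        group_scale = np.ones(n_groups)
        if k < n_diff:
            group_scale = 1.0 + config.effect_size * np.arange(n_groups)
        values += heights[k] * group_scale[codes][:, None] * shape[None, :]
    if noise_sd > 0:
        values += rng_noise.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    values *= _drift(config, rng_drift, n)[:, None]

    var_ids = [f"t{j:04d}" for j in range(n_timepoints)]
    truth: set[str] = set()
    for k in range(n_diff):
        lo = int(np.ceil(peak_centers[k] - 2 * peak_sigmas[k]))
        hi = int(np.floor(peak_centers[k] + 2 * peak_sigmas[k]))
        truth.update(var_ids[j] for j in range(max(lo, 0), min(hi, n_timepoints - 1) + 1))

    features = FeatureTable(
        sample_ids=design.sample_ids,
        variable_ids=var_ids,
        values=values,
        variable_kind="tic_channel",
    )
    return SyntheticDataset(
        features=features, design=design, truth_markers=truth, config=config
    )


def generate_centroid_scans(
    config: SyntheticConfig,
    n_scans: int,
    n_features: int | None = None,
    min_scans: int = 5,
    mz_jitter: float = 1e-3,
    rt_step: float = 0.1,
) -> tuple[dict[str, pd.DataFrame], list[dict]]:
    """Emit centroided scan tables with planted chromatographic features.

    Each planted feature appears in at least ``min_scans`` consecutive
    scans at a stable m/z (Gaussian jitter of scale ``mz_jitter``) with
    log-normal intensities.  Returns ``(scans, truth)`` where ``scans``
    maps sample id to a DataFrame with columns (scan, rt, mz, intensity)
    and ``truth`` lists per-feature dicts (mz, first_scan, n_scans, and
    the per-sample planted areas).
    """
    if n_scans < 2:
        raise ConfigurationError("n_scans must be >= 2")
    if n_features is None:
        n_features = config.n_variables
    if n_features < 0:
        raise ConfigurationError("n_features must be non-negative")
    if min_scans < 1 or min_scans > n_scans:
        raise ConfigurationError("min_scans must satisfy 1 <= min_scans <= n_scans")

    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    design, _ = _design(config)

    # Feature skeleton shared across samples; m/z spaced out to avoid
    # accidental trace merging in downstream ROI extraction.
    mzs = np.sort(rng.uniform(100.0, 1000.0, size=n_features))
    max_extra = max(n_scans - min_scans, 0)
    durations = min_scans + rng.integers(0, min(max_extra, 6) + 1, size=n_features)
    starts = np.array(
        [rng.integers(0, n_scans - d + 1) for d in durations], dtype=int
    )

    truth: list[dict] = [
        {
            "mz": float(mzs[k]),
            "first_scan": int(starts[k]),
            "n_scans": int(durations[k]),
            "area": {},
        }
        for k in range(n_features)
    ]
    scans: dict[str, pd.DataFrame] = {}
    for sid in design.sample_ids:
        recs = []
        for k in range(n_features):
            intens = np.exp(
                rng.normal(
                    config.baseline_log_mean, config.baseline_log_sd, durations[k]
                )
            )
            truth[k]["area"][sid] = float(intens.sum())
            for j in range(durations[k]):
                s = starts[k] + j
                recs.append(
                    (
                        s,
                        s * rt_step,
                        mzs[k] + rng.normal(0.0, mz_jitter),
                        intens[j],
                    )
                )
        df = pd.DataFrame(recs, columns=list(SCAN_COLUMNS))
        df = df.sort_values(["scan", "mz"], kind="stable").reset_index(drop=True)
        scans[sid] = df
    return scans, truth


def write_truth(dataset: SyntheticDataset, path) -> None:
    """Write the planted ground truth as JSON."""
    payload = {
        "markers": sorted(dataset.truth_markers),
        "blocks": [sorted(b) for b in dataset.truth_blocks],
        "effect_size": dataset.config.effect_size if dataset.config else None,
        "seed": dataset.config.seed if dataset.config else None,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def dataset_to_csvs(dataset: SyntheticDataset, features_path, design_path, truth_path=None):
    """Convenience writer for features/design (+ optional truth JSON)."""
    from .io import write_design, write_feature_table

    write_feature_table(dataset.features, features_path)
    write_design(dataset.design, design_path)
    if truth_path is not None:
        write_truth(dataset, truth_path)


def _config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    if "group_levels" in d:
        d["group_levels"] = tuple(d["group_levels"])
    if "block_spec" in d:
        d["block_spec"] = tuple((int(s), float(r)) for s, r in d["block_spec"])
    try:
        return SyntheticConfig(**d)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from None
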