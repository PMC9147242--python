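"""Tabular I/O and preprocessing for designed LC-MS experiments.

This module defines the two central tables of the package — the feature
table (samples x variables, either m/z-defined features or TIC time
channels) and the design table (per-sample factor levels plus a sample
amount used for normalization) — together with:

* CSV readers/writers for both tables (full-precision round trip),
* construction of TIC chromatograms from centroided scan tables,
* a deliberately simplified region-of-interest (ROI) feature extractor
  (greedy m/z trace building over consecutive scans), and
* internal-standard normalization, mean-centering and autoscaling.

The ROI extractor is a documented stand-in for full MSROI-style
algorithms: it builds traces greedily and is only intended to turn
synthetic or well-behaved centroided data into a feature matrix.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    ConfigurationError,
    ConstantColumnError,
    DegenerateSampleError,
    FormatError,
)

__all__ = [
    "FeatureTable",
    "DesignTable",
    "ROIParams",
    "read_feature_table",
    "write_feature_table",
    "read_design",
    "write_design",
    "extract_tic",
    "roi_features",
    "normalize",
    "center",
    "autoscale",
    "SCAN_COLUMNS",
]

#: Column order of a centroided scan table.
SCAN_COLUMNS = ("scan", "rt", "mz", "intensity")

#: Reserved first-column label of the optional internal-standard header row.
_IS_ROW_LABEL = "is_internal_standard"


def _check_unique(ids, what):
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """A samples x variables matrix of non-negative intensities/areas.

    Parameters
    ----------
    sample_ids : ordered unique sample labels (length n).
    variable_ids : ordered unique variable labels (length p); m/z strings
        for features, channel indices for TIC matrices.
    values : (n, p) float array, finite.
    variable_kind : ``"feature"`` or ``"tic_channel"``.
    is_internal_standard : boolean flag per variable (default all False).
    """

    sample_ids: list[str]
    variable_ids: list[str]
    values: np.ndarray
    variable_kind: str = "feature"
    is_internal_standard: np.ndarray | None = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise FormatError(
                f"{len(self.sample_ids)} sample ids but {n} value rows"
            )
        if p != len(self.variable_ids):
            raise FormatError(
                f"{len(self.variable_ids)} variable ids but {p} value columns"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.variable_ids, "variable id")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"variable {self.variable_ids[bad[1]]!r}"
            )
        if self.variable_kind not in ("feature", "tic_channel"):
            raise FormatError(
                f"variable_kind must be 'feature' or 'tic_channel', "
                f"got {self.variable_kind!r}"
            )
        if self.is_internal_standard is None:
            self.is_internal_standard = np.zeros(p, dtype=bool)
        else:
            self.is_internal_standard = np.asarray(
                self.is_internal_standard, dtype=bool
            )
            if self.is_internal_standard.shape != (p,):
                raise FormatError("is_internal_standard must have one flag per variable")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def drop_internal_standards(self) -> "FeatureTable":
        """Return a copy without the internal-standard columns."""
        keep = ~self.is_internal_standard
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            variable_ids=[v for v, k in zip(self.variable_ids, keep) if k],
            values=self.values[:, keep],
            variable_kind=self.variable_kind,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.variable_ids
        )


@dataclass
class DesignTable:
    """Per-sample factor levels and sample amounts.

    ``factors`` maps a factor name to the per-sample level labels (aligned
    with ``sample_ids``).  ``sample_amount`` is the per-sample quantity
    used in normalization (A600 value, embryo count, ...), defaulting to 1.
    """

    sample_ids: list[str]
    factors: dict[str, list[str]] = field(default_factory=dict)
    sample_amount: np.ndarray | None = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample id")
        n = len(self.sample_ids)
        self.factors = {
            str(f): [str(l) for l in levels] for f, levels in self.factors.items()
        }
        for f, levels in self.factors.items():
            if len(levels) != n:
                raise FormatError(
                    f"factor {f!r} has {len(levels)} levels for {n} samples"
                )
        if self.sample_amount is None:
            self.sample_amount = np.ones(n, dtype=float)
        else:
            self.sample_amount = np.asarray(self.sample_amount, dtype=float)
            if self.sample_amount.shape != (n,):
                raise FormatError("sample_amount must have one entry per sample")
        if np.any(self.sample_amount <= 0):
            bad = self.sample_ids[int(np.argmax(self.sample_amount <= 0))]
            raise FormatError(f"sample_amount must be > 0 (sample {bad!r})")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def levels(self, factor: str) -> list[str]:
        """Level labels of ``factor`` in order of first appearance."""
        labels = self.factors[factor]
        out: list[str] = []
        for l in labels:
            if l not in out:
                out.append(l)
        return out

    def codes(self, factor: str) -> np.ndarray:
        """Integer level codes per sample (level order = first appearance)."""
        levels = self.levels(factor)
        index = {l: i for i, l in enumerate(levels)}
        return np.array([index[l] for l in self.factors[factor]], dtype=int)

    def replace_factor(self, factor: str, labels) -> "DesignTable":
        """Copy of the design with ``factor`` set to ``labels``."""
        factors = dict(self.factors)
        factors[factor] = [str(l) for l in labels]
        return DesignTable(
            sample_ids=list(self.sample_ids),
            factors=factors,
            sample_amount=self.sample_amount.copy(),
        )

    def subset(self, sample_ids) -> "DesignTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [index[str(s)] for s in sample_ids]
        except KeyError as exc:
            raise AlignmentError(f"sample {exc.args[0]!r} not in design") from None
        return DesignTable(
            sample_ids=[self.sample_ids[i] for i in rows],
            factors={f: [v[i] for i in rows] for f, v in self.factors.items()},
            sample_amount=self.sample_amount[rows],
        )

    def aligned_to(self, table: FeatureTable) -> "DesignTable":
        """Design rows reordered to match the feature table's samples.

        Raises :class:`AlignmentError` if any feature-table sample is
        missing from the design.
        """
        return self.subset(table.sample_ids)


@dataclass(frozen=True)
class ROIParams:
    """Parameters of the simplified ROI feature extractor."""

    mz_tolerance: float = 0.01
    min_intensity: float = 0.0
    min_consecutive_scans: int = 5

    def __post_init__(self):
        if self.mz_tolerance <= 0:
            raise ConfigurationError("mz_tolerance must be positive")
        if self.min_intensity < 0:
            raise ConfigurationError("min_intensity must be non-negative")
        if self.min_consecutive_scans < 1:
            raise ConfigurationError("min_consecutive_scans must be >= 1")


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table CSV (full float precision round trip).

    Layout: header row ``sample_id,<var>,...``; an optional second row
    labelled ``is_internal_standard`` with 0/1 flags; one row per sample.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", *table.variable_ids])
        if table.is_internal_standard.any():
            w.writerow(
                [_IS_ROW_LABEL, *(int(f) for f in table.is_internal_standard)]
            )
        for sid, row in zip(table.sample_ids, table.values):
            w.writerow([sid, *(repr(float(v)) for v in row)])


def read_feature_table(path, variable_kind: str = "feature") -> FeatureTable:
    """Read a feature table CSV written by :func:`write_feature_table`.

    Raises :class:`FormatError` on ragged rows, duplicate ids or
    non-numeric cells, naming the offending row/column.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if not header or header[0] != "sample_id":
        raise FormatError(f"{path}: first header column must be 'sample_id'")
    variable_ids = header[1:]
    _check_unique(variable_ids, "variable column")
    body = rows[1:]
    is_flags = None
    if body and body[0] and body[0][0] == _IS_ROW_LABEL:
        flag_row = body.pop(0)
        if len(flag_row) != len(header):
            raise FormatError(f"{path}: ragged {_IS_ROW_LABEL} row")
        try:
            is_flags = np.array([bool(int(v)) for v in flag_row[1:]])
        except ValueError:
            raise FormatError(
                f"{path}: {_IS_ROW_LABEL} row must contain 0/1 flags"
            ) from None
    sample_ids, values = [], []
    for r, row in enumerate(body, start=2 + (is_flags is not None)):
        if len(row) != len(header):
            raise FormatError(
                f"{path}: row {r} has {len(row)} cells, expected {len(header)}"
            )
        sample_ids.append(row[0])
        parsed = []
        for c, cell in enumerate(row[1:]):
            try:
                parsed.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell at row {r}, "
                    f"column {variable_ids[c]!r}: {cell!r}"
                ) from None
        values.append(parsed)
    return FeatureTable(
        sample_ids=sample_ids,
        variable_ids=variable_ids,
        values=np.array(values, dtype=float).reshape(len(sample_ids), len(variable_ids)),
        variable_kind=variable_kind,
        is_internal_standard=is_flags,
    )


def write_design(design: DesignTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", *design.factors, "sample_amount"])
        for i, sid in enumerate(design.sample_ids):
            w.writerow(
                [sid]
                + [design.factors[f][i] for f in design.factors]
                + [repr(float(design.sample_amount[i]))]
            )


def read_design(path) -> DesignTable:
    """Read a design CSV: ``sample_id``, one column per factor, optional
    ``sample_amount`` column (missing amounts default to 1)."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    if not header or header[0] != "sample_id":
        raise FormatError(f"{path}: first header column must be 'sample_id'")
    factor_names = [h for h in header[1:] if h != "sample_amount"]
    has_amount = "sample_amount" in header
    amount_col = header.index("sample_amount") if has_amount else None
    sample_ids = []
    factors: dict[str, list[str]] = {f: [] for f in factor_names}
    amounts = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(
                f"{path}: row {r} has {len(row)} cells, expected {len(header)}"
            )
        sample_ids.append(row[0])
        for c, name in enumerate(header[1:], start=1):
            if name == "sample_amount":
                continue
            if row[c] == "":
                raise FormatError(
                    f"{path}: missing level for factor {name!r} at row {r}"
                )
            factors[name].append(row[c])
        if has_amount:
            try:
                amounts.append(float(row[amount_col]))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric sample_amount at row {r}"
                ) from None
    return DesignTable(
        sample_ids=sample_ids,
        factors=factors,
        sample_amount=np.array(amounts) if has_amount else None,
    )


# ---------------------------------------------------------------------------
# Scan tables: TIC and ROI features
# ---------------------------------------------------------------------------

def extract_tic(scans: pd.DataFrame) -> np.ndarray:
    """Total ion current chromatogram from a centroided scan table.

    The value at scan index ``s`` is the sum of all record intensities at
    that scan; scans with no records contribute 0.  An empty table yields
    a zero-length vector.
    """
    if len(scans) == 0:
        return np.zeros(0)
    scan_idx = np.asarray(scans["scan"], dtype=int)
    if np.any(scan_idx < 0):
        raise FormatError("negative scan index in scan table")
    return np.bincount(
        scan_idx,
        weights=np.asarray(scans["intensity"], dtype=float),
        minlength=int(scan_idx.max()) + 1,
    )


class _Trace:
    __slots__ = ("mz_sum", "int_sum", "n", "scans", "last_scan")

    def __init__(self, mz, intensity, scan):
        self.mz_sum = mz
        self.int_sum = intensity
        self.n = 1
        self.scans = {scan}
        self.last_scan = scan

    @property
    def mean_mz(self):
        return self.mz_sum / self.n

    def extend(self, mz, intensity, scan):
        self.mz_sum += mz
        self.int_sum += intensity
        self.n += 1
        self.scans.add(scan)
        self.last_scan = scan


def roi_features(
    scans: pd.DataFrame, params: ROIParams, sample_id: str = "sample"
) -> FeatureTable:
    """Simplified greedy ROI extraction for a single sample.

    Records below ``min_intensity`` are discarded.  A record extends the
    open trace whose running-mean m/z is nearest and within
    ``mz_tolerance``, provided the trace was last extended in the current
    or previous scan; otherwise it opens a new trace.  Traces covering at
    least ``min_consecutive_scans`` scans become features whose value is
    the summed intensity (area) and whose id is the mean m/z rounded to 4
    decimals (collisions suffixed ``_2``, ``_3``, ...).
    """
    open_traces: list[_Trace] = []
    closed: list[_Trace] = []

    if len(scans) > 0:
        df = scans[scans["intensity"] >= params.min_intensity]
        df = df.sort_values(["scan", "mz"], kind="stable")
        for scan, sub in df.groupby("scan", sort=True):
            scan = int(scan)
            still_open = []
            for t in open_traces:
                if t.last_scan >= scan - 1:
                    still_open.append(t)
                else:
                    closed.append(t)
            open_traces = still_open
            for mz, inten in zip(sub["mz"].to_numpy(), sub["intensity"].to_numpy()):
                best, best_d = None, None
                for t in open_traces:
                    d = abs(t.mean_mz - mz)
                    if d <= params.mz_tolerance and (best is None or d < best_d):
                        best, best_d = t, d
                if best is not None:
                    best.extend(float(mz), float(inten), scan)
                else:
                    open_traces.append(_Trace(float(mz), float(inten), scan))
    closed.extend(open_traces)

    kept = [t for t in closed if len(t.scans) >= params.min_consecutive_scans]
    kept.sort(key=lambda t: t.mean_mz)
    ids: list[str] = []
    used: dict[str, int] = {}
    for t in kept:
        base = f"{t.mean_mz:.4f}"
        if base in used:
            used[base] += 1
            ids.append(f"{base}_{used[base]}")
        else:
            used[base] = 1
            ids.append(base)
    values = np.array([[t.int_sum for t in kept]], dtype=float)
    if not kept:
        values = np.zeros((1, 0))
    return FeatureTable(
        sample_ids=[sample_id],
        variable_ids=ids,
        values=values,
        variable_kind="feature",
    )


# ---------------------------------------------------------------------------
# Normalization and scaling
# ---------------------------------------------------------------------------

def normalize(table: FeatureTable, design: DesignTable) -> FeatureTable:
    """Internal-standard / sample-amount normalization.

    Each sample row is divided by (mean of its internal-standard values x
    its sample amount).  Internal-standard columns are retained and stay
    flagged.  Multiplying an entire row (IS included) by a constant leaves
    the normalized row unchanged, so per-sample multiplicative drift is
    removed exactly when the IS channels carry the drift.
    """
    if not table.is_internal_standard.any():
        raise ConfigurationError(
            "normalize requires at least one internal-standard variable"
        )
    aligned = design.aligned_to(table)
    is_mean = table.values[:, table.is_internal_standard].mean(axis=1)
    zero = np.isclose(is_mean, 0.0)
    if np.any(zero):
        bad = table.sample_ids[int(np.argmax(zero))]
        raise DegenerateSampleError(
            f"internal-standard mean is zero for sample {bad!r}"
        )
    scale = is_mean * aligned.sample_amount
    return replace(table, values=table.values / scale[:, None])


def center(matrix: np.ndarray) -> np.ndarray:
    """Column mean-centering."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("center requires a matrix with >= 2 rows")
    return X - X.mean(axis=0)


def autoscale(matrix: np.ndarray) -> np.ndarray:
    """Column mean-centering followed by unit-variance scaling (ddof=1).

    Raises :class:`ConstantColumnError` listing any zero-variance columns;
    the caller may drop them and retry.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("autoscale requires a matrix with >= 2 rows")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        cols = np.flatnonzero(sd == 0).tolist()
        raise ConstantColumnError(
            f"autoscale undefined for constant columns {cols}"
        )
    Xc = X - X.mean(axis=0)
    Xc -= Xc.mean(axis=0)  # second pass kills cancellation residue
    return Xc / sd
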