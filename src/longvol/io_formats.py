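"""Readers, writers and validation for the three tabular interchange formats.

The package exchanges data through three plain-text formats common in
microbiome work:

* **sample metadata** — a TSV keyed by sample ID, with a numeric *state*
  (time) column and a categorical *subject* column, plus arbitrary group
  or metric columns.  An optional second header line beginning
  ``#q2:types`` declares per-column types (``numeric``/``categorical``)
  and overrides inference.
* **feature tables** — dense samples x features TSV matrices of
  nonnegative counts or relative frequencies, or BIOM v2.1 (HDF5,
  read-only).
* **distance matrices** — square, symmetric, hollow TSV matrices over
  sample IDs.

A small Jaccard helper turns a feature table into a presence/absence
distance matrix ("the proportion of features that are not shared").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: accepted spellings of the leading metadata ID header (case-insensitive)
ID_HEADERS = ("#sampleid", "sample-id", "sampleid", "id")

#: strings treated as missing metadata cells
MISSING_VALUES = ("", "NA")

_TYPES_DIRECTIVE = "#q2:types"


class FormatError(ValueError):
    """A file violates its format contract (hard error)."""


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample metadata table keyed by unique sample IDs.

    Parameters
    ----------
    frame : pandas.DataFrame
        Indexed by sample ID.  Numeric columns hold floats with NaN for
        missing; categorical columns hold strings with NaN for missing.
    state_column : str
        Name of the numeric time/state column (the ``t`` of a series).
    subject_column : str
        Name of the categorical per-individual column.
    column_types : dict
        Maps column name to ``"numeric"`` or ``"categorical"``.
    """

    frame: pd.DataFrame
    state_column: str
    subject_column: str
    column_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.frame.index
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise FormatError(f"duplicate sample IDs: {dups}")
        for col in (self.state_column, self.subject_column):
            if col is not None and col not in self.frame.columns:
                raise FormatError(f"designated column {col!r} not in metadata")
        if self.state_column is not None:
            if self.column_types.get(self.state_column) == "categorical":
                raise FormatError(
                    f"state column {self.state_column!r} declared categorical"
                )
            states = self.frame[self.state_column]
            bad = states.notna() & ~np.isfinite(
                pd.to_numeric(states, errors="coerce").fillna(0.0)
            )
            if bad.any():
                raise FormatError(
                    f"non-finite state values for samples {list(self.frame.index[bad])}"
                )
        if not self.column_types:
            self.column_types = {
                c: ("numeric" if pd.api.types.is_numeric_dtype(self.frame[c]) else "categorical")
                for c in self.frame.columns
            }

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)

    def is_numeric(self, column: str) -> bool:
        return self.column_types.get(column) == "numeric"

    def longitudinal_frame(self, extra_required: Sequence[str] = ()) -> pd.DataFrame:
        """Rows usable for longitudinal work.

        Rows missing the state, the subject, or any of ``extra_required``
        are dropped with a logged warning rather than raising: real
        cohorts have gaps.
        """
        df = self.frame
        required = [self.state_column, self.subject_column, *extra_required]
        mask = np.ones(len(df), dtype=bool)
        for col in required:
            mask &= df[col].notna().to_numpy()
        if not mask.all():
            dropped = list(df.index[~mask])
            logger.warning(
                "excluding %d sample(s) with missing state/subject/metric: %s",
                len(dropped), dropped,
            )
        return df.loc[mask]


def _resolve_id_header(header: str) -> bool:
    return header.strip().lower() in ID_HEADERS


def read_metadata(
    path: str | Path,
    state_column: str | None = None,
    subject_column: str | None = None,
) -> SampleMetadata:
    """Read a TSV metadata file, honouring an optional ``#q2:types`` row.

    Column types are taken from the directive row when present and
    inferred otherwise (numeric iff every non-missing value parses as a
    number).  Missing cells are the empty string or ``NA``.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty metadata file")
    header = lines[0].split("\t")
    if not _resolve_id_header(header[0]):
        raise FormatError(
            f"{path}: first header {header[0]!r} is not an accepted sample-ID "
            f"header {ID_HEADERS}"
        )
    columns = header[1:]
    declared: dict[str, str] = {}
    body_start = 1
    if len(lines) > 1 and lines[1].split("\t")[0].strip().lower() == _TYPES_DIRECTIVE:
        types_row = lines[1].split("\t")[1:]
        for name, typ in zip(columns, types_row):
            typ = typ.strip().lower()
            if typ in ("numeric", "categorical"):
                declared[name] = typ
        body_start = 2

    rows: list[list[str]] = []
    index: list[str] = []
    for lineno, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(cells)}"
            )
        index.append(cells[0])
        rows.append(cells[1:])

    raw = pd.DataFrame(rows, columns=columns, index=pd.Index(index, name="sample-id"))
    raw = raw.map(lambda v: np.nan if v.strip() in MISSING_VALUES else v.strip())

    column_types: dict[str, str] = {}
    frame = pd.DataFrame(index=raw.index)
    for col in columns:
        series = raw[col]
        as_num = pd.to_numeric(series, errors="coerce")
        inferred_numeric = bool((series.isna() | as_num.notna()).all())
        typ = declared.get(col, "numeric" if inferred_numeric else "categorical")
        if typ == "numeric" and not inferred_numeric:
            bad = series[series.notna() & as_num.isna()]
            sample, value = bad.index[0], bad.iloc[0]
            raise FormatError(
                f"{path}: column {col!r} declared numeric but sample "
                f"{sample!r} has non-numeric value {value!r}"
            )
        column_types[col] = typ
        frame[col] = as_num if typ == "numeric" else series

    if state_column is not None:
        if state_column not in frame.columns:
            raise FormatError(f"{path}: state column {state_column!r} not present")
        series = raw[state_column]
        as_num = pd.to_numeric(series, errors="coerce")
        bad = series[series.notna() & as_num.isna()]
        if len(bad):
            sample, value = bad.index[0], bad.iloc[0]
            raise FormatError(
                f"{path}: non-numeric value {value!r} in state column "
                f"{state_column!r} at sample {sample!r}"
            )
        frame[state_column] = as_num
        column_types[state_column] = "numeric"
    if subject_column is not None and subject_column not in frame.columns:
        raise FormatError(f"{path}: subject column {subject_column!r} not present")
    if subject_column is not None:
        frame[subject_column] = raw[subject_column]
        column_types[subject_column] = "categorical"

    return SampleMetadata(frame, state_column, subject_column, column_types)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    """Write metadata as TSV with a ``#q2:types`` directive row."""
    path = Path(path)
    cols = list(metadata.frame.columns)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(["sample-id", *cols]) + "\n")
        fh.write(
            "\t".join([_TYPES_DIRECTIVE, *(metadata.column_types.get(c, "categorical") for c in cols)])
            + "\n"
        )
        for sid, row in metadata.frame.iterrows():
            cells = [str(sid)]
            for c in cols:
                v = row[c]
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    cells.append("")
                elif metadata.column_types.get(c) == "numeric":
                    cells.append(f"{float(v):.10g}")
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Samples x features matrix of nonnegative abundances."""

    data: pd.DataFrame  # index: sample IDs, columns: feature IDs

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample IDs in feature table")
        if self.data.columns.duplicated().any():
            raise FormatError("duplicate feature IDs in feature table")
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative entry at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        self.data = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def check_relative(self, tol: float = 1e-6) -> None:
        """Assert each sample row sums to 1 (or 0 for an empty sample)."""
        sums = self.values.sum(axis=1)
        bad = ~(np.isclose(sums, 1.0, atol=tol) | (sums == 0.0))
        if bad.any():
            raise FormatError(
                f"rows do not sum to 1: {list(np.asarray(self.sample_ids)[bad])}"
            )

    def to_relative(self) -> "FeatureTable":
        """Close each sample row to relative frequencies (empty rows stay 0)."""
        v = self.values
        sums = v.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.where(sums > 0, v / sums, 0.0)
        return FeatureTable(pd.DataFrame(rel, index=self.data.index, columns=self.data.columns))


def read_feature_table(path: str | Path, orientation: str = "samples-as-rows") -> FeatureTable:
    """Read a dense TSV or BIOM v2.1 feature table, oriented samples x features.

    ``orientation`` applies to TSV input only; BIOM carries its own axis
    labels and is auto-oriented.
    """
    path = Path(path)
    if orientation not in ("samples-as-rows", "features-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if _is_hdf5(path):
        return _read_biom_hdf5(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty feature table")
    header = lines[0].split("\t")
    width = len(header)
    col_ids = header[1:]
    row_ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != width:
            raise FormatError(f"{path}:{lineno}: ragged row ({len(cells)} != {width} fields)")
        row_ids.append(cells[0])
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric entry ({exc})") from exc
    df = pd.DataFrame(rows, index=row_ids, columns=col_ids, dtype=float)
    if orientation == "features-as-rows":
        df = df.T
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a dense samples x features TSV at 10 significant digits."""
    _write_matrix_tsv(Path(path), "feature-id", table.data)


def _is_hdf5(path: Path) -> bool:
    try:
        with path.open("rb") as fh:
            return fh.read(8) == b"\x89HDF\r\n\x1a\n"
    except OSError:
        return False


def _read_biom_hdf5(path: Path) -> FeatureTable:
    # BIOM 2.1 stores the matrix twice, CSR over each axis; the
    # sample-major copy lives under /sample/matrix.
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as f:
        sample_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sample/ids"][:]]
        feature_ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["observation/ids"][:]]
        grp = f["sample/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(sample_ids), len(feature_ids)),
        )
    return FeatureTable(pd.DataFrame(mat.toarray(), index=sample_ids, columns=feature_ids))


# ---------------------------------------------------------------------------
# distance matrix
# ---------------------------------------------------------------------------

SYMMETRY_TOL = 1e-8


@dataclass
class DistanceMatrix:
    """Square symmetric hollow matrix of distances over sample IDs."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise FormatError("duplicate IDs in distance matrix")
        if self.values.shape != (n, n):
            raise FormatError(
                f"distance matrix shape {self.values.shape} does not match {n} IDs"
            )
        dev = np.abs(self.values - self.values.T).max() if n else 0.0
        if dev > SYMMETRY_TOL:
            raise FormatError(f"asymmetric distance matrix (max deviation {dev:.3g})")
        self.values = (self.values + self.values.T) / 2.0
        if n and np.abs(np.diag(self.values)).max() > SYMMETRY_TOL:
            raise FormatError("nonzero diagonal in distance matrix")
        np.fill_diagonal(self.values, 0.0)
        if (self.values < 0).any():
            raise FormatError("negative distance")
        self._index: Mapping[str, int] = {sid: k for k, sid in enumerate(self.ids)}

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._index

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def filter(self, ids: Iterable[str]) -> "DistanceMatrix":
        keep = [i for i in ids if i in self._index]
        pos = [self._index[i] for i in keep]
        return DistanceMatrix(keep, self.values[np.ix_(pos, pos)])


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square TSV distance matrix with matching row/column IDs."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise FormatError(f"{path}: row and column ID orderings differ")
    return DistanceMatrix(row_ids, df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a square TSV at 10 significant digits."""
    frame = pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids)
    _write_matrix_tsv(Path(path), "", frame)


def _write_matrix_tsv(path: Path, corner: str, frame: pd.DataFrame) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join([corner, *map(str, frame.columns)]) + "\n")
        for rid, row in zip(frame.index, frame.to_numpy()):
            fh.write("\t".join([str(rid), *(f"{v:.10g}" for v in row)]) + "\n")


# ---------------------------------------------------------------------------
# Jaccard helper
# ---------------------------------------------------------------------------


def jaccard_distances(table: FeatureTable, detection_threshold: float = 0.0) -> DistanceMatrix:
    """Pairwise Jaccard distance: the proportion of features not shared.

    A feature is "present" in a sample when its abundance is strictly
    greater than ``detection_threshold`` (default 0, i.e. plain
    presence/absence).  Two empty samples are at distance 0.
    """
    if len(table.sample_ids) < 2:
        raise ValueError("jaccard_distances requires at least 2 samples")
    presence = (table.values > detection_threshold).astype(float)
    inter = presence @ presence.T
    counts = presence.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(union > 0, 1.0 - inter / union, 0.0)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(table.sample_ids, dist)
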