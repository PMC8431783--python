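"""Quantification-matrix data model shared by every pipeline stage.

A wide label-free quantification (LFQ) table — rows are protein accessions,
columns are samples, cells are peak intensities — is held as an
:class:`IntensityMatrix`: a pandas DataFrame of floats where missing cells
are ``NaN``, plus a ``scale`` flag (``raw`` linear intensities or ``log2``).
Missingness is always represented by the explicit NaN mask, never by
sentinel zeros, because a zero in an MS export is ambiguous (true absence
vs. below detection vs. software artifact).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "SampleGroups",
    "FilterConfig",
    "read_matrix",
    "write_matrix",
    "log2_transform",
    "unlog2_transform",
    "select_groups",
]

RAW = "raw"
LOG2 = "log2"

#: cell tokens interpreted as missing when reading a matrix
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "N/A"})


@dataclass
class IntensityMatrix:
    """Proteins x samples intensity grid with an explicit missingness mask.

    Parameters
    ----------
    values : pandas.DataFrame
        Float grid, index = protein accessions, columns = sample names,
        ``NaN`` marks a missing cell.
    scale : str
        ``"raw"`` (linear, all present values > 0) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate protein accessions: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample names: {list(dups)[:5]}")
        self.values = self.values.astype(float)
        if self.scale == RAW:
            present = self.values.to_numpy()
            if np.any(present[~np.isnan(present)] <= 0):
                raise ValueError("raw-scale matrix contains non-positive intensities")

    # -- derived views ---------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean grid, True exactly where the cell is missing."""
        return self.values.isna()

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_fraction(self) -> float:
        return float(self.values.isna().to_numpy().mean())

    def is_complete(self) -> bool:
        return not bool(self.values.isna().to_numpy().any())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.scale)

    def subset_rows(self, accessions: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[list(accessions)], self.scale)


@dataclass
class SampleGroups:
    """Sample-to-group assignment plus the pairwise contrast.

    ``contrast`` is an ordered (treatment, reference) pair; log fold change
    downstream is treatment minus reference on the log2 scale.
    """

    assignment: Mapping[str, str]
    contrast: tuple[str, str]

    def __post_init__(self) -> None:
        self.assignment = dict(self.assignment)
        t, r = self.contrast
        if t == r:
            raise ValueError("contrast labels must differ")
        for label in (t, r):
            if self.n_in_group(label) == 0:
                raise ValueError(f"contrast label {label!r} has no samples")

    @property
    def treatment(self) -> str:
        return self.contrast[0]

    @property
    def reference(self) -> str:
        return self.contrast[1]

    def samples_in(self, label: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == label]

    def n_in_group(self, label: str) -> int:
        return len(self.samples_in(label))

    def validate_against(self, m: IntensityMatrix) -> None:
        missing = [s for s in m.sample_ids if s not in self.assignment]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        for label in self.contrast:
            n = len([s for s in self.samples_in(label) if s in m.sample_ids])
            if n < 2:
                raise ValueError(
                    f"group {label!r} has {n} sample(s) in the matrix; need >= 2"
                )


@dataclass
class FilterConfig:
    """Sparsity-filter settings.

    ``intensity_threshold`` is on the raw intensity scale (default 2**15 =
    32768, the conventional low-abundance floor for Orbitrap LFQ exports);
    a protein is sparse when at least ``sparse_fraction`` of its samples are
    missing or below that threshold, or when it has fewer than
    ``min_observations`` observed values.
    """

    intensity_threshold: float = 2.0 ** 15
    sparse_fraction: float = 0.5
    min_observations: int = 3
    apply_sparse_rule: bool = True
    apply_min_obs_rule: bool = True

    def __post_init__(self) -> None:
        if self.intensity_threshold <= 0:
            raise ValueError("intensity_threshold must be > 0")
        if not (0 < self.sparse_fraction <= 1):
            raise ValueError("sparse_fraction must be in (0, 1]")
        if self.min_observations < 0:
            raise ValueError("min_observations must be >= 0")


# -- I/O -------------------------------------------------------------------

def read_matrix(
    path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    zero_is_missing: bool = False,
    sep: str | None = None,
) -> IntensityMatrix:
    """Read a wide delimited intensity table into an :class:`IntensityMatrix`.

    The first column must hold protein accessions and the header row sample
    names. Cells equal to one of ``missing_tokens`` (and, if
    ``zero_is_missing``, numeric zero) become missing. The returned matrix
    has ``scale="raw"``.
    """
    tokens = set(missing_tokens)
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique()[0]
        raise ValueError(f"duplicate accession in input: {dup!r}")

    def _cell(v: str, row, col):
        v = v.strip()
        if v in tokens:
            return np.nan
        try:
            x = float(v)
        except ValueError:
            raise ValueError(f"non-numeric cell {v!r} at row {row!r}, column {col!r}") from None
        if zero_is_missing and x == 0:
            return np.nan
        return x

    out = pd.DataFrame(
        {c: [_cell(df.at[i, c], i, c) for i in df.index] for c in df.columns},
        index=df.index,
    )
    if out.isna().to_numpy().all():
        warnings.warn("matrix is 100% missing", stacklevel=2)
    return IntensityMatrix(out, scale=RAW)


def write_matrix(m: IntensityMatrix, path, sep: str = "\t", missing_token: str = "NA") -> None:
    """Write a matrix back to delimited text; missing cells become ``missing_token``."""
    m.values.to_csv(path, sep=sep, na_rep=missing_token, index_label="accession")


# -- transforms ------------------------------------------------------------

def log2_transform(m: IntensityMatrix) -> IntensityMatrix:
    """Return the log2-scale matrix; the missingness mask is unchanged.

    All Gaussian-family imputation models downstream assume log intensities,
    so this is applied once after raw-scale filtering.
    """
    if m.scale == LOG2:
        raise ValueError("matrix is already log2 scale")
    vals = m.values.to_numpy()
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise ValueError("cannot log-transform non-positive intensities")
    return IntensityMatrix(np.log2(m.values), scale=LOG2)


def unlog2_transform(m: IntensityMatrix) -> IntensityMatrix:
    """Inverse of :func:`log2_transform`."""
    if m.scale == RAW:
        raise ValueError("matrix is already raw scale")
    return IntensityMatrix(2.0 ** m.values, scale=RAW)


def select_groups(m: IntensityMatrix, g: SampleGroups) -> IntensityMatrix:
    """Restrict the matrix to the two contrast groups' columns.

    Column order is treatment block first, then reference block, preserving
    within-group input order; values and mask are untouched.
    """
    cols: list[str] = []
    for label in (g.treatment, g.reference):
        block = [s for s in m.sample_ids if g.assignment.get(s) == label]
        if not block:
            raise ValueError(f"contrast group {label!r} has no columns in the matrix")
        cols.extend(block)
    return IntensityMatrix(m.values[cols], scale=m.scale)
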