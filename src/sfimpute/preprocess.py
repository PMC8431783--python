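"""Selection-Filter stages: contaminant removal, sparsity filtering, quantile normalization."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .matrix import LOG2, RAW, FilterConfig, IntensityMatrix

__all__ = [
    "FilterReport",
    "filter_contaminants",
    "filter_sparse",
    "quantile_normalize",
    "read_contaminant_list",
]


@dataclass
class FilterReport:
    """Which rows a filter removed and under which rule."""

    removed: dict[str, str] = field(default_factory=dict)  # accession -> rule

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def count_by_rule(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rule in self.removed.values():
            out[rule] = out.get(rule, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"accession": list(self.removed), "rule": list(self.removed.values())}
        )


def read_contaminant_list(path) -> set[str]:
    """Read a plain-text contaminant accession list (one accession per line).

    Blank lines and ``#`` comments are ignored — the format of cRAP and
    MaxQuant contaminant accession exports.
    """
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def filter_contaminants(
    m: IntensityMatrix,
    contaminant_ids: Iterable[str],
    prefixes: tuple[str, ...] = (),
) -> tuple[IntensityMatrix, FilterReport]:
    """Drop rows whose accession is a known contaminant.

    A row is removed when its accession is in ``contaminant_ids`` exactly,
    or when, after stripping one of ``prefixes`` (e.g. the MaxQuant
    ``"CON__"`` marker), the remainder is in the set.
    """
    contaminants = set(contaminant_ids)
    report = FilterReport()
    keep = []
    for acc in m.protein_ids:
        hit = acc in contaminants
        if not hit:
            for pre in prefixes:
                if acc.startswith(pre) and acc[len(pre):] in contaminants:
                    hit = True
                    break
        if hit:
            report.removed[acc] = "contaminant"
        else:
            keep.append(acc)
    return m.subset_rows(keep), report


def filter_sparse(m: IntensityMatrix, cfg: FilterConfig | None = None) -> tuple[IntensityMatrix, FilterReport]:
    """Remove sparse / under-observed protein rows on the raw intensity scale.

    Two rules, both on by default and applied as a union:

    * ``sparse``: the fraction of samples whose cell is missing **or** below
      ``cfg.intensity_threshold`` is >= ``cfg.sparse_fraction``. A missing
      cell cannot certify abundance above the limit, so it counts as below.
    * ``min_obs``: fewer than ``cfg.min_observations`` observed values.
    """
    if m.scale != RAW:
        raise ValueError("sparsity filtering operates on the raw intensity scale")
    cfg = cfg or FilterConfig()
    vals = m.values.to_numpy()
    below = np.isnan(vals) | (vals < cfg.intensity_threshold)
    frac_below = below.mean(axis=1)
    n_obs = (~np.isnan(vals)).sum(axis=1)

    report = FilterReport()
    keep = []
    for i, acc in enumerate(m.protein_ids):
        sparse_hit = cfg.apply_sparse_rule and frac_below[i] >= cfg.sparse_fraction
        minobs_hit = cfg.apply_min_obs_rule and n_obs[i] < cfg.min_observations
        if sparse_hit and minobs_hit:
            report.removed[acc] = "sparse+min_obs"
        elif sparse_hit:
            report.removed[acc] = "sparse"
        elif minobs_hit:
            report.removed[acc] = "min_obs"
        else:
            keep.append(acc)
    return m.subset_rows(keep), report


def quantile_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Force every sample column onto the common (mean) intensity distribution.

    Each column's sorted values are replaced by the vector of row-wise means
    of the column-sorted matrix; ties within a column share the average of
    the tied quantile means, so within-column rank order is preserved.
    Requires a complete matrix (normalization is specified after imputation).
    """
    if not m.is_complete():
        raise ValueError("quantile normalization requires a complete (imputed) matrix")
    vals = m.values.to_numpy(dtype=float)
    order = np.sort(vals, axis=0)
    ref = order.mean(axis=1)  # quantile means

    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        col = vals[:, j]
        # average rank for ties -> average of tied quantile means
        sorter = np.argsort(col, kind="mergesort")
        ranks = np.empty(n, dtype=int)
        ranks[sorter] = np.arange(n)
        mapped = ref[ranks]
        # resolve ties: identical input values get the mean of their mapped refs
        uniq, inv = np.unique(col, return_inverse=True)
        if uniq.size < n:
            sums = np.bincount(inv, weights=mapped)
            counts = np.bincount(inv)
            mapped = (sums / counts)[inv]
        out[:, j] = mapped
    return IntensityMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), scale=m.scale
    )
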