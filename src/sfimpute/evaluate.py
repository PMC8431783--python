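"""Method-comparison metrics: capture rate, missingness bins, top-list merging,
spread statistics, threshold classification and complex-member rank-rating."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .impute import ModelSelectorResult
from .matrix import IntensityMatrix, SampleGroups

__all__ = [
    "capture_rate",
    "bin_missingness",
    "merge_top",
    "spread_stats",
    "classify_vs_threshold",
    "rank_rating",
    "RankRating",
]


def capture_rate(truth_sig: Iterable[str], observed_sig: Iterable[str]) -> float:
    """Percentage of ground-truth significant proteins recovered after imputation."""
    truth = set(truth_sig)
    if not truth:
        raise ValueError("ground-truth significant set is empty")
    return 100.0 * len(truth & set(observed_sig)) / len(truth)


def bin_missingness(mask: pd.DataFrame, g: SampleGroups) -> pd.Series:
    """Bin each protein by how its missing values distribute over the two groups.

    With missing values confined to one contrast group the bin is that
    group's missing count ("0".."3" for triplicates); values missing in
    both groups give "B2" or "B3" by the larger per-group count; a fully
    observed protein is "0".
    """
    t_cols = [s for s in mask.columns if g.assignment.get(s) == g.treatment]
    r_cols = [s for s in mask.columns if g.assignment.get(s) == g.reference]
    ct = mask[t_cols].sum(axis=1).to_numpy()
    cr = mask[r_cols].sum(axis=1).to_numpy()
    out = []
    for a, b in zip(ct, cr):
        if a > 0 and b > 0:
            out.append(f"B{max(a, b)}")
        else:
            out.append(str(int(max(a, b))))
    return pd.Series(out, index=mask.index, name="missing_bin")


def merge_top(
    tables: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame], n: int
) -> pd.DataFrame:
    """Union of each method's top-n proteins by rank, deduplicated.

    Returns a frame indexed by accession with one ``in_<method>`` flag per
    method and ``best_rank`` (the minimum rank across methods), ordered by
    best rank then accession.
    """
    if not isinstance(tables, Mapping):
        tables = {f"method_{i + 1}": t for i, t in enumerate(tables)}
    members: dict[str, dict[str, bool]] = {}
    best: dict[str, float] = {}
    for name, t in tables.items():
        k = n
        if n > len(t):
            warnings.warn(f"top-{n} requested but {name} has only {len(t)} rows")
            k = len(t)
        top = t.sort_values("rank").head(k)
        for acc, rank in zip(top.index, top["rank"]):
            members.setdefault(acc, {})[name] = True
            best[acc] = min(best.get(acc, np.inf), float(rank))
    rows = []
    for acc in members:
        row = {f"in_{name}": members[acc].get(name, False) for name in tables}
        row["best_rank"] = best[acc]
        rows.append((acc, row))
    out = pd.DataFrame({acc: row for acc, row in rows}).T
    out.index.name = "accession"
    out["best_rank"] = out["best_rank"].astype(float)
    # order by best cross-method rank, ties by accession
    return out.sort_index(kind="mergesort").sort_values("best_rank", kind="mergesort")


def spread_stats(
    tables: Mapping[str, pd.DataFrame], accessions: Sequence[str]
) -> pd.DataFrame:
    """Across-iteration spread of logFC and -log10 q for selected proteins.

    One row per (accession, method) with the four statistics plus the 95%
    spread-ellipse half-widths (1.96 x SD per axis); proteins absent from a
    method's table are flagged, not errors.
    """
    rows = []
    for method, t in tables.items():
        for acc in accessions:
            if acc in t.index:
                r = t.loc[acc]
                rows.append(
                    {
                        "accession": acc,
                        "method": method,
                        "absent": False,
                        "logfc_mean": r["logfc_mean"],
                        "logfc_sd": r["logfc_sd"],
                        "neglog10q_mean": r["neglog10q_mean"],
                        "neglog10q_sd": r["neglog10q_sd"],
                        "ellipse_halfwidth_logfc": 1.96 * r["logfc_sd"],
                        "ellipse_halfwidth_neglog10q": 1.96 * r["neglog10q_sd"],
                    }
                )
            else:
                rows.append(
                    {"accession": acc, "method": method, "absent": True}
                )
    return pd.DataFrame(rows)


def classify_vs_threshold(
    combined: pd.DataFrame,
    imputed: IntensityMatrix,
    sel: ModelSelectorResult,
    alpha: float = 0.05,
) -> pd.Series:
    """Cross-classify proteins by mean expression vs. the MNAR censoring
    threshold and by mean q-value vs. alpha."""
    mean_expr = imputed.values.mean(axis=1)
    out = []
    for acc in combined.index:
        above = mean_expr.loc[acc] >= sel.threshold_log2
        sig = combined.loc[acc, "qmean"] < alpha
        out.append(
            ("above" if above else "below")
            + ", "
            + ("significant" if sig else "not significant")
        )
    return pd.Series(out, index=combined.index, name="threshold_class")


@dataclass
class RankRating:
    """Per-target method ratings and their totals.

    ``ratings``: targets x methods, each row a (tie-averaged) permutation
    of 1..n_methods by ascending mean q-value; ``totals``: column sums —
    lower is better; ``overall``: methods ordered best-first.
    """

    ratings: pd.DataFrame
    totals: pd.Series
    overall: list[str]

    def add(self, other: "RankRating") -> "RankRating":
        """Sum totals across experiments (e.g. the two IP contrasts)."""
        totals = self.totals.add(other.totals, fill_value=0.0)
        return RankRating(
            ratings=pd.concat([self.ratings, other.ratings]),
            totals=totals,
            overall=list(totals.sort_values(kind="mergesort").index),
        )


def rank_rating(
    tables: Mapping[str, pd.DataFrame], targets: Sequence[str]
) -> RankRating:
    """Rate methods on a panel of target proteins by mean q-value.

    For each target, the method giving it the lowest mean q-value is rated
    1, the next 2, and so on; ties share the mean rating. A target absent
    from a method's table is assigned that method's worst possible q.
    Per-method totals (sums down the target panel) give the overall
    ordering, lowest total best.
    """
    if not targets:
        raise ValueError("empty target list")
    methods = list(tables)
    grid = np.empty((len(targets), len(methods)))
    for j, method in enumerate(methods):
        t = tables[method]
        for i, acc in enumerate(targets):
            if acc in t.index:
                grid[i, j] = t.loc[acc, "qmean"]
            else:
                warnings.warn(f"target {acc!r} absent from {method}; assigned worst rank")
                grid[i, j] = np.inf
    ratings = np.vstack([rankdata(row, method="average") for row in grid])
    ratings_df = pd.DataFrame(ratings, index=list(targets), columns=methods)
    totals = ratings_df.sum(axis=0)
    overall = list(totals.sort_values(kind="mergesort").index)
    return RankRating(ratings=ratings_df, totals=totals, overall=overall)
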