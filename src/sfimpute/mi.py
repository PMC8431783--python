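"""Multiple-imputation differential-expression engine.

A single imputation fixes one guess for every missing cell; repeating the
imputation m times (default 25) with iteration-specific seeds and, for kNN
and SVD, an iteration-indexed number of neighbors / components, exposes how
sensitive each protein's fold change and significance are to that guess.
Each iteration runs impute -> quantile normalize -> moderated t-test ->
q-values; the m per-protein tables are then combined by across-iteration
means and standard deviations of logFC and -log10 q, and proteins are
rank-ordered by mean q-value.

The engine is exposed both as plain functions (:func:`run_mi`,
:func:`combine_mi`) and as a model/results pair
(:class:`MIDifferentialExpression` / :class:`MIResults`) for interactive
use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .de_stats import moderated_ttest
from .evaluate import bin_missingness
from .impute import ImputeParams, impute
from .matrix import LOG2, IntensityMatrix, SampleGroups
from .preprocess import quantile_normalize

__all__ = ["MIConfig", "run_mi", "combine_mi", "MIDifferentialExpression", "MIResults"]

_Q_FLOOR = 1e-300  # guards -log10 against an exactly-zero q


@dataclass
class MIConfig:
    """Settings for one multiple-imputation run."""

    m: int = 25
    params: ImputeParams = field(default_factory=ImputeParams)
    vary_k_with_iteration: bool = True
    base_seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("number of MI iterations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def _iteration_params(cfg: MIConfig, i: int, shape: tuple[int, int]) -> ImputeParams:
    """Parameters for iteration i (1-based): fresh seed, iteration-indexed k/PCs."""
    n, ncol = shape
    p = replace(cfg.params, seed=cfg.base_seed + i)
    if cfg.vary_k_with_iteration and p.method in ("knn", "svd"):
        if p.method == "knn":
            p = replace(p, k_neighbors=min(i, max(n - 1, 1)))
        else:
            p = replace(p, n_components=min(i, n, ncol))
    return p


def run_mi(
    m: IntensityMatrix, g: SampleGroups, cfg: MIConfig
) -> list[pd.DataFrame]:
    """Run the m-iteration impute/normalize/test loop; returns one DE table per iteration."""
    if m.scale != LOG2:
        raise ValueError("MI runs on log2-scale matrices")
    tables: list[pd.DataFrame] = []
    for i in range(1, cfg.m + 1):
        p = _iteration_params(cfg, i, m.values.shape)
        try:
            completed = impute(m, p, g=g)
            normalized = quantile_normalize(completed)
            tables.append(moderated_ttest(normalized, g, alpha=cfg.alpha))
        except Exception as exc:  # noqa: BLE001 - re-raise with iteration context
            raise RuntimeError(f"MI iteration {i} ({p.method}) failed: {exc}") from exc
    return tables


def combine_mi(
    tables: list[pd.DataFrame],
    mask: pd.DataFrame | None,
    g: SampleGroups,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combine per-iteration DE tables into the ranked consensus table.

    Per protein: across-iteration mean/SD of logFC and of -log10 q, the
    mean q-value, the rank when sorted ascending by mean q (ties broken by
    accession), a strict ``significant`` call at ``qmean < alpha`` and,
    when the pre-imputation mask is supplied, the missingness bin.
    """
    if not tables:
        raise ValueError("no DE tables to combine")
    index = tables[0].index
    for t in tables[1:]:
        if not t.index.equals(index):
            raise ValueError("DE tables have inconsistent protein sets")

    logfc = np.column_stack([t["logFC"].to_numpy() for t in tables])
    q = np.column_stack([t["q"].to_numpy() for t in tables])
    neglog10q = -np.log10(np.maximum(q, _Q_FLOOR))

    def _sd(a: np.ndarray) -> np.ndarray:
        if a.shape[1] == 1:
            return np.zeros(a.shape[0])
        sd = a.std(axis=1, ddof=1)
        # identical values across iterations (deterministic imputers) must
        # give an exact zero, not mean-accumulation rounding noise
        sd[np.ptp(a, axis=1) == 0] = 0.0
        return sd

    combined = pd.DataFrame(
        {
            "logfc_mean": logfc.mean(axis=1),
            "logfc_sd": _sd(logfc),
            "neglog10q_mean": neglog10q.mean(axis=1),
            "neglog10q_sd": _sd(neglog10q),
            "qmean": q.mean(axis=1),
        },
        index=index,
    )
    order = combined.assign(_acc=combined.index.astype(str)).sort_values(
        ["qmean", "_acc"], kind="mergesort"
    )
    combined["rank"] = pd.Series(
        np.arange(1, len(combined) + 1), index=order.index
    ).reindex(index)
    combined["significant"] = combined["qmean"] < alpha
    if mask is not None:
        combined["missing_bin"] = bin_missingness(mask, g).reindex(index)
    return combined


class MIDifferentialExpression:
    """Multiple-imputation differential-expression model.

    Built from a filtered log2-scale :class:`IntensityMatrix` and a
    two-group contrast; :meth:`fit` executes the MI loop and returns an
    :class:`MIResults`.

    Examples
    --------
    >>> model = MIDifferentialExpression(matrix, groups,
    ...                                  MIConfig(m=25, params=ImputeParams(method="hybrid")))
    >>> res = model.fit()
    >>> res.combined.head()
    """

    def __init__(
        self,
        matrix: IntensityMatrix,
        groups: SampleGroups,
        config: MIConfig | None = None,
    ) -> None:
        groups.validate_against(matrix)
        if matrix.scale != LOG2:
            raise ValueError("model expects a log2-scale matrix")
        self.matrix = matrix
        self.groups = groups
        self.config = config or MIConfig()

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        assignment: dict[str, str],
        contrast: tuple[str, str],
        scale: str = LOG2,
        config: MIConfig | None = None,
    ) -> "MIDifferentialExpression":
        return cls(IntensityMatrix(values, scale=scale), SampleGroups(assignment, contrast), config)

    def fit(self) -> "MIResults":
        tables = run_mi(self.matrix, self.groups, self.config)
        combined = combine_mi(
            tables, self.matrix.mask, self.groups, alpha=self.config.alpha
        )
        return MIResults(self, tables, combined)


class MIResults:
    """Results of a fitted :class:`MIDifferentialExpression`."""

    def __init__(
        self,
        model: MIDifferentialExpression,
        tables: list[pd.DataFrame],
        combined: pd.DataFrame,
    ) -> None:
        self.model = model
        self.tables = tables
        self.combined = combined

    @property
    def n_significant(self) -> int:
        return int(self.combined["significant"].sum())

    @property
    def significant_ids(self) -> set[str]:
        return set(self.combined.index[self.combined["significant"]])

    def ranked(self) -> pd.DataFrame:
        return self.combined.sort_values("rank")

    def top(self, n: int) -> pd.DataFrame:
        return self.ranked().head(n)

    def summary(self) -> str:
        cfg = self.model.config
        g = self.model.groups
        lines = [
            "Multiple-imputation differential expression",
            "=" * 46,
            f"method: {cfg.params.method}    iterations: {cfg.m}    "
            f"base seed: {cfg.base_seed}",
            f"contrast: {g.treatment} vs {g.reference}",
            f"proteins: {len(self.combined)}    "
            f"significant (qmean < {cfg.alpha}): {self.n_significant}",
            "",
            "top proteins by mean q-value:",
            self.top(10)
            .loc[:, ["logfc_mean", "logfc_sd", "qmean", "rank"]]
            .to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.combined.to_csv(path, sep="\t", index_label="accession")
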