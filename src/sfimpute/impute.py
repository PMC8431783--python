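"""Missing-value imputation strategies for LFQ intensity matrices.

Seven strategies are provided, split by the missingness mechanism they
model:

* MAR (value-independent) — :func:`impute_knn`, :func:`impute_svd`,
  :func:`impute_mle`. These borrow information across proteins with similar
  expression profiles and are appropriate when a value is missing for
  reasons unrelated to its magnitude.
* MNAR (left-censored) — :func:`impute_mindet`, :func:`impute_minprob`,
  :func:`impute_qrilc`. These place imputed values in the low-intensity
  tail, modelling loss below an effective detection limit.
* Hybrid — :func:`impute_hybrid` flags each protein MAR or MNAR with
  :func:`model_selector` and imputes kNN (MAR) or QRILC (MNAR) separately
  within each treatment group.

All imputers operate on log2-scale matrices, return a complete matrix and
never alter an observed cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import LOG2, IntensityMatrix, SampleGroups

__all__ = [
    "ImputeParams",
    "ModelSelectorResult",
    "MVNParams",
    "model_selector",
    "impute_knn",
    "impute_svd",
    "impute_mle",
    "impute_mindet",
    "impute_minprob",
    "impute_qrilc",
    "impute_hybrid",
    "impute",
    "METHODS",
]

_KNN_EPS = 1e-10  # weight floor distance for exact-duplicate neighbor rows


@dataclass
class ImputeParams:
    """Tunable knobs shared by all imputation strategies."""

    method: str = "hybrid"
    k_neighbors: int = 10
    n_components: int = 2
    svd_tol: float = 0.01
    svd_relative_tol: bool = True
    svd_max_iter: int = 100
    mindet_quantile: float = 0.01
    mindet_global: bool = False
    minprob_sigma_scale: float = 1.0
    qrilc_sigma_scale: float = 1.0
    mle_draw: bool = True
    mle_tol: float = 1e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.svd_tol <= 0:
            raise ValueError("svd_tol must be > 0")
        if not (0 < self.mindet_quantile < 1):
            raise ValueError("mindet_quantile must be in (0, 1)")


@dataclass
class ModelSelectorResult:
    """Per-protein MAR/MNAR flags plus the censoring threshold.

    ``flags`` maps accession -> 1 (MAR) or 0 (MNAR); ``threshold_log2`` is
    the intensity below which a protein's mean observed abundance marks it
    as left-censored.
    """

    flags: pd.Series
    threshold_log2: float

    @property
    def mar_ids(self) -> list[str]:
        return list(self.flags.index[self.flags == 1])

    @property
    def mnar_ids(self) -> list[str]:
        return list(self.flags.index[self.flags == 0])


@dataclass
class MVNParams:
    """Multivariate-normal parameters over samples (the MLE imputer's theta)."""

    mu: np.ndarray
    sigma: np.ndarray


def _require_log2(m: IntensityMatrix) -> None:
    if m.scale != LOG2:
        raise ValueError("imputation operates on log2-scale matrices")


def _finish(m: IntensityMatrix, filled: np.ndarray) -> IntensityMatrix:
    """Write imputed values into masked cells only; observed cells are copied bitwise."""
    vals = m.values.to_numpy(dtype=float).copy()
    mask = np.isnan(vals)
    vals[mask] = filled[mask]
    return IntensityMatrix(
        pd.DataFrame(vals, index=m.values.index, columns=m.values.columns), scale=m.scale
    )


# -- model selector --------------------------------------------------------

def model_selector(
    m: IntensityMatrix,
    mode: Literal["auto", "mar", "mnar"] = "auto",
    empty_rows: Literal["error", "mnar"] = "error",
) -> ModelSelectorResult:
    """Flag each protein row MAR (1) or MNAR (0).

    The censoring threshold is the quantile of per-row mean observed
    intensities at probability equal to the matrix's overall missing
    fraction; rows whose mean falls below it are flagged MNAR. With no
    missingness the threshold sits at the 0-quantile and every row is MAR.
    ``mode="mar"``/``"mnar"`` force a uniform flag vector (the all-MAR mode
    is how the pure MAR strategies disable left-censored imputation).
    """
    _require_log2(m)
    vals = m.values.to_numpy(dtype=float)
    obs_counts = (~np.isnan(vals)).sum(axis=1)
    if empty_rows == "error" and np.any(obs_counts == 0):
        bad = m.values.index[obs_counts == 0][0]
        raise ValueError(f"row {bad!r} has no observed values; filter it first")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(vals, axis=1)
    finite = row_means[np.isfinite(row_means)]

    if mode == "mar":
        flags = np.ones(m.n_proteins, dtype=int)
        threshold = float(np.min(finite)) if finite.size else float("nan")
    elif mode == "mnar":
        flags = np.zeros(m.n_proteins, dtype=int)
        threshold = float(np.max(finite)) if finite.size else float("nan")
    else:
        pi = m.missing_fraction
        threshold = float(np.quantile(finite, pi))
        flags = np.where(np.isnan(row_means), 0, (row_means >= threshold).astype(int))
    return ModelSelectorResult(
        flags=pd.Series(flags, index=m.values.index), threshold_log2=threshold
    )


# -- MAR methods -----------------------------------------------------------

def impute_knn(m: IntensityMatrix, p: ImputeParams | None = None) -> IntensityMatrix:
    """k-nearest-neighbour imputation across protein rows.

    For each missing cell the k closest protein rows (Euclidean distance
    over mutually observed columns, scaled by sqrt(n_columns / n_overlap)
    so sparse overlaps are not rewarded) that observe the target column
    donate an inverse-distance-weighted average. Rows with no eligible
    donor fall back to their own observed mean.
    """
    _require_log2(m)
    p = p or ImputeParams(method="knn")
    vals = m.values.to_numpy(dtype=float)
    n, ncol = vals.shape
    obs = ~np.isnan(vals)
    filled = vals.copy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(vals, axis=1)

    for i in np.flatnonzero(~obs.all(axis=1)):
        # scaled distances from row i to every other row
        diff = vals[i] - vals  # (n, ncol), NaN where either missing
        shared = obs[i] & obs
        overlap = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sq = np.where(shared, np.nan_to_num(diff) ** 2, 0.0).sum(axis=1)
            dist = np.sqrt(sq * (ncol / np.maximum(overlap, 1)))
        dist[overlap == 0] = np.inf
        dist[i] = np.inf

        for j in np.flatnonzero(~obs[i]):
            eligible = np.flatnonzero(obs[:, j] & np.isfinite(dist))
            if eligible.size == 0:
                warnings.warn(
                    f"no eligible kNN donor for cell ({m.protein_ids[i]}, "
                    f"{m.sample_ids[j]}); falling back to row mean"
                )
                filled[i, j] = row_means[i]
                continue
            k = p.k_neighbors
            if k > eligible.size:
                warnings.warn(
                    f"k={k} exceeds donor pool ({eligible.size}); using pool size"
                )
                k = eligible.size
            order = eligible[np.argsort(dist[eligible], kind="mergesort")[:k]]
            w = 1.0 / np.maximum(dist[order], _KNN_EPS)
            filled[i, j] = float(np.sum(w * vals[order, j]) / np.sum(w))
    return _finish(m, filled)


def impute_svd(m: IntensityMatrix, p: ImputeParams | None = None) -> IntensityMatrix:
    """Iterative low-rank (eigenprotein) completion.

    Missing cells start at their row mean; each iteration takes the rank-k
    SVD of the filled matrix, regresses every incomplete row's observed
    entries on the top right-singular vectors and replaces its missing
    entries with the fitted values, until the change in imputed cells
    (root-sum-of-squares, relative to the matrix norm by default) drops
    below ``svd_tol``.
    """
    _require_log2(m)
    p = p or ImputeParams(method="svd")
    vals = m.values.to_numpy(dtype=float)
    n, ncol = vals.shape
    k = min(p.n_components, n, ncol)
    mask = np.isnan(vals)
    if not mask.any():
        return m.copy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_means = np.nanmean(vals, axis=1)
    if np.any(np.isnan(row_means[mask.any(axis=1)])):
        raise ValueError("row with no observed values; filter it first")

    filled = vals.copy()
    filled[mask] = np.broadcast_to(row_means[:, None], vals.shape)[mask]

    converged = False
    for _ in range(p.svd_max_iter):
        _, _, vt = np.linalg.svd(filled, full_matrices=False)
        basis = vt[:k].T  # (ncol, k) eigen-sample basis
        new = filled.copy()
        for i in np.flatnonzero(mask.any(axis=1)):
            o = ~mask[i]
            beta, *_ = np.linalg.lstsq(basis[o], filled[i, o], rcond=None)
            new[i, mask[i]] = basis[mask[i]] @ beta
        change = np.sqrt(np.sum((new[mask] - filled[mask]) ** 2))
        if p.svd_relative_tol:
            change /= max(np.sqrt(np.sum(new ** 2)), np.finfo(float).tiny)
        filled = new
        if change < p.svd_tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"SVD imputation did not converge in {p.svd_max_iter} iterations")
    return _finish(m, filled)


def _em_mvn(vals: np.ndarray, tol: float, max_iter: int = 200) -> MVNParams:
    """EM estimate of a multivariate normal over columns from rows with missing entries.

    Rows sharing a missingness pattern are processed together, so the cost
    per sweep scales with the number of distinct patterns, not rows.
    """
    n, d = vals.shape
    obs = ~np.isnan(vals)
    mu = np.nanmean(vals, axis=0)
    filled0 = np.where(obs, vals, mu)
    sigma = np.cov(filled0, rowvar=False, bias=True) + 1e-6 * np.eye(d)

    patterns: dict[bytes, np.ndarray] = {}
    for key in np.unique(obs, axis=0):
        sel = np.flatnonzero((obs == key).all(axis=1))
        patterns[key.tobytes()] = sel

    last_ll = -np.inf
    for _ in range(max_iter):
        ex = np.where(obs, vals, 0.0)
        exx_corr = np.zeros((d, d))
        ll = 0.0
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            if not o.any():
                ex[rows] = mu
                exx_corr += sigma * len(rows)
                continue
            block = vals[rows][:, o]
            soo = sigma[np.ix_(o, o)]
            ll += float(
                stats.multivariate_normal.logpdf(
                    block, mu[o], soo, allow_singular=True
                ).sum()
            )
            if o.all():
                continue
            mis = ~o
            smo = sigma[np.ix_(mis, o)]
            smm = sigma[np.ix_(mis, mis)]
            try:
                gain = np.linalg.solve(soo, smo.T).T
            except np.linalg.LinAlgError:
                soo = soo + 1e-8 * np.eye(int(o.sum()))
                gain = np.linalg.solve(soo, smo.T).T
            cond_means = mu[mis] + (block - mu[o]) @ gain.T
            cond_cov = smm - gain @ smo.T
            ex[np.ix_(rows, np.flatnonzero(mis))] = cond_means
            full = np.zeros((d, d))
            full[np.ix_(mis, mis)] = cond_cov * len(rows)
            exx_corr += full
        mu = ex.mean(axis=0)
        centered = ex - mu
        sigma = (centered.T @ centered + exx_corr) / n
        # keep sigma well conditioned; tiny ridge when near-singular
        if np.linalg.cond(sigma) > 1e10:
            warnings.warn("near-singular covariance in EM; adding ridge")
            sigma = sigma + 1e-6 * np.trace(sigma) / d * np.eye(d)
        if abs(ll - last_ll) < tol:
            break
        last_ll = ll
    return MVNParams(mu=mu, sigma=sigma)


def impute_mle(m: IntensityMatrix, p: ImputeParams | None = None) -> IntensityMatrix:
    """Maximum-likelihood (EM) imputation under a row-i.i.d. multivariate normal.

    Protein rows are treated as draws from a multivariate normal over the
    samples; theta = (mu, Sigma) is estimated by EM and each row's missing
    block is replaced by a draw from (or, in deterministic mode, the mean
    of) the conditional normal given the row's observed entries.
    """
    _require_log2(m)
    p = p or ImputeParams(method="mle")
    vals = m.values.to_numpy(dtype=float)
    n, d = vals.shape
    if n <= d:
        warnings.warn("fewer rows than columns; covariance estimate will be unstable")
    mask = np.isnan(vals)
    if not mask.any():
        return m.copy()
    theta = _em_mvn(vals, p.mle_tol)
    rng = np.random.default_rng(p.seed)

    filled = vals.copy()
    obs = ~mask
    for i in np.flatnonzero(mask.any(axis=1)):
        o = obs[i]
        mis = mask[i]
        if not o.any():
            raise ValueError("row with no observed values; filter it first")
        soo = theta.sigma[np.ix_(o, o)]
        smo = theta.sigma[np.ix_(mis, o)]
        smm = theta.sigma[np.ix_(mis, mis)]
        gain = np.linalg.solve(soo + 1e-12 * np.eye(o.sum()), smo.T).T
        cond_mean = theta.mu[mis] + gain @ (vals[i, o] - theta.mu[o])
        if p.mle_draw:
            cond_cov = smm - gain @ smo.T
            cond_cov = (cond_cov + cond_cov.T) / 2
            w, v = np.linalg.eigh(cond_cov)
            w = np.clip(w, 0, None)
            z = rng.standard_normal(mis.sum())
            filled[i, mis] = cond_mean + v @ (np.sqrt(w) * z)
        else:
            filled[i, mis] = cond_mean
    return _finish(m, filled)


# -- MNAR methods ----------------------------------------------------------

def _mindet_centers(m: IntensityMatrix, p: ImputeParams) -> np.ndarray:
    """Per-column deterministic-minimum replacement values."""
    vals = m.values.to_numpy(dtype=float)
    pooled = vals[~np.isnan(vals)]
    if pooled.size == 0:
        raise ValueError("matrix has no observed values")
    global_q = float(np.quantile(pooled, p.mindet_quantile))
    if p.mindet_global:
        return np.full(vals.shape[1], global_q)
    centers = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        col = vals[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            warnings.warn(
                f"sample {m.sample_ids[j]!r} has no observed values; "
                "using the global low quantile"
            )
            centers[j] = global_q
        else:
            centers[j] = float(np.quantile(col, p.mindet_quantile))
    return centers


def impute_mindet(m: IntensityMatrix, p: ImputeParams | None = None) -> IntensityMatrix:
    """Deterministic minimum: every missing cell gets its sample's low quantile.

    Per-sample mode (default) uses each column's ``mindet_quantile``
    quantile of observed values; global mode pools all observed values.
    Repeated calls are bitwise identical, so across-iteration variability
    of any downstream statistic is exactly zero.
    """
    _require_log2(m)
    p = p or ImputeParams(method="mindet")
    centers = _mindet_centers(m, p)
    filled = np.broadcast_to(centers, m.values.shape).copy()
    return _finish(m, filled)


def _robust_spread(vals: np.ndarray) -> float:
    """Median of per-row observed SDs; robust to 3-sample columns."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_sds = np.nanstd(vals, axis=1, ddof=1)
    row_sds = row_sds[np.isfinite(row_sds)]
    return float(np.median(row_sds)) if row_sds.size else 0.0


def impute_minprob(m: IntensityMatrix, p: ImputeParams | None = None) -> IntensityMatrix:
    """Probabilistic minimum: Gaussian draws centered on the MinDet value.

    Draw SD is ``minprob_sigma_scale`` times a robust spread estimate (the
    median of per-row observed SDs); as the scale goes to zero the output
    degenerates to :func:`impute_mindet`.
    """
    _require_log2(m)
    p = p or ImputeParams(method="minprob")
    vals = m.values.to_numpy(dtype=float)
    centers = _mindet_centers(m, p)
    sd = p.minprob_sigma_scale * _robust_spread(vals)
    if sd == 0:
        warnings.warn("zero spread estimate; MinProb draws degenerate to MinDet")
    rng = np.random.default_rng(p.seed)
    draws = rng.normal(
        loc=np.broadcast_to(centers, vals.shape), scale=sd, size=vals.shape
    )
    return _finish(m, draws)


def _qrilc_column_fit(col_obs: np.ndarray, pi: float) -> tuple[float, float]:
    """Estimate the uncensored normal (mu, sigma) of one left-censored column.

    The observed values are taken to be the upper (1 - pi) tail; their
    empirical quantiles are regressed on standard-normal quantiles over a
    probability grid spanning (pi + 0.001, 0.999), so the OLS intercept and
    slope recover mu and sigma of the full distribution.
    """
    probs = np.linspace(pi + 0.001, 0.999, 100)
    # overall probability p maps to observed-tail probability (p - pi)/(1 - pi)
    tail_probs = (probs - pi) / (1.0 - pi)
    y = np.quantile(col_obs, tail_probs)
    x = stats.norm.ppf(probs)
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(max(slope, 1e-9))


def impute_qrilc(m: IntensityMatrix, p: ImputeParams | None = None) -> IntensityMatrix:
    """Quantile regression imputation of left-censored data (QRILC).

    Per sample column: the missing fraction pi is read as the censored mass
    in the left tail; the uncensored normal (mu, sigma) is recovered from a
    normal quantile-quantile regression of observed order statistics, and
    missing cells are drawn from that normal truncated above at its
    pi-quantile mu + sigma * Phi^-1(pi). Columns with no missing cells are
    untouched.
    """
    _require_log2(m)
    p = p or ImputeParams(method="qrilc")
    vals = m.values.to_numpy(dtype=float)
    rng = np.random.default_rng(p.seed)
    filled = vals.copy()
    for j in range(vals.shape[1]):
        col = vals[:, j]
        mis = np.isnan(col)
        if not mis.any():
            continue
        obs = col[~mis]
        if obs.size < 4:
            raise ValueError(
                f"sample {m.sample_ids[j]!r} has {obs.size} observed values; "
                "QRILC needs >= 4"
            )
        pi = float(mis.mean())
        mu, sigma = _qrilc_column_fit(obs, pi)
        sigma_draw = p.qrilc_sigma_scale * sigma
        upper = mu + sigma * stats.norm.ppf(pi)
        b = (upper - mu) / sigma_draw
        draws = stats.truncnorm.rvs(
            -np.inf, b, loc=mu, scale=sigma_draw, size=int(mis.sum()), random_state=rng
        )
        filled[mis, j] = draws
    return _finish(m, filled)


# -- hybrid ----------------------------------------------------------------

def impute_hybrid(
    m: IntensityMatrix,
    g: SampleGroups,
    p: ImputeParams | None = None,
) -> tuple[IntensityMatrix, dict[str, ModelSelectorResult]]:
    """Per-group MAR/MNAR hybrid imputation (the SFI-hybrid core).

    Each treatment group's column block is imputed independently: the model
    selector flags each protein MAR or MNAR within the block, MAR rows'
    missing cells are filled by kNN and MNAR rows' by QRILC. A row with no
    observed value inside a block (the presence/absence case) is treated as
    left-censored and handled by QRILC. Returns the completed matrix and
    the per-group selector results.
    """
    _require_log2(m)
    p = p or ImputeParams(method="hybrid")
    out = m.values.copy()
    selectors: dict[str, ModelSelectorResult] = {}
    labels = sorted({g.assignment[s] for s in m.sample_ids})
    for label in labels:
        cols = [s for s in m.sample_ids if g.assignment[s] == label]
        block = IntensityMatrix(m.values[cols], scale=LOG2)
        sel = model_selector(block, empty_rows="mnar")
        selectors[label] = sel
        if block.is_complete():
            continue
        knn_block = impute_knn(block, p)
        qrilc_block = impute_qrilc(block, p)
        merged = knn_block.values.copy()
        mnar = sel.flags == 0
        merged.loc[mnar] = qrilc_block.values.loc[mnar]
        out[cols] = merged
    return IntensityMatrix(out, scale=LOG2), selectors


# -- dispatch --------------------------------------------------------------

METHODS = ("knn", "svd", "mle", "mindet", "minprob", "qrilc", "hybrid")

_DISPATCH: dict[str, Callable[..., IntensityMatrix]] = {
    "knn": impute_knn,
    "svd": impute_svd,
    "mle": impute_mle,
    "mindet": impute_mindet,
    "minprob": impute_minprob,
    "qrilc": impute_qrilc,
}


def impute(
    m: IntensityMatrix,
    p: ImputeParams,
    g: SampleGroups | None = None,
    per_group: bool | None = None,
) -> IntensityMatrix:
    """Dispatch to the strategy named by ``p.method``.

    Non-hybrid methods impute the whole matrix jointly by default; pass
    ``per_group=True`` (with groups) to run any method within each group's
    column block. The hybrid method is always per group and requires ``g``.
    """
    if p.method == "hybrid":
        if g is None:
            raise ValueError("hybrid imputation requires sample groups")
        return impute_hybrid(m, g, p)[0]
    if p.method not in _DISPATCH:
        raise ValueError(f"unknown imputation method {p.method!r}")
    fn = _DISPATCH[p.method]
    if per_group:
        if g is None:
            raise ValueError("per-group imputation requires sample groups")
        out = m.values.copy()
        for label in sorted({g.assignment[s] for s in m.sample_ids}):
            cols = [s for s in m.sample_ids if g.assignment[s] == label]
            block = IntensityMatrix(m.values[cols], scale=LOG2)
            out[cols] = fn(block, p).values
        return IntensityMatrix(out, scale=LOG2)
    return fn(m, p)
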