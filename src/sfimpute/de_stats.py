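"""Differential-expression statistics.

Per-protein significance is assessed with an empirical-Bayes moderated
t-test: each protein's pooled residual variance s_g^2 (d residual degrees
of freedom) is shrunk toward a prior variance s0^2 with d0 prior degrees of
freedom, fitted by matching the moments of log s_g^2 to a scaled
inverse-chi-square distribution. The moderated statistic

    t_g = logFC_g / (s_tilde_g * sqrt(1/n1 + 1/n2)),
    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

is referred to a t distribution on d0 + d degrees of freedom. P-values are
Benjamini-Hochberg adjusted and converted to Storey q-values; proteins with
q < alpha (default 0.05, strict) are called differentially expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import LOG2, IntensityMatrix, SampleGroups

__all__ = [
    "EBPrior",
    "fit_variance_prior",
    "moderated_ttest",
    "bh_adjust",
    "estimate_pi0",
    "qvalues",
    "decide_significant",
]

#: d0 at or above this value is treated as infinite moderation
D0_INF = 1e6


@dataclass
class EBPrior:
    """Scaled inverse-chi-square prior on residual variances."""

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("prior degrees of freedom must be >= 0")
        if self.s0sq <= 0:
            raise ValueError("prior variance must be > 0")


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y (monotone decreasing)
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> EBPrior:
    """Fit (d0, s0^2) by moment-matching log sample variances.

    Under the hierarchical model, z_g = log s_g^2 follows a shifted
    log-F distribution whose mean and variance involve digamma/trigamma
    terms; inverting those moments yields the prior.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size == 0:
        raise ValueError("all residual variances are zero; cannot fit a prior")
    if pos.size < s2.size:
        warnings.warn("zero residual variances excluded from prior fit")
    if pos.size < 2:
        warnings.warn("single usable variance; no moderation applied")
        return EBPrior(d0=0.0, s0sq=float(pos[0]))
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        half_d0 = _trigamma_inverse(evar)
        d0 = 2.0 * half_d0
        s0sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        # no excess dispersion beyond sampling noise: infinite shrinkage,
        # prior variance = the mean observed variance
        d0 = D0_INF
        s0sq = float(np.mean(pos))
    d0 = min(d0, D0_INF)
    return EBPrior(d0=d0, s0sq=s0sq)


def moderated_ttest(
    m: IntensityMatrix,
    g: SampleGroups,
    prior: EBPrior | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per protein.

    Returns a table indexed by accession with columns ``logFC`` (treatment
    minus reference group mean), ``t_mod``, ``df_total``, ``p``, ``p_adj``,
    ``q`` and ``significant``. Pass ``prior`` to bypass the empirical fit
    (``d0=0`` gives the classical pooled t; a huge ``d0`` pins every
    posterior variance at ``s0sq``).
    """
    if m.scale != LOG2:
        raise ValueError("moderated t-test expects log2-scale intensities")
    if not m.is_complete():
        raise ValueError("matrix must be complete (impute first)")
    g.validate_against(m)

    t_cols = [s for s in m.sample_ids if g.assignment[s] == g.treatment]
    r_cols = [s for s in m.sample_ids if g.assignment[s] == g.reference]
    x1 = m.values[t_cols].to_numpy(dtype=float)
    x2 = m.values[r_cols].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    df_resid = n1 + n2 - 2

    logfc = x1.mean(axis=1) - x2.mean(axis=1)
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid

    if prior is None:
        if len(logfc) < 2:
            warnings.warn("single protein; using ordinary t-test (no prior estimable)")
            prior = EBPrior(d0=0.0, s0sq=float(max(s2[0], np.finfo(float).tiny)))
        else:
            prior = fit_variance_prior(s2, df_resid)

    if prior.d0 >= D0_INF:
        s2_post = np.full_like(s2, prior.s0sq)
        df_total = np.inf
    else:
        s2_post = (prior.d0 * prior.s0sq + df_resid * s2) / (prior.d0 + df_resid)
        df_total = prior.d0 + df_resid
    # the pooled information cannot exceed all proteins' residual df combined
    df_total = min(df_total, len(s2) * df_resid)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    if np.any(se == 0):
        raise ValueError("zero posterior standard error; variances degenerate")
    t_mod = logfc / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
        },
        index=m.values.index,
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["q"] = qvalues(table["p"].to_numpy())
    return decide_significant(table, alpha)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 by the smoother convention.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) is computed over a
    lambda grid (default 0.05..0.95 in steps of 0.05), a cubic polynomial
    smoother is fitted and evaluated at the largest lambda, and the result
    is clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size < 10:
        warnings.warn("fewer than 10 p-values; pi0 fixed at 1")
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, 3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return float(np.clip(pi0, 1.0 / p.size, 1.0))


def qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: pi0-scaled step-up FDR estimates, monotone in p-rank."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must be in (0, 1]")
    return np.minimum(pi0 * bh_adjust(p), 1.0)


def decide_significant(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Set the ``significant`` flag: q strictly below ``alpha``."""
    if "q" not in table.columns:
        raise ValueError("table has no q column")
    out = table.copy()
    out["significant"] = out["q"] < alpha
    return out
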