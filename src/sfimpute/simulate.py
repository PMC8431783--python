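"""Synthetic data: template-based simulation, mechanism-controlled amputation,
and a self-contained ground-truth generator.

Benchmarking imputation needs data whose missing cells have known true
values and known mechanisms. Three layers provide that:

* :func:`simulate_from_template` resamples a real (or realistic) matrix —
  per protein, per treatment group, replicates are drawn from a normal with
  that group's observed mean and SD, so the simulated set preserves the
  template's abundance structure and group effects.
* :func:`ampute` deliberately introduces missing values into complete
  rows. Each mechanism builds its own candidate mask — MAR masking
  probability driven by the row's remaining observed values, MNAR by the
  value that would be deleted (left-shaped, so low-abundance cells go
  missing preferentially) — and a random allocation vector decides, row by
  row, which mechanism's pattern applies.
* :func:`generate_ground_truth` builds a complete two-group log2 dataset
  with planted effects from scratch, then amputes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .matrix import LOG2, IntensityMatrix, SampleGroups

__all__ = [
    "SimConfig",
    "AmputeConfig",
    "GroundTruth",
    "simulate_from_template",
    "ampute",
    "generate_ground_truth",
]


@dataclass
class SimConfig:
    """Template-resampling settings."""

    n_replicates: int = 3
    seed: int | None = None
    keep_all_missing_groups: bool = True

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


@dataclass
class AmputeConfig:
    """Mechanism mix and shapes for deliberate amputation.

    ``prop_mar`` / ``prop_mnar`` are the fractions of candidate rows each
    mechanism's pass masks (the study grid pairs them as 0.2:0.2, 0.2:0.8,
    0.5:0.5, 0.8:0.2). ``patterns`` lists boolean column masks (True =
    delete); the default is one single-column pattern per sample.
    ``prob_shape`` maps mechanism -> logistic link shape over the
    standardized weighted-sum score: ``left`` favours low scores, ``right``
    high, ``mid`` central, ``tail`` extreme.
    """

    prop_mar: float = 0.5
    prop_mnar: float = 0.5
    patterns: list[np.ndarray] | None = None
    mar_weights: np.ndarray | None = None
    prob_shape: dict[str, str] = field(
        default_factory=lambda: {"mar": "right", "mnar": "left"}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        for name, prop in (("prop_mar", self.prop_mar), ("prop_mnar", self.prop_mnar)):
            if not (0.0 <= prop <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for shape in self.prob_shape.values():
            if shape not in ("left", "right", "mid", "tail", "mcar"):
                raise ValueError(f"unknown prob_shape {shape!r}")


@dataclass
class GroundTruth:
    """Complete matrix, its amputed counterpart, and all truth labels."""

    complete: IntensityMatrix
    amputed: IntensityMatrix
    groups: SampleGroups
    effects: pd.Series  # per-protein true logFC (treatment - reference)
    de_labels: pd.Series  # True where |effect| > 0
    mechanism: pd.DataFrame  # per-cell: "observed", "MAR", "MNAR" (or "MCAR")

    def write(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        self.complete.values.to_csv(
            os.path.join(directory, "complete.tsv"), sep="\t", index_label="accession"
        )
        self.amputed.values.to_csv(
            os.path.join(directory, "amputed.tsv"),
            sep="\t",
            na_rep="NA",
            index_label="accession",
        )
        pd.DataFrame(
            {"effect": self.effects, "de": self.de_labels}
        ).to_csv(os.path.join(directory, "truth.tsv"), sep="\t", index_label="accession")
        self.mechanism.to_csv(
            os.path.join(directory, "mechanism.tsv"), sep="\t", index_label="accession"
        )


def simulate_from_template(
    template: IntensityMatrix, g: SampleGroups, cfg: SimConfig
) -> IntensityMatrix:
    """Resample a dataset from a template's per-protein, per-group moments.

    For each protein and group: with >= 2 observed values, ``n_replicates``
    draws from Normal(group mean, group SD); with exactly 1, the value is
    replicated (zero SD); with 0, the simulated group stays fully missing —
    preserving the template's presence/absence rows.
    """
    if template.scale != LOG2:
        raise ValueError("template must be log2 scale")
    rng = np.random.default_rng(cfg.seed)
    labels = sorted({g.assignment[s] for s in template.sample_ids})
    cols: dict[str, np.ndarray] = {}
    n = template.n_proteins
    singles = 0
    for label in labels:
        if not any(g.assignment[s] == label for s in template.sample_ids):
            raise ValueError(f"group {label!r} absent from template")
        block = template.values[
            [s for s in template.sample_ids if g.assignment[s] == label]
        ].to_numpy(dtype=float)
        obs_n = (~np.isnan(block)).sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(block, axis=1)
            sd = np.nanstd(block, axis=1, ddof=1)
        sd = np.where(obs_n >= 2, sd, 0.0)
        singles += int((obs_n == 1).sum())
        sims = rng.normal(mean[:, None], np.maximum(sd, 0)[:, None], (n, cfg.n_replicates))
        sims[obs_n == 0] = np.nan  # group never observed stays missing
        for r in range(cfg.n_replicates):
            cols[f"{label}_{r + 1}"] = sims[:, r]
    if singles:
        warnings.warn(f"{singles} protein/group cells had one observation; replicated with SD 0")
    return IntensityMatrix(
        pd.DataFrame(cols, index=template.values.index), scale=LOG2
    )


def _shape_score(z: np.ndarray, shape: str) -> np.ndarray:
    if shape == "right":
        return z
    if shape == "left":
        return -z
    if shape == "mid":
        return -np.abs(z)
    return np.abs(z)  # tail


def _masking_probs(scores: np.ndarray, shape: str, prop: float) -> np.ndarray:
    """Logistic-link masking probabilities with mean exactly ``prop``.

    Scores are standardized, oriented by ``shape`` and pushed through a
    unit-steepness logistic whose shift is solved so the expected masked
    fraction equals the requested proportion.
    """
    if prop <= 0:
        return np.zeros_like(scores)
    if prop >= 1:
        return np.ones_like(scores)
    if shape == "mcar":
        return np.full_like(scores, prop)
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    s = _shape_score(z, shape)

    def mean_prob(shift: float) -> float:
        return float(special.expit(s - shift).mean()) - prop

    shift = optimize.brentq(mean_prob, -60.0, 60.0)
    return special.expit(s - shift)


def ampute(
    m: IntensityMatrix, cfg: AmputeConfig
) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Introduce MAR and MNAR missingness into complete rows.

    Only rows with no pre-existing missing cells are candidates. Each
    candidate row gets one randomly chosen deletion pattern; the MAR pass
    masks rows with probability driven by the weighted sum of the values
    that would remain observed, the MNAR pass by the values that would be
    deleted (left shape: low intensity, high deletion chance). A random
    allocation vector — uniform over the mechanisms with positive
    proportion — picks which pass's outcome each row takes. Returns the
    amputed matrix and the per-cell mechanism frame ("observed" / "MAR" /
    "MNAR").
    """
    vals = m.values.to_numpy(dtype=float)
    n, ncol = vals.shape
    rng = np.random.default_rng(cfg.seed)

    patterns = cfg.patterns
    if patterns is None:
        patterns = [np.eye(ncol, dtype=bool)[j] for j in range(ncol)]
    for pat in patterns:
        if pat.sum() == 0 or pat.sum() >= ncol:
            raise ValueError("each pattern must delete >= 1 and < all columns")
    weights = cfg.mar_weights if cfg.mar_weights is not None else np.ones(ncol)

    candidates = np.flatnonzero(~np.isnan(vals).any(axis=1))
    mechanism = pd.DataFrame(
        "observed", index=m.values.index, columns=m.values.columns
    )
    out = vals.copy()
    if candidates.size == 0:
        if cfg.prop_mar > 0 or cfg.prop_mnar > 0:
            raise ValueError("no complete rows eligible for amputation")
        return m.copy(), mechanism

    cand_vals = vals[candidates]
    col_sd = cand_vals.std(axis=0)
    col_z = (cand_vals - cand_vals.mean(axis=0)) / np.where(col_sd > 0, col_sd, 1.0)

    mech_masks: dict[str, np.ndarray] = {}
    mech_pats: dict[str, np.ndarray] = {}
    for mech, prop in (("mar", cfg.prop_mar), ("mnar", cfg.prop_mnar)):
        shape = cfg.prob_shape[mech]
        if mech == "mnar" and shape != "mcar":
            # the deleted value drives MNAR: pattern choice is weighted by the
            # shaped (standardized) value its deleted cells would have, so low
            # cells are preferentially deleted even when every row is amputed
            pat_scores = np.column_stack(
                [col_z[:, pat].sum(axis=1) for pat in patterns]
            )
            pref = np.exp(_shape_score(pat_scores, shape))
            pref /= pref.sum(axis=1, keepdims=True)
            pat_idx = np.array(
                [rng.choice(len(patterns), p=pref[i]) for i in range(candidates.size)]
            )
        else:
            pat_idx = rng.integers(0, len(patterns), size=candidates.size)
        pat_grid = np.vstack([patterns[k] for k in pat_idx])
        if mech == "mar":
            scores = np.where(pat_grid, 0.0, weights * cand_vals).sum(axis=1)
        else:
            scores = np.where(pat_grid, cand_vals, 0.0).sum(axis=1)
        probs = _masking_probs(scores, shape, prop)
        mech_masks[mech] = rng.random(candidates.size) < probs
        mech_pats[mech] = pat_grid

    active = [mech for mech, prop in (("mar", cfg.prop_mar), ("mnar", cfg.prop_mnar)) if prop > 0]
    if not active:
        return m.copy(), mechanism
    alloc = rng.integers(0, len(active), size=candidates.size)

    for idx in range(candidates.size):
        mech = active[alloc[idx]]
        if not mech_masks[mech][idx]:
            continue
        i = candidates[idx]
        cols = np.flatnonzero(mech_pats[mech][idx])
        out[i, cols] = np.nan
        label = "MCAR" if cfg.prob_shape[mech] == "mcar" else mech.upper()
        mechanism.iloc[i, cols] = label

    amputed = IntensityMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        scale=m.scale,
    )
    return amputed, mechanism


def generate_ground_truth(
    n_proteins: int = 1000,
    n_per_group: int = 3,
    frac_de: float = 0.5,
    effect_size_sd: float = 2.0,
    noise_sd: float = 0.5,
    missing_cfg: AmputeConfig | None = None,
    seed: int | None = None,
    group_labels: tuple[str, str] = ("treatment", "control"),
) -> GroundTruth:
    """Build a complete two-group log2 dataset with planted effects, then ampute.

    Baseline log2 abundances are Normal(20, 2); a ``frac_de`` fraction of
    proteins carries an effect drawn Normal(0, ``effect_size_sd``) added to
    the treatment group; replicates get Normal(0, ``noise_sd``) noise. The
    defaults mirror a typical whole-cell LFQ triplicate experiment with a
    strong treatment contrast.
    """
    if n_proteins < 50:
        raise ValueError("need at least 50 proteins")
    if n_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    if not (0 <= frac_de <= 1):
        raise ValueError("frac_de must be in [0, 1]")
    if noise_sd < 0 or effect_size_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)

    accessions = [f"P{i:05d}" for i in range(n_proteins)]
    baseline = rng.normal(20.0, 2.0, n_proteins)
    n_de = int(round(frac_de * n_proteins))
    effects = np.zeros(n_proteins)
    if n_de:
        de_rows = rng.choice(n_proteins, size=n_de, replace=False)
        eff = rng.normal(0.0, effect_size_sd, n_de)
        eff[eff == 0] = effect_size_sd  # degenerate draw guard
        effects[de_rows] = eff

    treat, ref = group_labels
    cols = {}
    assignment = {}
    for r in range(n_per_group):
        name = f"{treat}_{r + 1}"
        cols[name] = baseline + effects + rng.normal(0.0, noise_sd, n_proteins)
        assignment[name] = treat
    for r in range(n_per_group):
        name = f"{ref}_{r + 1}"
        cols[name] = baseline + rng.normal(0.0, noise_sd, n_proteins)
        assignment[name] = ref

    complete = IntensityMatrix(pd.DataFrame(cols, index=accessions), scale=LOG2)
    groups = SampleGroups(assignment, (treat, ref))

    missing_cfg = missing_cfg or AmputeConfig()
    if missing_cfg.seed is None:
        amp_cfg = AmputeConfig(
            prop_mar=missing_cfg.prop_mar,
            prop_mnar=missing_cfg.prop_mnar,
            patterns=missing_cfg.patterns,
            mar_weights=missing_cfg.mar_weights,
            prob_shape=dict(missing_cfg.prob_shape),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    else:
        amp_cfg = missing_cfg
    amputed, mechanism = ampute(complete, amp_cfg)

    return GroundTruth(
        complete=complete,
        amputed=amputed,
        groups=groups,
        effects=pd.Series(effects, index=accessions, name="effect"),
        de_labels=pd.Series(effects != 0, index=accessions, name="de"),
        mechanism=mechanism,
    )
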