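"""Profile normalization, cosine comparison, bootstrap, per-channel tests.

A *profile* is a non-negative weight vector over the channels of one
schema.  Group profiles are computed by normalizing each sample column to
sum one and averaging across samples, so every clone contributes equally
regardless of its mutation burden.

The bootstrap comparison redraws each sample's column as a multinomial
with the sample's own normalized profile as weights and its observed
mutation count as the draw size, aggregates per group, and averages over
replicates — a smoothed group profile whose cross-group cosine similarity
measures whether the two diets share one mutational spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import MutationCatalog
from .schemas import ChannelSchema, SchemaError

__all__ = [
    "Profile",
    "BootstrapConfig",
    "GroupProfile",
    "BootstrapComparison",
    "cosine_similarity",
    "cosine_vectors",
    "aggregate_group_profile",
    "pairwise_cosine",
    "bootstrap_profile",
    "bootstrap_group_profile",
    "group_channel_tests",
]


@dataclass
class Profile:
    """A non-negative weight vector over one schema's channels."""

    schema: ChannelSchema
    weights: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.schema),):
            raise SchemaError(
                f"profile length {self.weights.shape} does not match "
                f"schema {self.schema.name}"
            )
        if (self.weights < 0).any():
            raise ValueError("profile weights must be non-negative")
        if self.normalized and abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("normalized profile must sum to 1 within 1e-9")

    def normalize(self) -> "Profile":
        total = self.weights.sum()
        if total == 0:
            raise ValueError("cannot normalize an all-zero profile")
        return Profile(self.schema, self.weights / total, normalized=True)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.schema.labels))


@dataclass(frozen=True)
class BootstrapConfig:
    """Replicate count and seed for any bootstrap procedure.

    Defaults to 10,000 replicates as used for group-profile comparison;
    refitting bootstraps conventionally use 1000.
    """

    n_replicates: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def cosine_vectors(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def cosine_similarity(p: Profile, q: Profile) -> float:
    """Cosine similarity of two profiles on the same schema, in [0, 1]."""
    if p.schema.name != q.schema.name:
        raise SchemaError(
            f"schema mismatch: {p.schema.name} vs {q.schema.name}"
        )
    return cosine_vectors(p.weights, q.weights)


@dataclass
class GroupProfile:
    """Mean of per-sample normalized profiles with per-channel spread."""

    group: str
    profile: Profile
    sd: np.ndarray
    n_samples: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean": self.profile.weights, "sd": self.sd},
            index=list(self.profile.schema.labels),
        )


def _normalized_columns(catalog: MutationCatalog, sample_ids) -> np.ndarray:
    cols = catalog.df[list(sample_ids)].to_numpy(dtype=float)
    totals = cols.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = [s for s, z in zip(sample_ids, zero) if z]
        raise ValueError(f"sample(s) with zero mutations: {bad}")
    return cols / totals


def aggregate_group_profile(catalog: MutationCatalog, group: str) -> GroupProfile:
    """Average normalized profile of a group with per-channel sd."""
    ids = catalog.samples_in_group(group)
    rel = _normalized_columns(catalog, ids)
    mean = rel.mean(axis=1)
    sd = rel.std(axis=1, ddof=0) if rel.shape[1] > 1 else np.zeros(rel.shape[0])
    return GroupProfile(
        group=group,
        profile=Profile(catalog.schema, mean, normalized=True),
        sd=sd,
        n_samples=len(ids),
    )


def pairwise_cosine(catalog: MutationCatalog) -> tuple[pd.DataFrame, dict]:
    """All-vs-all sample cosine similarity matrix with a summary.

    Returns the symmetric samples x samples matrix (diagonal 1) and a
    summary dict with min/mean/max over the off-diagonal entries.
    """
    rel = _normalized_columns(catalog, catalog.sample_ids)
    norms = np.linalg.norm(rel, axis=0)
    sim = (rel.T @ rel) / np.outer(norms, norms)
    np.fill_diagonal(sim, 1.0)
    sim = np.clip(sim, -1.0, 1.0)
    df = pd.DataFrame(sim, index=catalog.sample_ids, columns=catalog.sample_ids)
    off = sim[~np.eye(len(sim), dtype=bool)]
    summary = {
        "min": float(off.min()) if off.size else float("nan"),
        "mean": float(off.mean()) if off.size else float("nan"),
        "max": float(off.max()) if off.size else float("nan"),
    }
    return df, summary


def bootstrap_profile(
    catalog: MutationCatalog, group: str, config: BootstrapConfig
) -> Profile:
    """Averaged bootstrap profile of one group.

    Each replicate redraws every sample column as
    multinomial(n = observed total, p = normalized profile), normalizes
    and averages across the group's samples; replicate profiles are then
    averaged.  Deterministic under the config seed.
    """
    rng = np.random.default_rng(config.seed)
    return _bootstrap_one_group(catalog, group, config.n_replicates, rng)


def _bootstrap_one_group(
    catalog: MutationCatalog, group: str, n_replicates: int, rng
) -> Profile:
    ids = catalog.samples_in_group(group)
    rel = _normalized_columns(catalog, ids)
    totals = catalog.df[ids].sum(axis=0).to_numpy()
    acc = np.zeros((n_replicates, rel.shape[0]))
    for j, sample in enumerate(ids):
        draws = rng.multinomial(int(totals[j]), rel[:, j], size=n_replicates)
        acc += draws / totals[j]
    acc /= len(ids)
    return Profile(catalog.schema, acc.mean(axis=0)).normalize()


@dataclass
class BootstrapComparison:
    """Bootstrap group profiles and their cross-group cosine similarity."""

    profiles: dict[str, Profile]
    cross_group_cosine: float
    config: BootstrapConfig


def bootstrap_group_profile(
    catalog: MutationCatalog,
    config: BootstrapConfig | None = None,
    groups: tuple[str, str] | None = None,
) -> BootstrapComparison:
    """Bootstrap both groups' profiles and compare them by cosine."""
    config = config or BootstrapConfig()
    if groups is None:
        gs = catalog.groups
        if len(gs) != 2:
            raise ValueError(
                f"need exactly two groups (got {gs}); pass groups= explicitly"
            )
        groups = (gs[0], gs[1])
    rng = np.random.default_rng(config.seed)
    profiles = {
        g: _bootstrap_one_group(catalog, g, config.n_replicates, rng)
        for g in groups
    }
    cos = cosine_similarity(profiles[groups[0]], profiles[groups[1]])
    return BootstrapComparison(profiles=profiles, cross_group_cosine=cos, config=config)


def group_channel_tests(
    catalog: MutationCatalog,
    groups: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-channel two-sided Welch t-tests between groups with Holm–Šidák
    correction.

    Operates on per-sample mutation *counts* per channel (typically of an
    SBS7 or ID16 catalog).  Returns one row per channel with the t
    statistic, raw and adjusted p-values, and a significance flag at
    ``alpha``.
    """
    if groups is None:
        gs = catalog.groups
        if len(gs) != 2:
            raise ValueError("need exactly two groups; pass groups= explicitly")
        groups = (gs[0], gs[1])
    a_ids = catalog.samples_in_group(groups[0])
    b_ids = catalog.samples_in_group(groups[1])
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    a = catalog.df[a_ids].to_numpy(dtype=float)
    b = catalog.df[b_ids].to_numpy(dtype=float)
    tstat, praw = stats.ttest_ind(a, b, axis=1, equal_var=False)
    praw = np.where(np.isnan(praw), 1.0, praw)
    tstat = np.where(np.isnan(tstat), 0.0, tstat)
    reject, padj, _, _ = multipletests(praw, alpha=alpha, method="holm-sidak")
    return pd.DataFrame(
        {
            "t": tstat,
            "p_raw": praw,
            "p_adj": padj,
            "significant": reject,
        },
        index=list(catalog.schema.labels),
    )
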