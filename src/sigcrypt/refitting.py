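"""Signature refitting: attribute mutation catalogs to known signatures.

Four procedures:

* plain non-negative least-squares refit (:func:`nnls_refit`);
* best-subset ("strict") refit by backward elimination — repeatedly drop
  the lowest-contributing signature while the reconstruction cosine of
  the sample degrades by at most ``max_delta`` (:func:`best_subset_refit`);
* bootstrapped refit — multinomial resampling of each sample's profile,
  best-subset refit per replicate, summarized as the fraction of
  replicates in which each signature was found active
  (:func:`bootstrap_refit`);
* the signature presence test — a likelihood-ratio test between the
  Poisson maximum-likelihood refit with and without a target signature,
  with a boundary-corrected halved chi-square(1) p-value
  (:func:`presence_test`).

:class:`SignatureRefit` wraps these as a model object:
``SignatureRefit(catalog, signatures).fit(method="strict")`` returns a
:class:`RefitResults` carrying exposures, reconstruction diagnostics, an
elimination trace, and a ``summary()`` table; ``fit_bootstrap`` and
``presence_test`` hang off the same object.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import chi2

from .catalog import ExposureMatrix, MutationCatalog, SignatureSet
from .nmf import fit_exposures_kl, poisson_loglik
from .profiles import BootstrapConfig, cosine_vectors
from .schemas import SchemaError

__all__ = [
    "BestSubsetResult",
    "BootstrapRefitResult",
    "PresenceTestResult",
    "SignatureRefit",
    "RefitResults",
    "nnls_refit",
    "best_subset_refit",
    "exhaustive_best_subset",
    "bootstrap_refit",
    "presence_test",
]


def _check_schema(catalog: MutationCatalog, signatures: SignatureSet) -> None:
    if catalog.schema.name != signatures.schema.name:
        raise SchemaError(
            f"catalog schema {catalog.schema.name} does not match "
            f"signature schema {signatures.schema.name}"
        )


def _collinearity_warning(signatures: SignatureSet, threshold: float = 0.95) -> None:
    S = signatures.matrix
    ids = signatures.signature_ids
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if cosine_vectors(S[:, i], S[:, j]) > threshold:
                pairs.append((ids[i], ids[j]))
    if pairs:
        warnings.warn(
            f"near-duplicate signature pairs (cosine > {threshold}): {pairs}"
        )


def nnls_refit(
    catalog: MutationCatalog, signatures: SignatureSet
) -> ExposureMatrix:
    """Per-sample non-negative least-squares exposures, in mutation counts.

    Minimizes ||m_j - S e_j||^2 over e_j >= 0 for every sample column.
    Since signature columns sum to one, exposures are on the mutation-count
    scale directly.  Near-collinear signature pairs trigger a warning.
    """
    _check_schema(catalog, signatures)
    _collinearity_warning(signatures)
    S = signatures.matrix
    M = catalog.matrix.astype(float)
    E = np.zeros((S.shape[1], M.shape[1]))
    for j in range(M.shape[1]):
        E[:, j], _ = nnls(S, M[:, j])
    return ExposureMatrix(
        pd.DataFrame(E, index=signatures.signature_ids, columns=catalog.sample_ids)
    )


@dataclass
class BestSubsetResult:
    """Best-subset refit of one or more samples."""

    selected: dict[str, list[str]]  # sample -> retained signature ids
    exposures: ExposureMatrix
    final_cosine: pd.Series  # per sample
    trace: pd.DataFrame  # sample, removed, cosine_before, cosine_after, delta, accepted


def _refit_one(m: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, float]:
    e, _ = nnls(S, m)
    recon = S @ e
    cos = cosine_vectors(m, recon) if recon.sum() > 0 else 0.0
    return e, cos


def _best_subset_one(
    m: np.ndarray, S: np.ndarray, ids: list[str], max_delta: float
) -> tuple[list[int], np.ndarray, float, list[dict]]:
    active = list(range(S.shape[1]))
    e, cos = _refit_one(m, S[:, active])
    trace: list[dict] = []
    while len(active) > 1:
        lowest = active[int(np.argmin(e))]
        trial = [i for i in active if i != lowest]
        e_new, cos_new = _refit_one(m, S[:, trial])
        delta = cos - cos_new
        accepted = delta <= max_delta
        trace.append(
            {
                "removed": ids[lowest],
                "cosine_before": cos,
                "cosine_after": cos_new,
                "delta": delta,
                "accepted": accepted,
            }
        )
        if not accepted:
            break
        active, e, cos = trial, e_new, cos_new
    return active, e, cos, trace


def best_subset_refit(
    catalog: MutationCatalog,
    signatures: SignatureSet,
    max_delta: float = 0.004,
) -> BestSubsetResult:
    """Backward-elimination sparse refit, per sample.

    Iteratively removes the lowest-contributing signature as long as the
    sample's reconstruction cosine decreases by at most ``max_delta``;
    the first rejected removal stops the elimination.  Signatures not
    retained for a sample get exposure zero.
    """
    _check_schema(catalog, signatures)
    if max_delta < 0:
        raise ValueError("max_delta must be >= 0")
    if max_delta >= 1:
        raise ValueError(
            "max_delta >= 1 would allow eliminating every signature; "
            "use a smaller threshold"
        )
    S = signatures.matrix
    ids = signatures.signature_ids
    M = catalog.matrix.astype(float)
    E = np.zeros((len(ids), M.shape[1]))
    selected: dict[str, list[str]] = {}
    cosines = {}
    trace_rows: list[dict] = []
    for j, sample in enumerate(catalog.sample_ids):
        active, e, cos, trace = _best_subset_one(M[:, j], S, ids, max_delta)
        E[active, j] = e
        selected[sample] = [ids[i] for i in sorted(active)]
        cosines[sample] = cos
        for row in trace:
            trace_rows.append({"sample_id": sample, **row})
    return BestSubsetResult(
        selected=selected,
        exposures=ExposureMatrix(
            pd.DataFrame(E, index=ids, columns=catalog.sample_ids)
        ),
        final_cosine=pd.Series(cosines),
        trace=pd.DataFrame(
            trace_rows,
            columns=["sample_id", "removed", "cosine_before",
                     "cosine_after", "delta", "accepted"],
        ),
    )


def exhaustive_best_subset(
    m: np.ndarray,
    signatures: SignatureSet,
    max_delta: float = 0.004,
) -> tuple[list[str], np.ndarray, float]:
    """Exhaustive best-subset oracle for small reference sets (n <= 12).

    Among all non-empty subsets whose reconstruction cosine is within
    ``max_delta`` of the full-set cosine, returns the smallest (ties by
    higher cosine).  Used as a cross-check for the greedy elimination.
    """
    ids = signatures.signature_ids
    if len(ids) > 12:
        raise ValueError("exhaustive search is limited to <= 12 signatures")
    S = signatures.matrix
    m = np.asarray(m, dtype=float)
    _, full_cos = _refit_one(m, S)
    best: tuple[int, float, list[int], np.ndarray] | None = None
    for size in range(1, len(ids) + 1):
        for combo in itertools.combinations(range(len(ids)), size):
            e, cos = _refit_one(m, S[:, list(combo)])
            if cos >= full_cos - max_delta:
                key = (size, -cos)
                if best is None or key < (best[0], -best[1]):
                    best = (size, cos, list(combo), e)
        if best is not None and best[0] == size:
            break  # no smaller subset can appear at larger sizes
    assert best is not None
    _, cos, combo, e = best
    return [ids[i] for i in combo], e, cos


@dataclass
class BootstrapRefitResult:
    """Stability of a best-subset refit under profile resampling."""

    found_fraction: pd.DataFrame  # signatures x samples, in [0, 1]
    mean_contribution: pd.DataFrame  # mean exposure over replicates where found
    config: BootstrapConfig


def bootstrap_refit(
    catalog: MutationCatalog,
    signatures: SignatureSet,
    config: BootstrapConfig | None = None,
    max_delta: float = 0.004,
) -> BootstrapRefitResult:
    """Bootstrapped best-subset refit.

    Each replicate redraws every sample column as multinomial(n =
    observed total, p = normalized observed profile) and re-runs the
    best-subset refit; ``found_fraction`` is the fraction of replicates
    with a nonzero exposure per (signature, sample).
    """
    _check_schema(catalog, signatures)
    config = config or BootstrapConfig(n_replicates=1000)
    totals = catalog.totals
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-mutation sample(s): {list(zero.index)}")
    rng = np.random.default_rng(config.seed)
    M = catalog.matrix.astype(float)
    rel = M / M.sum(axis=0)
    S = signatures.matrix
    ids = signatures.signature_ids
    found = np.zeros((len(ids), M.shape[1]))
    contrib_sum = np.zeros_like(found)
    for _ in range(config.n_replicates):
        for j, sample in enumerate(catalog.sample_ids):
            m_rep = rng.multinomial(int(totals.iloc[j]), rel[:, j]).astype(float)
            active, e, _, _ = _best_subset_one(m_rep, S, ids, max_delta)
            nz = [i for i, v in zip(active, e) if v > 0]
            vals = [v for v in e if v > 0]
            found[nz, j] += 1
            contrib_sum[nz, j] += vals
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_contrib = np.where(found > 0, contrib_sum / found, 0.0)
    found /= config.n_replicates
    return BootstrapRefitResult(
        found_fraction=pd.DataFrame(found, index=ids, columns=catalog.sample_ids),
        mean_contribution=pd.DataFrame(
            mean_contrib, index=ids, columns=catalog.sample_ids
        ),
        config=config,
    )


@dataclass
class PresenceTestResult:
    """Likelihood-ratio test for one signature's activity in one sample."""

    sample_id: str
    signature_id: str
    loglik_with: float
    loglik_without: float
    llr: float
    p_value: float
    non_identifiable: bool = False


def _poisson_refit_loglik(
    m: np.ndarray, S: np.ndarray, init: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    e = fit_exposures_kl(m, S, init=init)
    return e, poisson_loglik(m, S @ e)


def presence_test(
    sample_profile: np.ndarray | pd.Series,
    signatures: SignatureSet,
    target: str,
    sample_id: str = "",
) -> PresenceTestResult:
    """Signature presence test under an independent-Poisson model.

    Both models maximize the Poisson log-likelihood over non-negative
    exposures (by KL multiplicative updates); the with-model includes the
    target signature, the without-model excludes it.  Since the null
    (exposure 0) lies on the boundary of the parameter space, the p-value
    is the boundary-corrected 0.5 * P(chi2_1 > 2 * llr).
    """
    if target not in signatures.signature_ids:
        raise KeyError(f"target {target!r} not in signature set")
    if isinstance(sample_profile, pd.Series):
        sample_profile = sample_profile.reindex(
            list(signatures.schema.labels)
        ).to_numpy()
    m = np.asarray(sample_profile, dtype=float)
    if m.sum() <= 0:
        raise ValueError("sample has no mutations")

    ids = signatures.signature_ids
    t = ids.index(target)
    others = [i for i in range(len(ids)) if i != t]
    S = signatures.matrix

    non_identifiable = any(
        cosine_vectors(S[:, t], S[:, j]) > 0.999 for j in others
    )

    e_wo, ll_without = _poisson_refit_loglik(m, S[:, others])
    # With-model: uniform init, plus the without-optimum seeded with a small
    # positive target exposure (a zero can never move under multiplicative
    # updates); the better of the two guarantees nesting.
    order = others + [t]
    S_with = S[:, order]
    _, ll_uniform = _poisson_refit_loglik(m, S_with)
    seed_init = np.append(np.maximum(e_wo, 1e-6), max(m.sum() * 1e-3, 1e-6))
    _, ll_seeded = _poisson_refit_loglik(m, S_with, init=seed_init)
    ll_with = max(ll_uniform, ll_seeded, ll_without)

    llr = max(ll_with - ll_without, 0.0)
    p = 0.5 * float(chi2.sf(2.0 * llr, df=1))
    return PresenceTestResult(
        sample_id=sample_id,
        signature_id=target,
        loglik_with=ll_with,
        loglik_without=ll_without,
        llr=llr,
        p_value=p,
        non_identifiable=non_identifiable,
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class SignatureRefit:
    """Refitting model: one catalog against one known-signature set.

    Examples
    --------
    >>> model = SignatureRefit(catalog, cosmic_like)
    >>> res = model.fit(method="strict", max_delta=0.004)  # doctest: +SKIP
    >>> print(res.summary())                               # doctest: +SKIP
    """

    def __init__(self, catalog: MutationCatalog, signatures: SignatureSet) -> None:
        _check_schema(catalog, signatures)
        self.catalog = catalog
        self.signatures = signatures

    def fit(self, method: str = "strict", max_delta: float = 0.004) -> "RefitResults":
        if method == "plain":
            exposures = nnls_refit(self.catalog, self.signatures)
            S, M = self.signatures.matrix, self.catalog.matrix.astype(float)
            recon = S @ exposures.matrix
            cosines = pd.Series(
                {
                    s: cosine_vectors(M[:, j], recon[:, j])
                    for j, s in enumerate(self.catalog.sample_ids)
                }
            )
            subset = BestSubsetResult(
                selected={
                    s: list(self.signatures.signature_ids)
                    for s in self.catalog.sample_ids
                },
                exposures=exposures,
                final_cosine=cosines,
                trace=pd.DataFrame(
                    columns=["sample_id", "removed", "cosine_before",
                             "cosine_after", "delta", "accepted"]
                ),
            )
        elif method == "strict":
            subset = best_subset_refit(self.catalog, self.signatures, max_delta)
        else:
            raise ValueError(f"unknown method {method!r} (plain or strict)")
        return RefitResults(model=self, method=method, max_delta=max_delta, result=subset)

    def fit_bootstrap(
        self, config: BootstrapConfig | None = None, max_delta: float = 0.004
    ) -> BootstrapRefitResult:
        return bootstrap_refit(self.catalog, self.signatures, config, max_delta)

    def presence_test(self, targets: list[str] | None = None) -> pd.DataFrame:
        """Presence test for each target signature in every sample."""
        targets = targets or self.signatures.signature_ids
        rows = []
        for sample in self.catalog.sample_ids:
            m = self.catalog.df[sample]
            for target in targets:
                r = presence_test(m, self.signatures, target, sample_id=sample)
                rows.append(
                    {
                        "sample_id": r.sample_id,
                        "signature_id": r.signature_id,
                        "loglik_with": r.loglik_with,
                        "loglik_without": r.loglik_without,
                        "llr": r.llr,
                        "p_value": r.p_value,
                        "non_identifiable": r.non_identifiable,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class RefitResults:
    """Results of a fitted :class:`SignatureRefit`."""

    model: SignatureRefit
    method: str
    max_delta: float
    result: BestSubsetResult

    @property
    def exposures(self) -> ExposureMatrix:
        return self.result.exposures

    @property
    def selected(self) -> dict[str, list[str]]:
        return self.result.selected

    @property
    def final_cosine(self) -> pd.Series:
        return self.result.final_cosine

    @property
    def trace(self) -> pd.DataFrame:
        return self.result.trace

    def explained_fraction(self) -> pd.Series:
        """Attributed / observed mutations per sample."""
        return self.exposures.df.sum(axis=0) / self.model.catalog.totals

    def summary(self) -> str:
        exp = self.exposures.df
        active = exp.index[(exp > 0).any(axis=1)]
        lines = [
            f"Signature refit ({self.method}"
            + (f", max_delta={self.max_delta}" if self.method == "strict" else "")
            + ")",
            f"  catalog: {self.model.catalog.schema.name}, "
            f"{len(self.model.catalog.sample_ids)} samples",
            f"  reference set: {len(self.model.signatures)} signatures, "
            f"{len(active)} active after refit",
            f"  reconstruction cosine: min {self.final_cosine.min():.4f}, "
            f"mean {self.final_cosine.mean():.4f}",
            "",
            "  mean exposure (mutations) of active signatures:",
        ]
        means = exp.loc[active].mean(axis=1).sort_values(ascending=False)
        for sid, v in means.items():
            lines.append(f"    {sid}: {v:.1f}")
        return "\n".join(lines)
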