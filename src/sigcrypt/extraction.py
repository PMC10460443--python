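"""De-novo signature extraction with automated rank selection, and
decomposition of de-novo signatures into a reference catalog.

The number of signatures (the NMF rank) is chosen by the stability /
accuracy tradeoff: for every candidate rank the catalog is Poisson-
perturbed ``n_resamples`` times, each copy factorized from ``n_inits``
random starts keeping the best objective, and the pooled signature
columns are clustered by greedy cosine matching against the
best-objective factorization of the original catalog.  Average stability
(AS) is the mean silhouette width of the pooled columns under cosine
distance; accuracy is the mean sample cosine distance (MSCD) between the
original columns and their reconstruction from the consensus signatures.
The chosen rank is the stable rank (AS >= ``stability_min``) with the
smallest MSCD, ties to the smaller rank; if no rank is stable, the
smallest evaluated rank.

:class:`SignatureExtraction` is the model-object entry point:
``SignatureExtraction(catalog).fit(seed=0)`` returns an
:class:`ExtractionResults` with the per-rank diagnostics, the consensus
signatures and exposures at the chosen rank, and a ``summary()`` table.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.metrics import silhouette_score

from .catalog import ExposureMatrix, MutationCatalog, SignatureSet
from .nmf import NMFResult, nmf_factorize_matrix
from .profiles import cosine_vectors

__all__ = [
    "RankSelectionResult",
    "DecompositionResult",
    "SignatureExtraction",
    "ExtractionResults",
    "nmf_factorize",
    "select_rank",
    "decompose_to_reference",
]


def _signature_labels(schema_name: str, k: int) -> list[str]:
    letters = string.ascii_uppercase
    return [f"{schema_name}-{letters[i]}" for i in range(k)]


def nmf_factorize(
    catalog: MutationCatalog,
    k: int,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> tuple[SignatureSet, ExposureMatrix, NMFResult]:
    """Single NMF factorization of a catalog at rank ``k``.

    Returns the column-stochastic signatures, the exposure matrix in
    mutation counts, and the raw result (divergence, convergence flag).
    """
    res = nmf_factorize_matrix(
        catalog.matrix, k, seed=seed, max_iter=max_iter, tol=tol
    )
    if not res.converged:
        warnings.warn(
            f"NMF at rank {k} did not converge in {res.n_iter} iterations"
        )
    ids = _signature_labels(catalog.schema.name, k)
    S = SignatureSet(
        pd.DataFrame(res.W, index=list(catalog.schema.labels), columns=ids),
        catalog.schema,
    )
    E = ExposureMatrix(pd.DataFrame(res.H, index=ids, columns=catalog.sample_ids))
    return S, E, res


def _best_of_inits(M, k, rng, n_inits, max_iter, tol) -> NMFResult:
    best: NMFResult | None = None
    for _ in range(n_inits):
        res = nmf_factorize_matrix(M, k, seed=rng, max_iter=max_iter, tol=tol)
        if best is None or res.divergence < best.divergence:
            best = res
    return best


def _greedy_match(cols: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Assign each column of ``cols`` to a distinct reference column by
    descending cosine; returns the label per column."""
    k = ref.shape[1]
    sim = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            sim[i, j] = cosine_vectors(cols[:, i], ref[:, j])
    labels = np.full(k, -1)
    used_rows, used_cols = set(), set()
    flat = [(-sim[i, j], i, j) for i in range(k) for j in range(k)]
    for _, i, j in sorted(flat):
        if i in used_rows or j in used_cols:
            continue
        labels[i] = j
        used_rows.add(i)
        used_cols.add(j)
    return labels


def _nnls_exposures(M: np.ndarray, S: np.ndarray) -> np.ndarray:
    E = np.zeros((S.shape[1], M.shape[1]))
    for j in range(M.shape[1]):
        E[:, j], _ = nnls(S, M[:, j])
    return E


def _mscd(M: np.ndarray, S: np.ndarray) -> tuple[float, np.ndarray]:
    E = _nnls_exposures(M, S)
    recon = S @ E
    dists = np.array(
        [1.0 - cosine_vectors(M[:, j], np.maximum(recon[:, j], 1e-12))
         for j in range(M.shape[1])]
    )
    return float(dists.mean()), E


@dataclass
class RankSelectionResult:
    """Per-rank stability/accuracy diagnostics and the chosen rank."""

    table: pd.DataFrame  # index k, columns stability / mscd
    chosen_rank: int
    per_rank_signatures: dict[int, SignatureSet]
    per_rank_exposures: dict[int, ExposureMatrix]

    @property
    def signatures(self) -> SignatureSet:
        return self.per_rank_signatures[self.chosen_rank]

    @property
    def exposures(self) -> ExposureMatrix:
        return self.per_rank_exposures[self.chosen_rank]


def select_rank(
    catalog: MutationCatalog,
    k_range: tuple[int, ...] = (1, 2, 3, 4),
    n_resamples: int = 30,
    n_inits: int = 10,
    seed: int = 0,
    stability_min: float = 0.8,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> RankSelectionResult:
    """NMFk-style automated rank selection (see module docstring).

    Deterministic under ``seed``.  A rank whose pooled solutions cannot
    support a silhouette (fewer pooled columns than clusters + 1) is
    skipped with a warning.
    """
    if not k_range:
        raise ValueError("k_range must be non-empty")
    M = catalog.matrix.astype(float)
    rng = np.random.default_rng(seed)
    rows = []
    per_rank_S: dict[int, SignatureSet] = {}
    per_rank_E: dict[int, ExposureMatrix] = {}

    for k in sorted(k_range):
        reference = _best_of_inits(M, k, rng, n_inits, max_iter, tol)
        pooled: list[np.ndarray] = []
        labels: list[int] = []
        for _ in range(n_resamples):
            Mp = rng.poisson(M).astype(float)
            Mp[:, Mp.sum(axis=0) == 0] += 1e-9  # guard degenerate resample
            res = _best_of_inits(Mp, k, rng, n_inits, max_iter, tol)
            assign = _greedy_match(res.W, reference.W)
            for i in range(k):
                pooled.append(res.W[:, i])
                labels.append(int(assign[i]))
        X = np.array(pooled)
        lab = np.array(labels)
        if k == 1:
            stability = 1.0  # single-cluster silhouette is undefined
        else:
            if len(X) <= k or len(np.unique(lab)) < 2:
                warnings.warn(
                    f"rank {k}: too few pooled solutions for a silhouette; skipped"
                )
                continue
            stability = float(silhouette_score(X, lab, metric="cosine"))
        consensus = np.zeros((M.shape[0], k))
        for c in range(k):
            members = X[lab == c]
            col = members.mean(axis=0) if len(members) else reference.W[:, c]
            consensus[:, c] = col / col.sum()
        mscd, E = _mscd(M, consensus)
        rows.append({"k": k, "stability": stability, "mscd": mscd})
        ids = _signature_labels(catalog.schema.name, k)
        per_rank_S[k] = SignatureSet(
            pd.DataFrame(consensus, index=list(catalog.schema.labels), columns=ids),
            catalog.schema,
        )
        per_rank_E[k] = ExposureMatrix(
            pd.DataFrame(E, index=ids, columns=catalog.sample_ids)
        )

    if not rows:
        raise ValueError("no rank could be evaluated")
    table = pd.DataFrame(rows).set_index("k")
    stable = table[table["stability"] >= stability_min]
    if len(stable):
        chosen = int(stable["mscd"].idxmin())
        best = stable["mscd"].min()
        ties = stable[np.isclose(stable["mscd"], best)]
        chosen = int(min(ties.index.min(), chosen))
    else:
        chosen = int(table.index.min())
    return RankSelectionResult(
        table=table,
        chosen_rank=chosen,
        per_rank_signatures=per_rank_S,
        per_rank_exposures=per_rank_E,
    )


@dataclass
class DecompositionResult:
    """Percent contributions of reference signatures to one de-novo
    signature, with the residual cosine of the reconstruction."""

    weights: pd.Series  # percent per selected reference signature, sums to 100
    residual_cosine: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        total = float(self.weights.sum())
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"weights must sum to 100, got {total}")


def decompose_to_reference(
    signature: np.ndarray | pd.Series,
    reference: SignatureSet,
    min_gain: float = 0.01,
) -> DecompositionResult:
    """Forward-selection decomposition of a signature onto a reference set.

    Starting from the empty set, repeatedly add the reference signature
    whose inclusion (non-negative least-squares refit) raises the cosine
    between reconstruction and target by at least ``min_gain``; stop when
    no candidate achieves that.  If even the first candidate falls short
    of ``min_gain``, the single best signature is returned flagged
    ``low_confidence``.
    """
    if isinstance(signature, pd.Series):
        signature = signature.reindex(list(reference.schema.labels)).to_numpy()
    sig = np.asarray(signature, dtype=float)
    sig = sig / sig.sum()
    R = reference.matrix
    ids = reference.signature_ids
    if not ids:
        raise ValueError("reference set is empty")

    selected: list[int] = []
    current_cos = 0.0
    coefs = np.zeros(0)
    while len(selected) < len(ids):
        best_j, best_cos, best_coefs = None, current_cos, None
        for j in range(len(ids)):
            if j in selected:
                continue
            cols = R[:, selected + [j]]
            c, _ = nnls(cols, sig)
            recon = cols @ c
            if recon.sum() <= 0:
                continue
            cos = cosine_vectors(recon, sig)
            if cos > best_cos:
                best_j, best_cos, best_coefs = j, cos, c
        if best_j is None or best_cos - current_cos < min_gain:
            if not selected:
                # No single signature clears the gain bar; report the best
                # one anyway, flagged.
                sims = [cosine_vectors(R[:, j], sig) for j in range(len(ids))]
                j = int(np.argmax(sims))
                return DecompositionResult(
                    weights=pd.Series({ids[j]: 100.0}),
                    residual_cosine=float(sims[j]),
                    low_confidence=True,
                )
            break
        selected.append(best_j)
        current_cos, coefs = best_cos, best_coefs

    weights = coefs / coefs.sum() * 100.0
    return DecompositionResult(
        weights=pd.Series(weights, index=[ids[j] for j in selected]),
        residual_cosine=current_cos,
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class SignatureExtraction:
    """De-novo signature extraction model for one mutation catalog.

    Parameters mirror :func:`select_rank`; ``fit`` runs the rank scan and
    returns an :class:`ExtractionResults`.

    Examples
    --------
    >>> model = SignatureExtraction(catalog, k_range=(1, 2, 3, 4))
    >>> res = model.fit(seed=0)                            # doctest: +SKIP
    >>> res.chosen_rank                                    # doctest: +SKIP
    1
    """

    def __init__(
        self,
        catalog: MutationCatalog,
        k_range: tuple[int, ...] = (1, 2, 3, 4),
        n_resamples: int = 30,
        n_inits: int = 10,
        stability_min: float = 0.8,
        max_iter: int = 10_000,
        tol: float = 1e-8,
    ) -> None:
        self.catalog = catalog
        self.k_range = tuple(k_range)
        self.n_resamples = n_resamples
        self.n_inits = n_inits
        self.stability_min = stability_min
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, seed: int = 0) -> "ExtractionResults":
        selection = select_rank(
            self.catalog,
            k_range=self.k_range,
            n_resamples=self.n_resamples,
            n_inits=self.n_inits,
            seed=seed,
            stability_min=self.stability_min,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        return ExtractionResults(model=self, selection=selection, seed=seed)


@dataclass
class ExtractionResults:
    """Results of a fitted :class:`SignatureExtraction`."""

    model: SignatureExtraction
    selection: RankSelectionResult
    seed: int
    decompositions: dict[str, DecompositionResult] = field(default_factory=dict)

    @property
    def chosen_rank(self) -> int:
        return self.selection.chosen_rank

    @property
    def signatures(self) -> SignatureSet:
        return self.selection.signatures

    @property
    def exposures(self) -> ExposureMatrix:
        return self.selection.exposures

    @property
    def rank_table(self) -> pd.DataFrame:
        return self.selection.table

    def decompose(
        self, reference: SignatureSet, min_gain: float = 0.01
    ) -> dict[str, DecompositionResult]:
        """Decompose every consensus signature onto a reference catalog."""
        out = {}
        for sid in self.signatures.signature_ids:
            out[sid] = decompose_to_reference(
                self.signatures.df[sid], reference, min_gain=min_gain
            )
        self.decompositions = out
        return out

    def summary(self) -> str:
        lines = [
            "De-novo signature extraction (KL-NMF, NMFk rank selection)",
            f"  catalog: {self.model.catalog.schema.name}, "
            f"{len(self.model.catalog.sample_ids)} samples, "
            f"{int(self.model.catalog.totals.sum())} mutations",
            f"  ranks evaluated: {list(self.rank_table.index)}  "
            f"(resamples={self.model.n_resamples}, inits={self.model.n_inits})",
            "",
            self.rank_table.to_string(
                float_format=lambda x: f"{x:.4f}", header=["AS", "MSCD"]
            ),
            "",
            f"  chosen rank: {self.chosen_rank}",
        ]
        if self.decompositions:
            lines.append("  decomposition onto reference signatures:")
            for sid, dec in self.decompositions.items():
                parts = ", ".join(
                    f"{name} {w:.1f}%" for name, w in dec.weights.items()
                )
                flag = "  [low confidence]" if dec.low_confidence else ""
                lines.append(
                    f"    {sid}: {parts} (cosine {dec.residual_cosine:.4f}){flag}"
                )
        return "\n".join(lines)
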