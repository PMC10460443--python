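"""Non-negative matrix factorization under generalized Kullback–Leibler
divergence, by multiplicative updates.

The generalized KL divergence D(M || WH) = sum m log(m/x) - m + x is, up
to a constant in M, the negative Poisson log-likelihood of counts M with
mean WH — the natural objective for mutation-count catalogs.  The classic
multiplicative updates never increase it, which the test suite asserts
per iteration on small instances.

W (channels x k) is kept column-stochastic by pushing column scales into
H after every update, so W columns are directly interpretable as
signatures and H rows as mutation counts attributed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = ["NMFResult", "kl_divergence", "nmf_factorize_matrix", "fit_exposures_kl", "poisson_loglik"]

_EPS = 1e-12


def kl_divergence(M: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(M || WH) >= 0."""
    M = np.asarray(M, dtype=float)
    WH = np.maximum(WH, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(M > 0, M * np.log(M / WH), 0.0)
    return float(term.sum() - M.sum() + WH.sum())


def poisson_loglik(m: np.ndarray, mu: np.ndarray) -> float:
    """Independent-Poisson log-likelihood sum m log mu - mu - log m!."""
    m = np.asarray(m, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _EPS)
    return float(np.sum(m * np.log(mu) - mu - gammaln(m + 1.0)))


@dataclass
class NMFResult:
    W: np.ndarray  # channels x k, column-stochastic
    H: np.ndarray  # k x samples, counts scale
    divergence: float
    n_iter: int
    converged: bool
    objective_history: list[float] | None = None


def _normalize_WH(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scale = W.sum(axis=0)
    scale = np.maximum(scale, _EPS)
    return W / scale, H * scale[:, None]


def nmf_factorize_matrix(
    M: np.ndarray,
    k: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    check_every: int = 10,
    track_objective: bool = False,
) -> NMFResult:
    """Factorize a non-negative matrix as W @ H at rank ``k``.

    Runs multiplicative KL updates from a random (seeded) initialization
    until the relative change of the objective between checks falls below
    ``tol`` or ``max_iter`` iterations are reached (the result then
    carries ``converged=False``).
    """
    M = np.asarray(M, dtype=float)
    if (M < 0).any():
        raise ValueError("input matrix must be non-negative")
    if (M.sum(axis=0) == 0).any():
        raise ValueError("input matrix has an all-zero column")
    n_channels, n_samples = M.shape
    if not 1 <= k <= min(n_channels, n_samples):
        raise ValueError(
            f"rank {k} outside [1, {min(n_channels, n_samples)}]"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_scale = M.mean() / k
    W = rng.uniform(0.5, 1.5, size=(n_channels, k))
    H = rng.uniform(0.5, 1.5, size=(k, n_samples)) * mean_scale
    W, H = _normalize_WH(W, H)

    prev = kl_divergence(M, W @ H)
    history = [prev] if track_objective else None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WH = np.maximum(W @ H, _EPS)
        H *= W.T @ (M / WH)  # W columns sum to 1, denominator is 1
        WH = np.maximum(W @ H, _EPS)
        W *= (M / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
        W, H = _normalize_WH(W, H)
        if track_objective:
            history.append(kl_divergence(M, W @ H))
        if it % check_every == 0:
            cur = kl_divergence(M, W @ H)
            denom = max(abs(prev), _EPS)
            if abs(prev - cur) / denom < tol:
                converged = True
                prev = cur
                break
            prev = cur
    return NMFResult(
        W=W, H=H, divergence=kl_divergence(M, W @ H), n_iter=it,
        converged=converged, objective_history=history,
    )


def fit_exposures_kl(
    m: np.ndarray,
    S: np.ndarray,
    max_iter: int = 5000,
    tol: float = 1e-10,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Maximum-likelihood Poisson exposures of one sample to fixed signatures.

    Multiplicative updates on the exposure vector only (S column-stochastic
    and fixed); equivalently minimizes KL(m || S e).  ``init`` must be
    strictly positive where an exposure should be allowed to move — a zero
    stays zero under multiplicative updates.
    """
    m = np.asarray(m, dtype=float)
    S = np.asarray(S, dtype=float)
    k = S.shape[1]
    e = np.full(k, m.sum() / k) if init is None else np.array(init, dtype=float)
    prev = None
    for it in range(1, max_iter + 1):
        mu = np.maximum(S @ e, _EPS)
        e = e * (S.T @ (m / mu))
        if it % 20 == 0:
            cur = kl_divergence(m, np.maximum(S @ e, _EPS))
            if prev is not None and abs(prev - cur) / max(abs(prev), _EPS) < tol:
                break
            prev = cur
    return e
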