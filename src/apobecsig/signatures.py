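"""De novo mutational-signature extraction by Bayesian NMF.

Factorizes a samples x 96 mutation catalog V as V ~ W H under a
Poisson (generalized Kullback–Leibler) objective with automatic
relevance determination (ARD): each latent component k carries an
exponential (L1) prior on its signature and exposure entries with a
shared scale lambda_k, itself under an inverse-gamma hyperprior.
Maximum a posteriori estimation by multiplicative updates shrinks the
scales of unneeded components toward zero, so the number of signatures
is selected automatically: components whose relevance falls below a
fraction of the largest are pruned.

The penalized objective minimized is

    C(W, H, lambda) = D_KL(V | W H)
        + sum_k [ (|w_k|_1 + |h_k|_1 + b) / lambda_k
                  + (F + N + a + 1) log lambda_k ]

with F = 96 channels, N samples, and inverse-gamma hyperparameters
(a, b). lambda has a closed-form update; W and H use standard
majorization–minimization multiplicative rules, so C is non-increasing
across iterations.

Extracted signatures are L1-normalized (rows sum to 1) with the scale
absorbed into the exposures, and relabeled W1..Wk in decreasing order
of total exposure. Cosine similarity against a reference signature set
(COSMIC v2 layout) identifies known processes such as the APOBEC
signatures 2 and 13.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from apobecsig.catalog import CHANNELS, CatalogMatrix, FormatError

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class SignatureSet:
    """Signatures (K x 96, rows sum to 1) and per-sample exposures (N x K)."""

    signatures: np.ndarray
    exposures: np.ndarray
    selected_rank: int
    run_seed: int
    converged: bool
    sample_ids: list[str] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    relevance: np.ndarray | None = None
    objective: float = float("nan")

    def signatures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.signatures, index=self.labels, columns=list(CHANNELS))

    def exposures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.exposures,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.labels,
        )


@dataclass
class StabilityReport:
    """Rank-selection recurrence across repeated NMF restarts."""

    n_runs: int
    rank_histogram: dict[int, float]
    modal_rank: int
    seeds: list[int]
    n_failed: int = 0


@dataclass
class CosineMatrix:
    """Cosine similarities of extracted vs reference signatures."""

    matrix: pd.DataFrame
    best_match: pd.DataFrame  # per extracted signature: reference label, similarity


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V[mask].sum() + WH.sum())
    return div


def _ard_objective(V, W, H, lam, b, c) -> float:
    WH = W @ H + _EPS
    penalty = float(
        ((W.sum(axis=0) + H.sum(axis=1) + b) / lam + c * np.log(lam)).sum()
    )
    return _kl_divergence(V, WH) + penalty


def _ard_nmf(
    V: np.ndarray,
    rank: int,
    rng: np.random.Generator,
    a: float,
    b: float,
    tol: float,
    max_iter: int,
    track_objective: bool = False,
):
    """Run the multiplicative ARD updates; V is channels x samples."""
    F, N = V.shape
    c = F + N + a + 1
    scale = np.sqrt(V.mean() / rank)
    W = rng.uniform(0.5, 1.5, size=(F, rank)) * scale
    H = rng.uniform(0.5, 1.5, size=(rank, N)) * scale
    lam = (W.sum(axis=0) + H.sum(axis=1) + b) / c
    prev = np.inf
    converged = False
    history: list[float] = []
    check_every = 10
    n_done = max_iter
    for it in range(1, max_iter + 1):
        R = V / (W @ H + _EPS)
        W *= (R @ H.T) / (H.sum(axis=1)[None, :] + 1.0 / lam[None, :] + _EPS)
        lam = (W.sum(axis=0) + H.sum(axis=1) + b) / c
        R = V / (W @ H + _EPS)
        H *= (W.T @ R) / (W.sum(axis=0)[:, None] + 1.0 / lam[:, None] + _EPS)
        lam = (W.sum(axis=0) + H.sum(axis=1) + b) / c
        if track_objective:
            history.append(_ard_objective(V, W, H, lam, b, c))
        if it % check_every == 0:
            obj = history[-1] if track_objective else _ard_objective(V, W, H, lam, b, c)
            if np.isfinite(prev) and abs(prev - obj) <= tol * abs(prev):
                converged = True
                n_done = it
                break
            prev = obj
    final_obj = _ard_objective(V, W, H, lam, b, c)
    return W, H, lam, converged, final_obj, history, n_done


def bayesian_nmf(
    catalog: CatalogMatrix,
    max_rank: int = 10,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 100000,
    a: float = 10.0,
    b: float | None = None,
    prune_fraction: float = 0.01,
) -> SignatureSet:
    """Extract mutational signatures from a catalog by ARD Bayesian NMF.

    Starts from ``max_rank`` components and lets the relevance priors
    shrink superfluous ones; components whose relevance weight falls
    below ``prune_fraction`` of the largest are removed. ``b`` defaults
    to a data-driven scale (see module docstring); ``a`` controls how
    strongly empty components are driven out.

    Raises ``ValueError`` on an all-zero catalog or fewer than 2
    samples. Non-convergence at ``max_iter`` returns a result flagged
    ``converged=False``.
    """
    V = catalog.matrix.T.astype(float)  # channels x samples
    F, N = V.shape
    if N < 2:
        raise ValueError("signature extraction needs at least 2 samples")
    if not V.any():
        raise ValueError("catalog is all zero")
    rank = min(max_rank, N - 1, F - 1)
    if rank < max_rank:
        logger.info("max_rank clipped to %d for %d samples", rank, N)
    if b is None:
        b = np.sqrt((a - 1.0) * (a - 2.0) * V.mean()) / rank if a > 2 else V.mean()
    rng = np.random.default_rng(seed)
    W, H, lam, converged, obj, _, n_iter = _ard_nmf(
        V, rank, rng, a=a, b=b, tol=tol, max_iter=max_iter
    )
    if not converged:
        logger.warning("ARD NMF did not converge within %d iterations", max_iter)
    # prune irrelevant components: relevance = component mass scale
    mass = W.sum(axis=0) * H.sum(axis=1)
    relevance = lam
    keep = (relevance >= prune_fraction * relevance.max()) & (mass > _EPS)
    if not keep.any():
        keep[np.argmax(relevance)] = True
    W, H, relevance = W[:, keep], H[keep, :], relevance[keep]
    # L1-normalize signatures, absorb scale into exposures
    col_sums = W.sum(axis=0)
    signatures = (W / col_sums[None, :]).T  # K x 96
    exposures = (H * col_sums[:, None]).T  # N x K
    order = np.argsort(-exposures.sum(axis=0), kind="stable")
    signatures, exposures, relevance = (
        signatures[order], exposures[:, order], relevance[order]
    )
    k = signatures.shape[0]
    logger.info("selected rank %d after %d iterations (seed %d)", k, n_iter, seed)
    return SignatureSet(
        signatures=signatures,
        exposures=exposures,
        selected_rank=k,
        run_seed=seed,
        converged=converged,
        sample_ids=list(catalog.sample_ids),
        labels=[f"W{i + 1}" for i in range(k)],
        relevance=relevance,
        objective=obj,
    )


def stability(
    catalog: CatalogMatrix,
    n_runs: int = 50,
    base_seed: int = 0,
    **nmf_params,
) -> StabilityReport:
    """Recurrence of the selected rank over repeated restarts.

    Runs :func:`bayesian_nmf` with seeds ``base_seed .. base_seed +
    n_runs - 1`` and reports the fraction of runs selecting each rank.
    A failed run is recorded, not fatal.
    """
    if n_runs < 2:
        raise ValueError("stability needs at least 2 runs")
    seeds = [base_seed + i for i in range(n_runs)]
    ranks: list[int] = []
    n_failed = 0
    for s in seeds:
        try:
            ranks.append(bayesian_nmf(catalog, seed=s, **nmf_params).selected_rank)
        except ValueError:
            raise
        except Exception:  # numerical failure in one restart
            logger.exception("NMF run with seed %d failed", s)
            n_failed += 1
    counts: dict[int, int] = {}
    for r in ranks:
        counts[r] = counts.get(r, 0) + 1
    hist = {r: c / len(ranks) for r, c in counts.items()}
    modal = max(hist, key=lambda r: (hist[r], -r))
    return StabilityReport(
        n_runs=n_runs,
        rank_histogram=hist,
        modal_rank=modal,
        seeds=seeds,
        n_failed=n_failed,
    )


def cosine_match(
    extracted: SignatureSet | pd.DataFrame,
    reference: pd.DataFrame,
) -> CosineMatrix:
    """Cosine similarity of every extracted x reference signature pair.

    ``reference`` is signatures x 96 with channel column names in the
    same fixed order; a header mismatch raises :class:`FormatError`.
    """
    ext = (
        extracted.signatures_frame()
        if isinstance(extracted, SignatureSet)
        else extracted
    )
    for df, name in ((ext, "extracted"), (reference, "reference")):
        if list(df.columns) != list(CHANNELS):
            raise FormatError(f"{name} signature matrix channel order does not match")
    U = ext.to_numpy(dtype=float)
    R = reference.to_numpy(dtype=float)
    U_norm = U / np.maximum(np.linalg.norm(U, axis=1, keepdims=True), _EPS)
    R_norm = R / np.maximum(np.linalg.norm(R, axis=1, keepdims=True), _EPS)
    sims = np.clip(U_norm @ R_norm.T, 0.0, 1.0)
    matrix = pd.DataFrame(sims, index=ext.index, columns=reference.index)
    best_idx = sims.argmax(axis=1)
    best = pd.DataFrame(
        {
            "reference": [reference.index[j] for j in best_idx],
            "similarity": sims[np.arange(len(best_idx)), best_idx],
        },
        index=ext.index,
    )
    return CosineMatrix(matrix=matrix, best_match=best)
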