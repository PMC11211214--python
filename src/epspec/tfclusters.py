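"""TF co-binding clusters by non-negative matrix factorization.

The binary element x TF presence matrices (TSS side and enhancer side,
separately) are factored as ``V ~ W H`` with ``W >= 0`` (element scores
per cluster) and ``H >= 0`` (cluster memberships per TF).  The cluster
score columns (``TF_NMF<i>_e`` / ``TF_NMF<i>_TSS``) enter the feature
matrix; the ``H`` rows, normalized to unit maximum, are the reported
co-binding memberships.

The solver minimizes the squared Frobenius reconstruction error with
classical multiplicative updates, runs several seeded restarts, and
keeps the best.  The per-iteration error trajectory is recorded so the
monotone-descent property of the updates can be asserted.  Fitting is
done on unique elements, not on EP rows, so dense regions do not weight
elements by pair multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_EPS = 1e-12
SIDE_SUFFIX = {"enhancer": "e", "tss": "TSS"}


@dataclass
class NMFResult:
    """One fitted factorization; all entries of W and H are >= 0."""

    W: pd.DataFrame  # elements x k, columns NMF1..NMFk
    H: pd.DataFrame  # k x TFs, index NMF1..NMFk (rows scaled to unit max)
    k: int
    side: str
    reconstruction_error: float
    error_trajectory: np.ndarray
    seed: int


def _mu_fit(
    V: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, m = V.shape
    scale = np.sqrt(max(V.mean(), _EPS) / k)
    W = rng.uniform(0.0, 1.0, size=(n, k)) * scale + _EPS
    H = rng.uniform(0.0, 1.0, size=(k, m)) * scale + _EPS
    errors = np.empty(max_iter)
    prev = np.inf
    it = 0
    for it in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        err = float(np.linalg.norm(V - W @ H) ** 2)
        errors[it] = err
        if prev - err < tol * max(prev, 1.0):
            it += 1
            break
        prev = err
    return W, H, errors[:it]


def nmf_fit(
    tf_matrix: pd.DataFrame,
    k: int,
    side: str = "tss",
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
    n_restarts: int = 5,
) -> NMFResult:
    """Factor a nonnegative presence matrix into k co-binding clusters.

    Runs ``n_restarts`` seeded multiplicative-update fits and keeps the
    one with the lowest squared Frobenius error.  After fitting, each H
    row is normalized to unit max (W rescaled inversely, preserving WH)
    so memberships are comparable across clusters.
    """
    V = np.asarray(tf_matrix, dtype=float)
    if (V < 0).any():
        raise ValueError("presence matrix must be nonnegative")
    if k > min(V.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound min{V.shape}")
    if k < 1:
        raise ValueError("k must be >= 1")
    best: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    best_err = np.inf
    for r in range(n_restarts):
        rng = np.random.default_rng(seed * 10_007 + r)
        W, H, traj = _mu_fit(V, k, rng, max_iter, tol)
        if traj[-1] < best_err:
            best_err = float(traj[-1])
            best = (W, H, traj)
    assert best is not None
    W, H, traj = best
    # resolve scale indeterminacy: H rows to unit max, W rescaled inversely
    row_max = H.max(axis=1)
    row_max[row_max == 0] = 1.0
    H = H / row_max[:, None]
    W = W * row_max[None, :]
    names = [f"NMF{i + 1}" for i in range(k)]
    return NMFResult(
        W=pd.DataFrame(W, index=tf_matrix.index, columns=names),
        H=pd.DataFrame(H, index=names, columns=tf_matrix.columns),
        k=k,
        side=side,
        reconstruction_error=best_err,
        error_trajectory=traj,
        seed=seed,
    )


def nmf_features(result: NMFResult, ep: pd.DataFrame) -> pd.DataFrame:
    """Broadcast element cluster scores to EP rows.

    Column names follow the ``TF_NMF<i>_<side>`` pattern; the side's
    element id column (``enhancer_id`` or ``tss_id``) selects the W row.
    """
    suffix = SIDE_SUFFIX[result.side]
    id_col = "enhancer_id" if result.side == "enhancer" else "tss_id"
    ids = ep[id_col]
    missing = set(ids) - set(result.W.index)
    if missing:
        raise KeyError(f"elements absent from NMF fit: {sorted(missing)[:5]} ...")
    scores = result.W.reindex(ids).to_numpy()
    cols = {f"TF_{name}_{suffix}": scores[:, i] for i, name in enumerate(result.W.columns)}
    return pd.DataFrame(cols, index=ep.index)


def cluster_members(result: NMFResult, cluster_index: int, top_n: int = 10) -> pd.Series:
    """Top TFs of one cluster by H membership weight (1-based index).

    Sorted descending; ties broken by TF name; truncated to ``top_n``
    (the full list if ``top_n`` exceeds the TF count).
    """
    if not 1 <= cluster_index <= result.k:
        raise IndexError(f"cluster_index {cluster_index} outside 1..{result.k}")
    row = result.H.iloc[cluster_index - 1]
    order = sorted(row.index, key=lambda tf: (-row[tf], tf))
    return row.loc[order[:top_n]]


def argmax_cluster(result: NMFResult) -> pd.Series:
    """Hard cluster assignment of each TF (argmax membership, 0-based)."""
    return pd.Series(
        np.argmax(result.H.to_numpy(), axis=0), index=result.H.columns, name="cluster"
    )
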