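"""NMF clustering of the fold-change matrix with permutation significance.

The signed fold-change matrix is losslessly embedded into a nonnegative
matrix by splitting each model column into positive and negative parts,
factorized by multiplicative-update NMF (Frobenius loss), and gene
memberships are assigned from right-sided empirical p-values of the
gene-side "activation" values against a pooled element-permutation null.
Clusters are ranked by the Euclidean norm of their activation columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .stats import empirical_p
from .transcriptomics import FoldChangeMatrix

__all__ = ["NMFFit", "NMFClustering", "nonneg_embed", "fit_nmf",
           "activation_significance", "rank_and_select", "cluster_fc_matrix"]

_EPS = 1e-12


def nonneg_embed(fc: Union[FoldChangeMatrix, pd.DataFrame]) -> pd.DataFrame:
    """Split each signed column c into (max(c,0), max(-c,0)) columns.

    The embedding is lossless: c is recoverable as the difference of the
    "+"/"-" column pair, and up/down semantics survive as separate columns.
    """
    df = fc.values if isinstance(fc, FoldChangeMatrix) else fc
    parts = {}
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        parts[f"{col}+"] = np.maximum(v, 0.0)
        parts[f"{col}-"] = np.maximum(-v, 0.0)
    return pd.DataFrame(parts, index=df.index)


@dataclass
class NMFFit:
    """Result of one multiplicative-update NMF run."""

    basis: np.ndarray    # genes x k (activation values)
    pattern: np.ndarray  # k x columns
    loss_history: list[float]

    @property
    def k(self) -> int:
        return self.basis.shape[1]


def _frobenius_loss(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    r = X - W @ H
    return 0.5 * float(np.sum(r * r))


def _nndsvda_init(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD initialization (zeros filled with mean/100)."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n, m = X.shape
    W = np.zeros((n, k))
    H = np.zeros((k, m))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, k):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            uu, vv, sig = up / max(n_up, _EPS), vp / max(n_vp, _EPS), n_up * n_vp
        else:
            uu, vv, sig = un / max(n_un, _EPS), vn / max(n_vn, _EPS), n_un * n_vn
        W[:, j] = np.sqrt(S[j] * sig) * uu
        H[j] = np.sqrt(S[j] * sig) * vv
    fill = max(X.mean(), _EPS) / 100.0
    W[W == 0] = fill
    H[H == 0] = fill
    return W, H


def fit_nmf(matrix: np.ndarray, k: int, seed: int = 0, max_iter: int = 500,
            tol: float = 1e-5, init: str = "nndsvda") -> NMFFit:
    """Multiplicative-update NMF minimizing the Frobenius loss.

    ``init="nndsvda"`` (default) seeds the factors from a nonnegative
    double-SVD decomposition, which is deterministic and concentrates
    planted block structure into single components even when k exceeds
    the true rank; ``init="random"`` draws the factors from a seeded
    uniform distribution scaled to the data magnitude.  Updates are the
    standard Lee-Seung multiplicative rules, which make the Frobenius
    loss nonincreasing.  Iteration stops at ``max_iter`` or when the
    relative loss change drops below ``tol``.  The run is a pure function
    of (matrix, k, seed, init): repeated calls are bit-identical.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ConfigError("matrix must be 2-D")
    if np.any(X < 0):
        raise ConfigError("NMF input must be nonnegative (embed first)")
    n, m = X.shape
    if not (1 <= k <= min(n, m)):
        raise ConfigError(f"k={k} must satisfy 1 <= k <= min{(n, m)}")
    if init == "nndsvda":
        W, H = _nndsvda_init(X, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        scale = np.sqrt(max(X.mean(), _EPS) / k)
        W = scale * rng.random((n, k))
        H = scale * rng.random((k, m))
    else:
        raise ConfigError(f"unknown init {init!r}")
    losses = [_frobenius_loss(X, W, H)]
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        loss = _frobenius_loss(X, W, H)
        losses.append(loss)
        prev = losses[-2]
        if prev > 0 and (prev - loss) / prev < tol:
            break
    # fix the W/H scale indeterminacy: unit-norm pattern rows, so that
    # activation values carry the component magnitude in data units and
    # are comparable across fits (required for pooled permutation nulls)
    norms = np.linalg.norm(H, axis=1)
    norms[norms == 0] = 1.0
    H /= norms[:, None]
    W *= norms[None, :]
    return NMFFit(basis=W, pattern=H, loss_history=losses)


def activation_significance(fc_nonneg: Union[pd.DataFrame, np.ndarray],
                            k: int, n_perm: int = 100, seed: int = 0,
                            max_iter: int = 500, tol: float = 1e-5,
                            init: str = "nndsvda",
                            fit: Optional[NMFFit] = None,
                            ) -> tuple[NMFFit, np.ndarray]:
    """Right-sided empirical p-values for every gene-activation value.

    For each of ``n_perm`` permutations all elements of the nonnegative
    matrix are globally shuffled, NMF is refit at the same ``k`` with a
    permutation-specific derived seed, and every gene-side factor entry
    is pooled into one null.  Each observed activation value receives a
    right-sided add-one empirical p against that pooled null.

    Returns the observed fit and the genes x k p-value array.
    """
    X = fc_nonneg.to_numpy(dtype=float) if isinstance(fc_nonneg, pd.DataFrame) \
        else np.asarray(fc_nonneg, dtype=float)
    if fit is None:
        fit = fit_nmf(X, k=k, seed=seed, max_iter=max_iter, tol=tol, init=init)
    rng = np.random.default_rng(seed)
    flat = X.ravel()
    null_chunks = []
    for i in range(n_perm):
        perm = rng.permutation(flat).reshape(X.shape)
        child = int(rng.integers(0, 2**31 - 1))
        null_fit = fit_nmf(perm, k=k, seed=child, max_iter=max_iter, tol=tol,
                           init=init)
        null_chunks.append(null_fit.basis.ravel())
    null = np.concatenate(null_chunks)
    p = empirical_p(fit.basis.ravel(), null, tail="right").reshape(fit.basis.shape)
    return fit, p


@dataclass
class NMFClustering:
    """Fitted clustering of a fold-change matrix."""

    basis: pd.DataFrame          # genes x clusters (activation values)
    pattern: pd.DataFrame        # clusters x embedded model columns
    activation_p: pd.DataFrame   # genes x clusters
    k: int
    cluster_p: float = 0.01
    loss_history: list[float] = field(default_factory=list)

    @property
    def memberships(self) -> dict[str, set[int]]:
        """gene -> set of cluster indices with activation_p < cluster_p."""
        sig = self.activation_p.to_numpy() < self.cluster_p
        out: dict[str, set[int]] = {}
        for gi, gene in enumerate(self.basis.index):
            clusters = set(np.flatnonzero(sig[gi]).tolist())
            if clusters:
                out[gene] = clusters
        return out

    def cluster_norms(self) -> np.ndarray:
        return np.linalg.norm(self.basis.to_numpy(), axis=0)

    @property
    def ranking(self) -> list[int]:
        """Cluster indices by descending activation norm, ties by index."""
        norms = self.cluster_norms()
        return sorted(range(self.k), key=lambda i: (-norms[i], i))

    def members_of(self, cluster: int) -> list[str]:
        mask = self.activation_p.iloc[:, cluster].to_numpy() < self.cluster_p
        return list(self.basis.index[mask])


def rank_and_select(clustering: NMFClustering, m: int
                    ) -> list[tuple[int, float, list[str]]]:
    """Top-m clusters by descending activation norm with member gene lists."""
    if m > clustering.k:
        raise ConfigError(f"cannot select top {m} of {clustering.k} clusters")
    norms = clustering.cluster_norms()
    return [(i, float(norms[i]), clustering.members_of(i))
            for i in clustering.ranking[:m]]


def cluster_fc_matrix(fc: FoldChangeMatrix, k: int, n_perm: int = 100,
                      seed: int = 0, cluster_p: float = 0.01,
                      max_iter: int = 500, tol: float = 1e-5,
                      init: str = "nndsvda") -> NMFClustering:
    """End-to-end: embed, fit, assess activation significance."""
    embedded = nonneg_embed(fc)
    fit, p = activation_significance(embedded, k=k, n_perm=n_perm, seed=seed,
                                     max_iter=max_iter, tol=tol, init=init)
    clusters = list(range(k))
    return NMFClustering(
        basis=pd.DataFrame(fit.basis, index=embedded.index, columns=clusters),
        pattern=pd.DataFrame(fit.pattern, index=clusters,
                             columns=embedded.columns),
        activation_p=pd.DataFrame(p, index=embedded.index, columns=clusters),
        k=k, cluster_p=cluster_p, loss_history=fit.loss_history)
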