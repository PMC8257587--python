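"""Shared statistical primitives.

Quantile normalization, the per-feature (T, log2-median-ratio) pair,
permutation empirical nulls with percentile-derived fold-change cutoffs,
empirical p-values, Stouffer combination of component p-values, and the
Z-score transform of an enrichment p-value.

Conventions
-----------
All expression inputs are on the log2 scale.  The two-sample statistic T
is a pooled-variance Student t computed on log2 values; the effect size
LMR is ``log2(median(A) / median(B))`` computed on the intensity scale
(``2**x``), so LMR = 1 means a two-fold change of group medians.  Zeros
upstream are encoded as NaN before these functions see them; a group
needs at least two finite values for T and a positive median for LMR.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigError, PermdiffError

__all__ = [
    "FeatureStatistic", "EmpiricalNull", "CombinedP",
    "quantile_normalize", "feature_statistic", "group_statistics",
    "build_empirical_null", "empirical_p", "stouffer_combine", "z_from_p",
    "lmr_cutoff_from_null",
]


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class FeatureStatistic:
    """Per-feature two-sample summary: t statistic and log2-median-ratio."""

    feature_id: str
    T: float
    LMR: float

    @property
    def direction(self) -> str:
        if not np.isfinite(self.LMR) or self.LMR == 0.0:
            return "none"
        return "up" if self.LMR > 0 else "down"


@dataclass
class EmpiricalNull:
    """Pooled permutation null of (T, LMR) for one two-group comparison."""

    null_T: np.ndarray
    null_LMR: np.ndarray
    lmr_cutoff: float
    scheme: str
    n_perm: int
    seed: int
    lmr_percentiles: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self) -> None:
        self.null_T = np.asarray(self.null_T, dtype=float)
        self.null_LMR = np.asarray(self.null_LMR, dtype=float)
        if self.null_T.size == 0 or self.null_LMR.size == 0:
            raise PermdiffError("empirical null is empty")


@dataclass(frozen=True)
class CombinedP:
    """Stouffer combination of the T and LMR component p-values."""

    p_T: float
    p_LMR: float
    z_T: float
    z_LMR: float
    overall_p: float


# ---------------------------------------------------------------------------
# quantile normalization

def quantile_normalize(matrix):
    """Quantile-normalize columns of a features x samples matrix.

    Every column is mapped onto the vector of row-wise means of the
    column-sorted matrix; within-column rank order is preserved.  Tied
    values within a column receive the mean of the reference values at
    their tied positions, so the result is deterministic.

    Accepts and returns either a DataFrame or a 2-D ndarray.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    values = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[1] < 1:
        raise ValueError("expected a 2-D matrix with at least one column")
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires a complete matrix "
                         "(missing values found)")
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        placed = np.empty(n)
        placed[order] = ref
        # ties share the mean of their reference slots
        srt = col[order]
        bounds = np.flatnonzero(np.r_[True, srt[1:] != srt[:-1], True])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a > 1:
                placed[order[a:b]] = ref[a:b].mean()
        out[:, j] = placed
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


# ---------------------------------------------------------------------------
# per-feature statistics

def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return math.nan
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 <= 0.0:
        return math.nan
    return float((a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb)))


def feature_statistic(values_a: Sequence[float], values_b: Sequence[float],
                      feature_id: str = "") -> FeatureStatistic:
    """T and LMR for one feature from two groups of log2 values.

    T is the pooled-variance two-sample t on the log2 values; LMR is
    log2(median(2**a) / median(2**b)).  NaN entries are ignored.  T is NaN
    when a group has fewer than two finite values or the pooled variance
    is zero; LMR is NaN when either intensity-scale median is nonpositive.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    t = _pooled_t(a, b)
    if a.size == 0 or b.size == 0:
        lmr = math.nan
    else:
        med_a = float(np.median(np.exp2(a)))
        med_b = float(np.median(np.exp2(b)))
        lmr = math.log2(med_a / med_b) if med_a > 0 and med_b > 0 else math.nan
    return FeatureStatistic(feature_id=feature_id, T=t, LMR=lmr)


def group_statistics(matrix: np.ndarray, idx_a: np.ndarray,
                     idx_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (T, LMR) for every row of a log2 matrix.

    ``idx_a`` / ``idx_b`` are column indices of the two groups.  NaN cells
    are ignored per row; rows without two finite values per group get NaN
    statistics.
    """
    A = matrix[:, idx_a]
    B = matrix[:, idx_b]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        na = np.sum(np.isfinite(A), axis=1)
        nb = np.sum(np.isfinite(B), axis=1)
        ma = np.nanmean(A, axis=1)
        mb = np.nanmean(B, axis=1)
        va = np.nanvar(A, axis=1, ddof=1)
        vb = np.nanvar(B, axis=1, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / np.maximum(na + nb - 2, 1)
        se = np.sqrt(sp2 * (1.0 / np.maximum(na, 1) + 1.0 / np.maximum(nb, 1)))
        t = (ma - mb) / se
        t[(na < 2) | (nb < 2) | (sp2 <= 0)] = np.nan
        med_a = np.nanmedian(np.exp2(A), axis=1)
        med_b = np.nanmedian(np.exp2(B), axis=1)
        lmr = np.log2(med_a / med_b)
        lmr[(na < 1) | (nb < 1)] = np.nan
    return t, lmr


# ---------------------------------------------------------------------------
# empirical nulls

def _label_arrangements(n_samples: int, n_a: int, n_perm: int,
                        rng: np.random.Generator) -> list[np.ndarray]:
    """Index sets (group-A columns) for up to n_perm distinct relabelings.

    Enumerates all C(n, n_a) arrangements (with a warning) when there are
    no more than n_perm of them; otherwise draws n_perm distinct
    arrangements without replacement.
    """
    total = math.comb(n_samples, n_a)
    if total < 2:
        raise PermdiffError("fewer than two distinct label arrangements exist")
    if total <= n_perm:
        if total < n_perm:
            warnings.warn(
                f"only {total} distinct label arrangements exist for "
                f"{n_a} vs {n_samples - n_a}; enumerating all of them "
                f"instead of drawing {n_perm}", stacklevel=3)
        return [np.array(c) for c in
                itertools.combinations(range(n_samples), n_a)]
    if total <= 2_000_000:
        combos = list(itertools.combinations(range(n_samples), n_a))
        picks = rng.choice(total, size=n_perm, replace=False)
        return [np.array(combos[i]) for i in picks]
    # huge space: independent draws, collisions are negligible
    return [np.sort(rng.permutation(n_samples)[:n_a]) for _ in range(n_perm)]


def lmr_cutoff_from_null(null_lmr: np.ndarray,
                         percentiles: tuple[float, float]) -> float:
    """Mean of |lo-th| and |hi-th| percentiles of the null LMR values."""
    lo, hi = percentiles
    finite = np.asarray(null_lmr, dtype=float)
    finite = finite[np.isfinite(finite)]
    if finite.size == 0:
        raise PermdiffError("no finite null LMR values to derive a cutoff")
    p_lo, p_hi = np.percentile(finite, [lo, hi])
    return float((abs(p_lo) + abs(p_hi)) / 2.0)


def build_empirical_null(data: np.ndarray, labels: Sequence,
                         scheme: str = "label_permutation",
                         n_perm: int = 100, seed: int = 0,
                         lmr_percentiles: tuple[float, float] = (5.0, 95.0),
                         ) -> EmpiricalNull:
    """Permutation (or bootstrap) null of (T, LMR) pooled over all features.

    ``data`` is a features x samples log2 matrix; ``labels`` assigns each
    column to one of exactly two groups.  For each permutation the group
    labels are shuffled over the sample axis, T and LMR are recomputed for
    every feature, and all permuted statistics are pooled into a single
    null per statistic.  ``scheme`` is one of:

    - ``"label_permutation"`` / ``"channel_permutation"``: distinct
      relabelings of the columns (the proteomic TMT-channel scheme and the
      transcriptomic resampling scheme share this engine);
    - ``"sample_resampling"``: bootstrap — columns of each pseudo-dataset
      are drawn with replacement, then split into the original group sizes.
    """
    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise PermdiffError(f"expected exactly two groups, got {list(uniq)}")
    n_a = int(np.sum(labels == uniq[0]))
    n = data.shape[1]
    if n_a < 2 or n - n_a < 2:
        raise PermdiffError("each group needs at least two samples")
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    null_t: list[np.ndarray] = []
    null_lmr: list[np.ndarray] = []
    if scheme in ("label_permutation", "channel_permutation"):
        for idx_a in _label_arrangements(n, n_a, n_perm, rng):
            mask = np.zeros(n, dtype=bool)
            mask[idx_a] = True
            t, lmr = group_statistics(data, np.flatnonzero(mask),
                                      np.flatnonzero(~mask))
            null_t.append(t)
            null_lmr.append(lmr)
        n_done = len(null_t)
    elif scheme == "sample_resampling":
        for _ in range(n_perm):
            cols = rng.integers(0, n, size=n)
            t, lmr = group_statistics(data[:, cols], np.arange(n_a),
                                      np.arange(n_a, n))
            null_t.append(t)
            null_lmr.append(lmr)
        n_done = n_perm
    else:
        raise ConfigError(f"unknown null scheme {scheme!r}")

    pooled_t = np.concatenate(null_t)
    pooled_lmr = np.concatenate(null_lmr)
    keep = np.isfinite(pooled_t) & np.isfinite(pooled_lmr)
    pooled_t = pooled_t[keep]
    pooled_lmr = pooled_lmr[keep]
    cutoff = lmr_cutoff_from_null(pooled_lmr, lmr_percentiles)
    return EmpiricalNull(null_T=pooled_t, null_LMR=pooled_lmr,
                         lmr_cutoff=cutoff, scheme=scheme, n_perm=n_done,
                         seed=seed, lmr_percentiles=tuple(lmr_percentiles))


# ---------------------------------------------------------------------------
# empirical p-values

def empirical_p(observed, null, tail: str = "two"):
    """Add-one empirical p-value of observed statistic(s) against a null.

    two-tailed: ``p = (1 + #{|x| >= |obs|}) / (1 + N)``;
    right-sided: ``p = (1 + #{x >= obs}) / (1 + N)``.  Always in (0, 1].
    Accepts a scalar or an array of observed values.
    """
    null = np.asarray(null, dtype=float).ravel()
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise PermdiffError("empirical null is empty")
    obs = np.asarray(observed, dtype=float)
    scalar = obs.ndim == 0
    obs = np.atleast_1d(obs)
    if tail == "two":
        ref = np.sort(np.abs(null))
        query = np.abs(obs)
    elif tail == "right":
        ref = np.sort(null)
        query = obs
    else:
        raise ConfigError(f"unknown tail {tail!r}")
    count = ref.size - np.searchsorted(ref, query, side="left")
    p = (1.0 + count) / (1.0 + ref.size)
    p = np.where(np.isfinite(obs), p, np.nan)
    return float(p[0]) if scalar else p


# ---------------------------------------------------------------------------
# Stouffer combination and Z-score transform

def _signed_z(p: float, direction: float, n_perm=None) -> float:
    """Signed one-sided z for a two-tailed p in the given effect direction."""
    if p == 0.0 and n_perm is not None:
        warnings.warn(f"component p-value of 0 clipped to 1/(1+{n_perm})",
                      stacklevel=3)
        p = 1.0 / (1.0 + n_perm)
    if not (0.0 < p <= 1.0):
        raise ValueError(f"component p-value must lie in (0, 1], got {p!r}")
    z = float(sps.norm.isf(p / 2.0))
    sign = 1.0 if direction >= 0 else -1.0
    return sign * z


def stouffer_combine(p_T: float, p_LMR: float, direction_T: float,
                     direction_LMR: float, n_perm=None) -> CombinedP:
    """Combine two-tailed component p-values into one overall p.

    Each component p is converted to a signed one-sided z in its effect
    direction (``z = sign * isf(p/2)``), the z's are averaged with equal
    weights, and the overall p is the two-sided tail of the combined z.
    Opposing directions give opposing signs, so disagreement attenuates
    the combined evidence.  Directions may be given as signs (+/-1) or as
    the raw effect values; only their sign is used.
    """
    z_t = _signed_z(p_T, direction_T, n_perm)
    z_l = _signed_z(p_LMR, direction_LMR, n_perm)
    z_comb = (z_t + z_l) / math.sqrt(2.0)
    overall = float(2.0 * sps.norm.sf(abs(z_comb)))
    overall = min(max(overall, np.nextafter(0.0, 1.0)), 1.0)
    return CombinedP(p_T=p_T, p_LMR=p_LMR, z_T=z_t, z_LMR=z_l,
                     overall_p=overall)


def stouffer_combine_arrays(p_T: np.ndarray, p_LMR: np.ndarray,
                            direction_T: np.ndarray,
                            direction_LMR: np.ndarray) -> np.ndarray:
    """Vectorized ``stouffer_combine`` returning only the overall p array."""
    p_T = np.clip(np.asarray(p_T, dtype=float), np.nextafter(0.0, 1.0), 1.0)
    p_LMR = np.clip(np.asarray(p_LMR, dtype=float), np.nextafter(0.0, 1.0), 1.0)
    z_t = np.where(np.asarray(direction_T) >= 0, 1.0, -1.0) * sps.norm.isf(p_T / 2.0)
    z_l = np.where(np.asarray(direction_LMR) >= 0, 1.0, -1.0) * sps.norm.isf(p_LMR / 2.0)
    z_comb = (z_t + z_l) / math.sqrt(2.0)
    overall = 2.0 * sps.norm.sf(np.abs(z_comb))
    return np.clip(overall, np.nextafter(0.0, 1.0), 1.0)


def z_from_p(P):
    """Z-score of an enrichment p-value: ``-ppf(P)``, decreasing in P."""
    p = np.asarray(P, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("P must lie strictly inside (0, 1)")
    z = -sps.norm.ppf(p)
    return float(z) if np.ndim(P) == 0 else z
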