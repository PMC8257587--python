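"""Model-similarity statistics.

Consistent-sibling-peptide selection, fold-change correlation between two
experiments with a sample-permutation null, hypergeometric DEP-overlap
significance, and average-linkage hierarchical clustering of model
fold-change profiles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .exceptions import PermdiffError
from .proteomics import DEPCall
from .stats import group_statistics
from .transcriptomics import FoldChangeMatrix

__all__ = ["SimilarityResult", "ModelDendrogram", "consistent_sibling_peptides",
           "fc_correlation", "dep_overlap_test", "cluster_models",
           "sample_correlation"]


@dataclass(frozen=True)
class SimilarityResult:
    """Correlation of fold-changes between two comparisons."""

    rho: float
    m: int                 # consistent DE sibling peptides used
    p_perm: float          # right-sided permutation p
    slope: float
    intercept: float
    r_squared: float
    label: str = ""


def consistent_sibling_peptides(de_peptides: pd.DataFrame,
                                deps: Sequence[DEPCall]) -> list[str]:
    """DE peptides whose protein is a DEP and whose direction matches it."""
    dep_dir = {c.protein_group: c.direction for c in deps}
    de = de_peptides.loc[de_peptides["is_de"]]
    keep = [str(row.peptide_id) for row in de.itertuples()
            if dep_dir.get(row.protein_group) == row.direction]
    return sorted(keep)


def _lmr_vector(values: np.ndarray, labels: np.ndarray,
                cond_a: str, cond_b: str) -> np.ndarray:
    idx_a = np.flatnonzero(labels == cond_a)
    idx_b = np.flatnonzero(labels == cond_b)
    _, lmr = group_statistics(values, idx_a, idx_b)
    return lmr


def fc_correlation(peptide_set: Sequence[str],
                   log2_a: pd.DataFrame, labels_a: dict,
                   log2_b: pd.DataFrame, labels_b: dict,
                   contrast_a: tuple[str, str], contrast_b: tuple[str, str],
                   n_perm: int = 5000, seed: int = 0,
                   label: str = "") -> SimilarityResult:
    """Pearson correlation of two experiments' LMRs with a permutation null.

    ``log2_a`` / ``log2_b`` are features x samples log2 matrices (rows
    indexed by feature id; NaN = missing), restricted here to
    ``peptide_set``.  The observed rho correlates the two LMR vectors on
    the set.  The null permutes the condition labels independently within
    each experiment before recomputing both LMR vectors and rho; the
    permutation p is right-sided with the add-one correction.
    """
    peptides = list(peptide_set)
    if len(peptides) < 3:
        raise PermdiffError(f"need >= 3 peptides for a correlation, "
                            f"got {len(peptides)}")
    A = log2_a.loc[peptides]
    B = log2_b.loc[peptides]
    lab_a = np.array([labels_a[s] for s in A.columns])
    lab_b = np.array([labels_b[s] for s in B.columns])
    va, vb = A.to_numpy(dtype=float), B.to_numpy(dtype=float)

    def rho_of(la, lb):
        x = _lmr_vector(va, la, *contrast_a)
        y = _lmr_vector(vb, lb, *contrast_b)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
            return math.nan, x, y, ok
        return float(np.corrcoef(x[ok], y[ok])[0, 1]), x, y, ok

    rho, x, y, ok = rho_of(lab_a, lab_b)
    if math.isnan(rho):
        raise PermdiffError("observed correlation undefined "
                            "(zero variance or too few finite pairs)")
    slope, intercept = np.polyfit(x[ok], y[ok], 1)
    r2 = rho * rho

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pa = rng.permutation(lab_a)
        pb = rng.permutation(lab_b)
        null[i], *_ = rho_of(pa, pb)
    null = null[np.isfinite(null)]
    if null.size == 0:
        raise PermdiffError("all permuted correlations undefined")
    p = (1.0 + int(np.sum(null >= rho))) / (1.0 + null.size)
    return SimilarityResult(rho=rho, m=int(ok.sum()), p_perm=float(p),
                            slope=float(slope), intercept=float(intercept),
                            r_squared=float(r2), label=label)


def dep_overlap_test(set_a: set, set_b: set,
                     universe_size: int) -> tuple[int, float]:
    """Right-tailed hypergeometric p of the observed set overlap."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise PermdiffError("set larger than the universe")
    overlap = len(a & b)
    p = float(sps.hypergeom.sf(overlap - 1, universe_size, len(a), len(b)))
    return overlap, min(p, 1.0)


@dataclass
class ModelDendrogram:
    """Average-linkage merge tree over model fold-change profiles."""

    linkage: np.ndarray        # scipy linkage matrix
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def recurse(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({recurse(tree.left, tree.dist)}," \
               f"{recurse(tree.right, tree.dist)});" if not tree.is_leaf() \
               else f"{self.labels[tree.id]};"


def cluster_models(fc: Union[FoldChangeMatrix, pd.DataFrame]) -> ModelDendrogram:
    """Hierarchical clustering of model columns (Euclidean, average linkage).

    Columns are ordered by model name before linkage so the tree is
    invariant to input column order.
    """
    df = fc.values if isinstance(fc, FoldChangeMatrix) else fc
    if df.shape[1] < 2:
        raise PermdiffError("need at least two model columns")
    df = df[sorted(df.columns)]
    points = df.to_numpy(dtype=float).T
    Z = hierarchy.linkage(pdist(points, metric="euclidean"), method="average")
    return ModelDendrogram(linkage=Z, labels=list(df.columns))


def sample_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of sample columns (convenience)."""
    return matrix.corr(method="pearson")
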