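"""Microarray differential-expression stage (human and yeast variants)
and assembly of the multi-model log2-fold-change matrix over the DEG union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigError, SchemaError
from .io import ExpressionMatrix
from .stats import EmpiricalNull, build_empirical_null, empirical_p, \
    group_statistics, quantile_normalize, stouffer_combine_arrays

__all__ = ["DEGResult", "FoldChangeMatrix", "call_degs", "collapse_probes",
           "build_fc_matrix"]

log = logging.getLogger(__name__)


@dataclass
class DEGResult:
    """Per-gene differential-expression results for one contrast.

    ``table`` columns: T, LMR, p_T, p_LMR, overall_p, direction, is_deg
    (overall_p is NaN for the yeast variant, which uses p_T alone).
    """

    table: pd.DataFrame
    null: EmpiricalNull
    contrast: tuple[str, str]
    variant: str
    n_excluded: int = 0

    @property
    def degs(self) -> pd.Index:
        return self.table.index[self.table["is_deg"]]

    @property
    def lmr(self) -> pd.Series:
        return self.table["LMR"]


@dataclass
class FoldChangeMatrix:
    """Genes (union of DEGs) x models matrix of log2-fold-changes."""

    values: pd.DataFrame
    #: boolean genes x models table: which genes were DEGs in which model
    deg_membership: pd.DataFrame
    normalized: bool = False

    @property
    def models(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def call_degs(matrix: ExpressionMatrix, contrast: tuple[str, str],
              variant: str = "human", n_perm: int = 1000, seed: int = 0,
              alpha: float = 0.05, alpha_strict: float = 0.01,
              lmr_percentiles: Optional[tuple[float, float]] = None,
              null_scheme: str = "label_permutation") -> DEGResult:
    """Integrative DEG calling against a label-permutation empirical null.

    For every gene a pooled-variance T and a log2-median-ratio are
    computed for the contrast; an empirical null of both statistics is
    built by shuffling the group labels ``n_perm`` times and pooling over
    genes, and two-tailed empirical p-values are assigned.

    variant "human": the component p-values are Stouffer-combined and a
    gene is a DEG iff overall_p < ``alpha`` and |LMR| strictly exceeds
    the cutoff derived from the (2.5, 97.5) null LMR percentiles.

    variant "yeast": a gene is a DEG iff p_T <= ``alpha_strict`` and
    |LMR| >= the cutoff derived from the (5, 95) null LMR percentiles
    (no Stouffer combination).

    ``null_scheme`` may be set to "sample_resampling" for a bootstrap
    null instead of label permutation.
    """
    if variant not in ("human", "yeast"):
        raise ConfigError(f"unknown variant {variant!r}")
    if lmr_percentiles is None:
        lmr_percentiles = (2.5, 97.5) if variant == "human" else (5.0, 95.0)
    cond_a, cond_b = contrast
    samples_a = matrix.samples_for(cond_a)
    samples_b = matrix.samples_for(cond_b)
    for cond, samples in ((cond_a, samples_a), (cond_b, samples_b)):
        if len(samples) < 2:
            raise ConfigError(f"group {cond!r} has {len(samples)} sample(s); "
                              "need at least 2")
    cols = samples_a + samples_b
    data = matrix.values[cols].to_numpy(dtype=float)

    # exclude zero-variance genes from testing
    variances = data.var(axis=1)
    testable = variances > 0
    n_excluded = int((~testable).sum())
    if n_excluded:
        log.info("excluding %d zero-variance genes", n_excluded)

    labels = [cond_a] * len(samples_a) + [cond_b] * len(samples_b)
    null = build_empirical_null(data[testable], labels, scheme=null_scheme,
                                n_perm=n_perm, seed=seed,
                                lmr_percentiles=lmr_percentiles)

    idx_a = np.arange(len(samples_a))
    idx_b = np.arange(len(samples_a), len(cols))
    t, lmr = group_statistics(data, idx_a, idx_b)
    p_t = np.full(len(t), np.nan)
    p_l = np.full(len(t), np.nan)
    finite = np.isfinite(t) & np.isfinite(lmr)
    p_t[finite] = empirical_p(t[finite], null.null_T, tail="two")
    p_l[finite] = empirical_p(lmr[finite], null.null_LMR, tail="two")

    overall = np.full(len(t), np.nan)
    is_deg = np.zeros(len(t), dtype=bool)
    if variant == "human":
        overall[finite] = stouffer_combine_arrays(
            p_t[finite], p_l[finite], np.sign(t[finite]), np.sign(lmr[finite]))
        is_deg[finite] = (overall[finite] < alpha) \
            & (np.abs(lmr[finite]) > null.lmr_cutoff)
    else:
        is_deg[finite] = (p_t[finite] <= alpha_strict) \
            & (np.abs(lmr[finite]) >= null.lmr_cutoff)

    direction = np.where(lmr > 0, "up", np.where(lmr < 0, "down", "none"))
    direction = np.where(np.isfinite(lmr), direction, "none")
    table = pd.DataFrame({
        "T": t, "LMR": lmr, "p_T": p_t, "p_LMR": p_l, "overall_p": overall,
        "direction": direction, "is_deg": is_deg,
    }, index=matrix.values.index)
    return DEGResult(table=table, null=null, contrast=contrast,
                     variant=variant, n_excluded=n_excluded)


def collapse_probes(matrix: ExpressionMatrix,
                    probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probes to genes by keeping the highest-mean probe per gene."""
    values = matrix.values
    genes = pd.Series({p: probe_to_gene[p] for p in values.index
                       if p in probe_to_gene})
    sub = values.loc[genes.index]
    means = sub.mean(axis=1)
    best = means.groupby(genes).idxmax()
    collapsed = sub.loc[best.to_numpy()]
    collapsed.index = best.index
    return ExpressionMatrix(values=collapsed.sort_index(),
                            groups=dict(matrix.groups),
                            organism=matrix.organism)


def build_fc_matrix(deg_results: Mapping[str, DEGResult],
                    normalize: bool = True) -> FoldChangeMatrix:
    """Assemble the models x genes fold-change matrix over the DEG union.

    Rows are the union of per-model DEG sets; each entry is the gene's
    LMR in that model whether or not it was a DEG there.  All models must
    share one gene universe.  Columns are quantile-normalized unless
    ``normalize=False``.
    """
    if len(deg_results) < 2:
        raise ConfigError("need at least two models to build a FC matrix")
    models = list(deg_results)
    universe = deg_results[models[0]].table.index
    for m in models[1:]:
        other = deg_results[m].table.index
        if not universe.equals(other):
            missing = universe.difference(other)
            raise SchemaError(
                f"model {m!r} gene universe differs from {models[0]!r} "
                f"(e.g. missing {list(missing[:3])})")
    union = sorted(set().union(*(deg_results[m].degs for m in models)))
    if not union:
        raise SchemaError("no DEGs in any model; FC matrix would be empty")
    values = pd.DataFrame({m: deg_results[m].lmr.loc[union] for m in models},
                          index=pd.Index(union, name="gene_id"))
    membership = pd.DataFrame(
        {m: deg_results[m].table.loc[union, "is_deg"] for m in models},
        index=values.index)
    if normalize:
        values = quantile_normalize(values)
    return FoldChangeMatrix(values=values, deg_membership=membership,
                            normalized=normalize)
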