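"""Synthetic-data generators with planted structure.

Every generator is a pure function of (parameters, seed) and returns the
dataset together with a :class:`SimulationTruth` holding the planted
feature labels and every generator parameter, so downstream recovery can
be asserted without re-deriving the truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import ChannelInfo, ExpressionMatrix, GeneSetCollection, \
    PeptideQuantTable
from .transcriptomics import FoldChangeMatrix

__all__ = ["SimulationTruth", "simulate_tmt", "simulate_microarray",
           "simulate_model_fc", "simulate_gmt"]


@dataclass
class SimulationTruth:
    """Planted truth: per-feature labels plus all generator parameters."""

    features: pd.DataFrame
    params: dict = field(default_factory=dict)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.features.to_csv(path, sep="\t", index=False)

    def planted(self, direction: Optional[str] = None) -> set:
        df = self.features
        mask = df["is_de"] if "is_de" in df.columns else df["block"] >= 0
        if direction is not None and "direction" in df.columns:
            mask = mask & (df["direction"] == direction)
        return set(df.loc[mask, df.columns[0]])


def _lognormal_sigma_from_cv(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def simulate_tmt(n_proteins: int = 1000, peptides_per_protein: int = 2,
                 frac_de: float = 0.05, fold: float = 4.0, cv: float = 0.1,
                 n_rep: int = 3, seed: int = 0,
                 conditions: tuple[str, str] = ("young", "senescent"),
                 fraction: Optional[str] = None,
                 frac_nonunique: float = 0.05,
                 frac_low_purity: float = 0.1,
                 ) -> tuple[PeptideQuantTable, SimulationTruth]:
    """Simulate a TMT peptide reporter-intensity table with planted DE.

    Protein base abundances are lognormal; each peptide carries a
    multiplicative ionization factor; every reporter intensity is
    abundance x factor x lognormal noise with the given CV.  A planted
    fraction of proteins is scaled by ``fold`` in the second condition
    (half up, half down).  Isolation purities are Beta-distributed and
    skewed toward 1 with a ``frac_low_purity`` tail below 0.75, and about
    ``frac_nonunique`` of peptides are flagged non-unique.
    """
    if not (0.0 <= frac_de < 1.0):
        raise ConfigError("frac_de must lie in [0, 1)")
    if fold <= 1.0:
        raise ConfigError("fold must be > 1")
    if n_rep < 2:
        raise ConfigError("n_rep must be >= 2")
    if cv <= 0:
        raise ConfigError("cv must be positive")
    rng = np.random.default_rng(seed)
    cond_a, cond_b = conditions

    n_de = int(round(frac_de * n_proteins))
    de_idx = rng.choice(n_proteins, size=n_de, replace=False)
    direction = np.full(n_proteins, "none", dtype=object)
    direction[de_idx[: n_de // 2]] = "up"       # up in cond_b
    direction[de_idx[n_de // 2:]] = "down"
    effect = np.ones(n_proteins)
    effect[direction == "up"] = fold
    effect[direction == "down"] = 1.0 / fold

    base = rng.lognormal(mean=math.log(1e6), sigma=1.0, size=n_proteins)
    sigma = _lognormal_sigma_from_cv(cv)

    channels: dict[str, ChannelInfo] = {}
    for cond in conditions:
        for r in range(1, n_rep + 1):
            channels[f"{cond}_{r}"] = ChannelInfo(condition=cond, replicate=r,
                                                  fraction=fraction)
    rows = []
    truth_rows = []
    for pi in range(n_proteins):
        protein = f"P{pi:05d}"
        truth_rows.append({"protein_group": protein,
                           "is_de": direction[pi] != "none",
                           "direction": direction[pi],
                           "fold": fold if direction[pi] != "none" else 1.0})
        for qi in range(peptides_per_protein):
            ion = rng.lognormal(mean=0.0, sigma=0.5)
            nonunique = rng.random() < frac_nonunique
            if rng.random() < frac_low_purity:
                purity = rng.uniform(0.4, 0.75)
            else:
                purity = rng.beta(20.0, 1.0) * 0.25 + 0.75
            row = {
                "peptide_id": f"P{pi:05d}_pep{qi}",
                "protein_group": f"P{pi:05d};P{(pi + 1) % n_proteins:05d}"
                                 if nonunique else protein,
                "is_unique": not nonunique,
                "isolation_purity": round(purity, 4),
            }
            mean_level = base[pi] * ion
            for ch, info in channels.items():
                level = mean_level * (effect[pi] if info.condition == cond_b
                                      else 1.0)
                row[ch] = level * rng.lognormal(mean=0.0, sigma=sigma)
            rows.append(row)
    table = PeptideQuantTable(data=pd.DataFrame(rows), channels=channels)
    truth = SimulationTruth(
        features=pd.DataFrame(truth_rows),
        params={"n_proteins": n_proteins,
                "peptides_per_protein": peptides_per_protein,
                "frac_de": frac_de, "fold": fold, "cv": cv, "n_rep": n_rep,
                "seed": seed, "conditions": list(conditions),
                "fraction": fraction, "frac_nonunique": frac_nonunique,
                "frac_low_purity": frac_low_purity})
    return table, truth


def simulate_microarray(n_genes: int = 2000, frac_de: float = 0.05,
                        effect_log2: float = 1.0, sigma: float = 0.25,
                        n_per_group: int = 3, seed: int = 0,
                        groups: tuple[str, str] = ("control", "case"),
                        organism: str = "human",
                        ) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate a log2-intensity microarray matrix with planted DEGs.

    Gene baselines are Normal(8, 2) on the log2 scale; a planted fraction
    of genes is shifted by +/- ``effect_log2`` in the second group; noise
    is i.i.d. Normal(0, sigma).
    """
    if not (0.0 <= frac_de < 1.0):
        raise ConfigError("frac_de must lie in [0, 1)")
    if sigma <= 0:
        raise ConfigError("sigma must be positive")
    if n_per_group < 2:
        raise ConfigError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    grp_a, grp_b = groups

    n_de = int(round(frac_de * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    direction = np.full(n_genes, "none", dtype=object)
    direction[de_idx[: n_de // 2]] = "up"
    direction[de_idx[n_de // 2:]] = "down"
    shift = np.zeros(n_genes)
    shift[direction == "up"] = effect_log2
    shift[direction == "down"] = -effect_log2

    baseline = rng.normal(8.0, 2.0, size=n_genes)
    samples = [f"{grp_a}_{i + 1}" for i in range(n_per_group)] + \
              [f"{grp_b}_{i + 1}" for i in range(n_per_group)]
    data = np.empty((n_genes, 2 * n_per_group))
    for j, s in enumerate(samples):
        mean = baseline + (shift if j >= n_per_group else 0.0)
        data[:, j] = mean + rng.normal(0.0, sigma, size=n_genes)
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")
    matrix = ExpressionMatrix(
        values=pd.DataFrame(data, index=genes, columns=samples),
        groups={s: (grp_b if j >= n_per_group else grp_a)
                for j, s in enumerate(samples)},
        organism=organism)
    truth = SimulationTruth(
        features=pd.DataFrame({"gene_id": genes,
                               "is_de": direction != "none",
                               "direction": direction,
                               "effect_log2": shift}),
        params={"n_genes": n_genes, "frac_de": frac_de,
                "effect_log2": effect_log2, "sigma": sigma,
                "n_per_group": n_per_group, "seed": seed,
                "groups": list(groups), "organism": organism})
    return matrix, truth


def simulate_model_fc(n_genes: int = 200, n_models: int = 4,
                      block_spec: Optional[Sequence[dict]] = None,
                      noise_sigma: float = 0.1, seed: int = 0,
                      ) -> tuple[FoldChangeMatrix, SimulationTruth]:
    """Simulate a genes x models fold-change matrix with planted blocks.

    ``block_spec`` is a sequence of dicts with keys ``n_genes``,
    ``models`` (names or indices), ``sign`` (+1/-1) and optional ``mean``
    (default 1.0 on the log2 scale).  Blocks occupy disjoint consecutive
    gene ranges; remaining genes are background noise around zero.
    """
    if noise_sigma < 0:
        raise ConfigError("noise_sigma must be nonnegative")
    models = [f"model{j + 1}" for j in range(n_models)]
    if block_spec is None:
        # default: one block per model pair, alternating sign, |log2FC| = 2,
        # covering about half the genes (sparse multi-column blocks are
        # recoverable; dense single-column ones are not — see module tests)
        block_spec = [{"n_genes": n_genes // (2 * n_models),
                       "models": [models[j], models[(j + 1) % n_models]],
                       "sign": 1 if j % 2 == 0 else -1, "mean": 2.0}
                      for j in range(n_models)]
    total = sum(int(b["n_genes"]) for b in block_spec)
    if total > n_genes:
        raise ConfigError(f"blocks claim {total} genes but only {n_genes} "
                          "exist (blocks must not overlap)")
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id")
    values = rng.normal(0.0, noise_sigma, size=(n_genes, n_models))
    labels = np.full(n_genes, -1)
    start = 0
    resolved_blocks = []
    for bi, block in enumerate(block_spec):
        nb = int(block["n_genes"])
        sign = int(block.get("sign", 1))
        mean = float(block.get("mean", 1.0))
        block_models = [models[m] if isinstance(m, int) else str(m)
                        for m in block["models"]]
        unknown = set(block_models) - set(models)
        if unknown:
            raise ConfigError(f"block {bi} names unknown models {unknown}")
        cols = [models.index(m) for m in block_models]
        values[start:start + nb, cols] += sign * mean
        labels[start:start + nb] = bi
        resolved_blocks.append({"block": bi, "n_genes": nb, "sign": sign,
                                "mean": mean, "models": block_models})
        start += nb
    df = pd.DataFrame(values, index=genes, columns=models)
    membership = pd.DataFrame(False, index=genes, columns=models)
    for b in resolved_blocks:
        rows = labels == b["block"]
        membership.loc[rows, b["models"]] = True
    fc = FoldChangeMatrix(values=df, deg_membership=membership,
                          normalized=False)
    truth = SimulationTruth(
        features=pd.DataFrame({"gene_id": genes, "block": labels}),
        params={"n_genes": n_genes, "n_models": n_models,
                "blocks": resolved_blocks, "noise_sigma": noise_sigma,
                "seed": seed})
    return fc, truth


def simulate_gmt(n_terms: int = 20, term_size_range: tuple[int, int] = (10, 30),
                 universe: Union[int, Sequence[str]] = 500,
                 overlap_spec: Optional[Sequence[tuple[int, int, int]]] = None,
                 seed: int = 0) -> GeneSetCollection:
    """Simulate a GMT collection, optionally planting exact pair overlaps.

    ``overlap_spec`` entries (size_i, size_j, shared) prepend term pairs
    with exactly ``shared`` common genes, for exercising Dice thresholds.
    Remaining terms draw their members uniformly from the universe.
    """
    if isinstance(universe, int):
        genes = [f"G{i:05d}" for i in range(universe)]
    else:
        genes = list(universe)
    lo, hi = term_size_range
    if hi > len(genes) or lo < 1 or lo > hi:
        raise ConfigError("term_size_range infeasible for the universe")
    rng = np.random.default_rng(seed)
    sets: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    ti = 0

    def add(members):
        nonlocal ti
        term = f"T{ti:04d}"
        sets[term] = frozenset(members)
        names[term] = f"simulated term {ti}"
        ti += 1

    for spec in overlap_spec or []:
        size_i, size_j, shared = spec
        need = size_i + size_j - shared
        if shared > min(size_i, size_j) or need > len(genes):
            raise ConfigError(f"infeasible overlap spec {spec!r}")
        pool = rng.choice(len(genes), size=need, replace=False)
        common = [genes[i] for i in pool[:shared]]
        only_i = [genes[i] for i in pool[shared:size_i]]
        only_j = [genes[i] for i in pool[size_i:]]
        add(common + only_i)
        add(common + only_j)
    while ti < n_terms:
        size = int(rng.integers(lo, hi + 1))
        add(genes[i] for i in rng.choice(len(genes), size=size, replace=False))
    return GeneSetCollection(sets=sets, names=names, universe=frozenset(genes))
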