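"""TMT differential-expression stage.

Peptide filtering (uniqueness, isolation purity, intensity floor),
DE-peptide calling against a channel-permutation empirical null, and
rollup of direction-consistent DE peptides to differentially expressed
proteins, plus the cross-fraction overlap bookkeeping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, PermdiffError
from .io import PeptideQuantTable
from .stats import EmpiricalNull, build_empirical_null, empirical_p, \
    group_statistics

__all__ = [
    "DEPCall", "filter_peptides", "build_channel_null", "call_de_peptides",
    "rollup_proteins", "cross_fraction_overlap",
]


@dataclass(frozen=True)
class DEPCall:
    """A protein called differentially expressed in one fraction."""

    protein_group: str
    direction: str  # "up" | "down"
    n_de_peptides: int
    supporting_peptides: tuple[str, ...]
    fraction: Optional[str] = None


def _log2_block(table: PeptideQuantTable,
                channels: Sequence[str]) -> np.ndarray:
    """log2 intensities with zeros mapped to NaN (treated as missing)."""
    values = table.data[list(channels)].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logged = np.log2(values)
    logged[values <= 0] = np.nan
    return logged


def filter_peptides(table: PeptideQuantTable, purity_min: float = 0.75,
                    intensity_percentile: float = 5.0) -> PeptideQuantTable:
    """Apply the uniqueness / purity / intensity-floor peptide filters.

    Retains peptides that (i) are unique to one protein group, (ii) have
    isolation purity strictly greater than ``purity_min``, and (iii) have
    a maximum log2 intensity across channels strictly greater than the
    ``intensity_percentile``-th percentile of the distribution of all
    peptides' max log2 intensities.
    """
    df = table.data
    logged = _log2_block(table, table.channel_columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        max_log2 = np.nanmax(logged, axis=1)
    finite = max_log2[np.isfinite(max_log2)]
    if finite.size == 0:
        raise PermdiffError("no peptide has a positive intensity")
    floor = np.percentile(finite, intensity_percentile)
    keep = (df["is_unique"].to_numpy(dtype=bool)
            & (df["isolation_purity"].to_numpy(dtype=float) > purity_min)
            & np.isfinite(max_log2) & (max_log2 > floor))
    if not keep.any():
        raise PermdiffError(
            "no peptides survive filtering; review purity_min "
            f"({purity_min}) and intensity_percentile ({intensity_percentile})")
    return PeptideQuantTable(data=df.loc[keep].reset_index(drop=True),
                             channels=dict(table.channels))


def _contrast_channels(table: PeptideQuantTable,
                       contrast: tuple[str, str]) -> tuple[list[str], list[str]]:
    cond_a, cond_b = contrast
    chan_a = table.channels_for(cond_a)
    chan_b = table.channels_for(cond_b)
    for cond, chans in ((cond_a, chan_a), (cond_b, chan_b)):
        if not chans:
            raise ConfigError(f"condition {cond!r} absent from channel map "
                              f"(known: {table.conditions()})")
    return chan_a, chan_b


def build_channel_null(table: PeptideQuantTable, contrast: tuple[str, str],
                       n_perm: int = 100, seed: int = 0,
                       lmr_percentiles: tuple[float, float] = (5.0, 95.0),
                       ) -> EmpiricalNull:
    """Channel-permutation null of (T, LMR) pooled over all peptides."""
    chan_a, chan_b = _contrast_channels(table, contrast)
    data = _log2_block(table, chan_a + chan_b)
    labels = ["a"] * len(chan_a) + ["b"] * len(chan_b)
    return build_empirical_null(data, labels, scheme="channel_permutation",
                                n_perm=n_perm, seed=seed,
                                lmr_percentiles=lmr_percentiles)


def call_de_peptides(table: PeptideQuantTable, contrast: tuple[str, str],
                     null: EmpiricalNull, alpha: float = 0.05,
                     min_replicates: int = 2) -> pd.DataFrame:
    """Call DE peptides for one contrast against a channel-permutation null.

    A peptide is DE iff its two-tailed empirical p (for T) is below
    ``alpha`` AND its |LMR| strictly exceeds the null-derived cutoff AND
    it is quantified (nonzero) in more than ``min_replicates`` replicates
    of at least one condition.

    Returns one row per peptide with columns peptide_id, protein_group,
    T, LMR, p, direction, is_de.
    """
    chan_a, chan_b = _contrast_channels(table, contrast)
    data = _log2_block(table, chan_a + chan_b)
    idx_a = np.arange(len(chan_a))
    idx_b = np.arange(len(chan_a), len(chan_a) + len(chan_b))
    t, lmr = group_statistics(data, idx_a, idx_b)
    with np.errstate(invalid="ignore"):
        p = empirical_p(t, null.null_T, tail="two")
    support = ((np.sum(np.isfinite(data[:, idx_a]), axis=1) > min_replicates)
               | (np.sum(np.isfinite(data[:, idx_b]), axis=1) > min_replicates))
    ok = np.isfinite(t) & np.isfinite(lmr) & np.isfinite(p)
    is_de = np.zeros(len(t), dtype=bool)
    is_de[ok] = (p[ok] < alpha) & (np.abs(lmr[ok]) > null.lmr_cutoff) \
        & support[ok]
    direction = np.where(lmr > 0, "up", np.where(lmr < 0, "down", "none"))
    direction = np.where(np.isfinite(lmr), direction, "none")
    return pd.DataFrame({
        "peptide_id": table.data["peptide_id"].to_numpy(),
        "protein_group": table.data["protein_group"].to_numpy(),
        "T": t, "LMR": lmr, "p": p,
        "direction": direction, "is_de": is_de,
    })


def rollup_proteins(de_peptides: pd.DataFrame,
                    fraction: Optional[str] = None) -> list[DEPCall]:
    """Roll DE peptides up to protein calls.

    A protein group is a DEP iff it has two or more DE peptides that all
    share one direction; groups with mixed-direction DE peptides make no
    call.  Output is sorted by protein group.
    """
    calls: list[DEPCall] = []
    de = de_peptides.loc[de_peptides["is_de"]]
    for protein, sub in de.groupby("protein_group"):
        directions = set(sub["direction"])
        if len(sub) >= 2 and len(directions) == 1:
            calls.append(DEPCall(
                protein_group=str(protein),
                direction=next(iter(directions)),
                n_de_peptides=len(sub),
                supporting_peptides=tuple(sorted(sub["peptide_id"])),
                fraction=fraction))
    return sorted(calls, key=lambda c: c.protein_group)


def deps_to_frame(calls: Sequence[DEPCall]) -> pd.DataFrame:
    """Tabular form of a DEP list (peptide ids joined with '|')."""
    return pd.DataFrame([{
        "protein_group": c.protein_group, "direction": c.direction,
        "n_de_peptides": c.n_de_peptides,
        "supporting_peptides": "|".join(c.supporting_peptides),
        "fraction": c.fraction,
    } for c in calls], columns=["protein_group", "direction", "n_de_peptides",
                                "supporting_peptides", "fraction"])


def cross_fraction_overlap(dep_nucleus: Sequence[DEPCall],
                           dep_cytoplasm: Sequence[DEPCall]) -> dict:
    """Direction-matched protein overlap between two fractions."""
    def by_direction(calls, direction):
        return {c.protein_group for c in calls if c.direction == direction}

    common_up = by_direction(dep_nucleus, "up") & by_direction(dep_cytoplasm, "up")
    common_down = (by_direction(dep_nucleus, "down")
                   & by_direction(dep_cytoplasm, "down"))
    return {
        "common_up": common_up,
        "common_down": common_down,
        "n_up": len(common_up),
        "n_down": len(common_down),
        "n_common": len(common_up) + len(common_down),
    }
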