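"""Readers and writers for the pipeline's tabular and graph formats.

Canonical table dialect is TSV (tab-delimited, UTF-8, "." decimal); CSV is
accepted via ``sep=","``.  Peptide tables are wide: one row per peptide,
one intensity column per TMT channel, with the channel -> (condition,
replicate) assignment supplied explicitly as a channel map rather than
inferred from column names.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConfigError, ParseError, SchemaError

__all__ = [
    "ChannelInfo", "PeptideQuantTable", "ExpressionMatrix", "GeneSetCollection",
    "read_peptide_table", "write_peptide_table",
    "read_channel_map", "write_channel_map",
    "read_expression_matrix", "write_expression_matrix",
    "read_gmt", "write_gmt", "write_network", "write_manifest",
]

PEPTIDE_META_COLUMNS = ["peptide_id", "protein_group", "is_unique",
                        "isolation_purity"]


@dataclass(frozen=True)
class ChannelInfo:
    condition: str
    replicate: int
    fraction: Optional[str] = None


@dataclass
class PeptideQuantTable:
    """Peptide rows with protein-group mapping, purity and reporter intensities.

    ``data`` holds the metadata columns plus one nonnegative intensity
    column per channel; ``channels`` maps each channel column to its
    (condition, replicate[, fraction]) assignment.
    """

    data: pd.DataFrame
    channels: dict[str, ChannelInfo]

    def __post_init__(self) -> None:
        missing = [c for c in PEPTIDE_META_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"peptide table lacks columns: {missing}")
        absent = [ch for ch in self.channels if ch not in self.data.columns]
        if absent:
            raise SchemaError(f"channel columns missing from table: {absent}")
        if self.data["peptide_id"].duplicated().any():
            dup = self.data.loc[self.data["peptide_id"].duplicated(), "peptide_id"]
            raise SchemaError(
                f"duplicate peptide rows (duplicate (peptide, channel) cells): "
                f"{sorted(set(dup))[:5]}")
        purity = self.data["isolation_purity"].to_numpy(dtype=float)
        if np.any((purity < 0) | (purity > 1)):
            raise SchemaError("isolation_purity must lie in [0, 1]")

    @property
    def channel_columns(self) -> list[str]:
        return list(self.channels)

    @property
    def n_peptides(self) -> int:
        return len(self.data)

    def intensities(self) -> pd.DataFrame:
        """Peptide x channel intensity block, indexed by peptide_id."""
        return self.data.set_index("peptide_id")[self.channel_columns].astype(float)

    def channels_for(self, condition: str,
                     fraction: Optional[str] = None) -> list[str]:
        return [ch for ch, info in self.channels.items()
                if info.condition == condition
                and (fraction is None or info.fraction == fraction)]

    def conditions(self) -> list[str]:
        seen: list[str] = []
        for info in self.channels.values():
            if info.condition not in seen:
                seen.append(info.condition)
        return seen


@dataclass
class ExpressionMatrix:
    """Genes x samples log2-intensity matrix with a sample -> group map."""

    values: pd.DataFrame
    groups: dict[str, str]
    organism: str = "human"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()]
            raise SchemaError(f"duplicated gene ids: {sorted(set(dup))[:5]}")
        unlabeled = [s for s in self.values.columns if s not in self.groups]
        if unlabeled:
            raise ConfigError(f"samples without a group label: {unlabeled}")
        sizes = pd.Series({s: g for s, g in self.groups.items()
                           if s in self.values.columns}).value_counts()
        for grp, n in sizes.items():
            if n < 2:
                warnings.warn(f"group {grp!r} has a single sample; "
                              "t statistics will be undefined", stacklevel=2)

    def samples_for(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups.get(s) == group]

    def group_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.values.columns:
            out[self.groups[s]] = out.get(self.groups[s], 0) + 1
        return out


@dataclass
class GeneSetCollection:
    """Term id -> (name, member gene set) plus a background universe."""

    sets: dict[str, frozenset]
    names: dict[str, str] = field(default_factory=dict)
    universe: Optional[frozenset] = None

    def __post_init__(self) -> None:
        empty = [t for t, members in self.sets.items() if not members]
        if empty:
            warnings.warn(f"dropping {len(empty)} empty gene sets", stacklevel=2)
            for t in empty:
                self.sets.pop(t)
                self.names.pop(t, None)
        if self.universe is None:
            self.universe = frozenset().union(*self.sets.values()) \
                if self.sets else frozenset()

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term: str) -> frozenset:
        return self.sets[term]


# ---------------------------------------------------------------------------
# peptide tables

def read_peptide_table(path: Union[str, Path],
                       channel_map: Mapping[str, Union[ChannelInfo, tuple]],
                       sep: str = "\t") -> PeptideQuantTable:
    """Read a wide peptide TSV and attach the channel -> condition map."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"peptide_id": str,
                                               "protein_group": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None
    channels = {ch: info if isinstance(info, ChannelInfo) else ChannelInfo(*info)
                for ch, info in channel_map.items()}
    for col in PEPTIDE_META_COLUMNS + list(channels):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in channels:
        raw = pd.to_numeric(df[col], errors="coerce")
        bad = raw.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{path}: non-numeric intensity in column {col!r} "
                             f"at row {row} (value {df[col].iloc[row]!r})")
        if raw.isna().any():
            row = int(np.flatnonzero(raw.isna())[0])
            raise ValueError(f"{path}: missing intensity in column {col!r} "
                             f"at row {row}")
        neg = raw < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0])
            raise ValueError(f"{path}: negative intensity in column {col!r} "
                             f"at row {row}")
        df[col] = raw.astype(float)
    df["is_unique"] = df["is_unique"].astype(bool)
    df["isolation_purity"] = df["isolation_purity"].astype(float)
    return PeptideQuantTable(data=df, channels=channels)


def write_peptide_table(table: PeptideQuantTable, path: Union[str, Path],
                        sep: str = "\t") -> None:
    cols = PEPTIDE_META_COLUMNS + table.channel_columns
    table.data[cols].to_csv(path, sep=sep, index=False)


def read_channel_map(path: Union[str, Path],
                     sep: str = "\t") -> dict[str, ChannelInfo]:
    """Read a channel map TSV: columns channel, condition, replicate[, fraction]."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("channel", "condition", "replicate"):
        if col not in df.columns:
            raise SchemaError(f"channel map lacks column {col!r}")
    out: dict[str, ChannelInfo] = {}
    for _, row in df.iterrows():
        frac = row.get("fraction")
        out[row["channel"]] = ChannelInfo(
            condition=row["condition"], replicate=int(row["replicate"]),
            fraction=None if pd.isna(frac) else frac)
    return out


def write_channel_map(channels: Mapping[str, ChannelInfo],
                      path: Union[str, Path], sep: str = "\t") -> None:
    rows = [{"channel": ch, "condition": info.condition,
             "replicate": info.replicate, "fraction": info.fraction}
            for ch, info in channels.items()]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_matrix(path: Union[str, Path],
                           group_labels: Mapping[str, str],
                           organism: str = "human",
                           sep: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples numeric TSV (first column = gene id)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path} is empty") from None
    if df.shape[1] == 0:
        raise SchemaError(f"{path} has no sample columns")
    df = df.astype(float)
    return ExpressionMatrix(values=df, groups=dict(group_labels),
                            organism=organism)


def write_expression_matrix(matrix: ExpressionMatrix, path: Union[str, Path],
                            sep: str = "\t") -> None:
    matrix.values.to_csv(path, sep=sep, index_label="gene_id")


def read_group_labels(path: Union[str, Path], sep: str = "\t") -> dict[str, str]:
    """Read a sample -> group TSV with columns sample, group."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise SchemaError(f"group table lacks column {col!r}")
    return dict(zip(df["sample"], df["group"]))


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: Union[str, Path]) -> GeneSetCollection:
    """Parse a GMT file: per line, term id, description, then members."""
    sets: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has "
                             f"{len(fields)} field(s), need >= 3")
        term, desc = fields[0], fields[1]
        members = frozenset(g for g in fields[2:] if g)
        sets[term] = members
        names[term] = desc
    return GeneSetCollection(sets=sets, names=names)


def write_gmt(collection: GeneSetCollection, path: Union[str, Path]) -> None:
    lines = []
    for term in sorted(collection.sets):
        members = sorted(collection.sets[term])
        lines.append("\t".join([term, collection.names.get(term, term)]
                               + members))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# networks

def write_network(net: nx.Graph, path: Union[str, Path],
                  format: str = "graphml") -> None:
    """Export a process network as GraphML or SIF.

    GraphML preserves node attributes and Dice edge weights (6 decimals);
    SIF writes one ``node<TAB>dice<TAB>node`` line per edge plus isolated
    nodes on their own lines.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        for node, attrs in net.nodes(data=True):
            clean = {}
            for k, v in attrs.items():
                if isinstance(v, (frozenset, set, list, tuple)):
                    clean[k] = "|".join(sorted(map(str, v)))
                else:
                    clean[k] = v
            g.add_node(node, **clean)
        for u, v, attrs in net.edges(data=True):
            clean = dict(attrs)
            if "dice" in clean:
                clean["dice"] = round(float(clean["dice"]), 6)
            g.add_edge(u, v, **clean)
        nx.write_graphml(g, path)
    elif format == "sif":
        lines = []
        connected = set()
        for u, v in sorted(net.edges()):
            lines.append(f"{u}\tdice\t{v}")
            connected.update((u, v))
        for node in sorted(set(net.nodes()) - connected):
            lines.append(str(node))
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ConfigError(f"unknown network format {format!r} "
                          "(expected 'graphml' or 'sif')")


def write_manifest(out_dir: Union[str, Path], command: str, seed: int,
                   config_dict: dict, extra: Optional[dict] = None) -> Path:
    """Write a deterministic run manifest (config + seed + versions)."""
    import scipy

    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "config": config_dict,
        "versions": {
            "permdiff": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "networkx": nx.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    out = Path(out_dir) / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
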