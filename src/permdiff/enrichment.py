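"""Gene-set enrichment and the Sørensen–Dice process network.

Enrichment is a one-sided hypergeometric test against a user-supplied GMT
collection (an optional EASE-style variant subtracts one from the
overlap).  A term passes when p < 0.1 and it shares at least five genes
with the query list.  Passing terms across clusters become network nodes;
node pairs are connected when they share at least ``min_shared`` genes
and their Dice coefficient strictly exceeds the cutoff (0.4, or the 95th
percentile of the all-pairs Dice distribution when set to "auto").
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import PermdiffError
from .io import GeneSetCollection
from .stats import z_from_p

__all__ = ["dice", "enrich", "build_process_network"]


def dice(a: set, b: set) -> float:
    """Sørensen–Dice coefficient 2|A∩B| / (|A|+|B|)."""
    if not a and not b:
        return 0.0
    return 2.0 * len(set(a) & set(b)) / (len(a) + len(b))


def enrich(gene_list: Sequence[str], collection: GeneSetCollection,
           universe: Optional[set] = None, p_threshold: float = 0.1,
           min_genes: int = 5, ease: bool = False) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene list against every term.

    Genes outside the universe are dropped with a warning.  The returned
    frame has one row per term: overlap, term_size, p, z (= -ppf(p)) and
    the passes flag (p < ``p_threshold`` and overlap >= ``min_genes``).
    ``ease=True`` subtracts one from the overlap before computing p
    (DAVID's EASE-score convention), making the test more conservative.
    """
    genes = set(gene_list)
    if not genes:
        raise PermdiffError("empty gene list")
    uni = set(universe) if universe is not None else set(collection.universe)
    outside = genes - uni
    if outside:
        warnings.warn(f"dropping {len(outside)} query genes outside the "
                      "universe", stacklevel=2)
        genes &= uni
        if not genes:
            raise PermdiffError("no query genes inside the universe")
    M = len(uni)
    n_query = len(genes)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term] & uni
        k = len(genes & members)
        k_eff = max(k - 1, 0) if ease else k
        p = float(sps.hypergeom.sf(k_eff - 1, M, len(members), n_query))
        p = min(p, 1.0)
        z = z_from_p(p) if 0.0 < p < 1.0 else -np.inf
        rows.append({
            "term": term, "name": collection.names.get(term, term),
            "overlap": k, "term_size": len(members), "p": p, "z": z,
            "passes": bool(p < p_threshold and k >= min_genes),
            "genes": "|".join(sorted(genes & members)),
        })
    return pd.DataFrame(rows).set_index("term")


def auto_dice_cutoff(dices: Sequence[float]) -> float:
    """95th percentile of the all-pairs Dice distribution."""
    arr = np.asarray(list(dices), dtype=float)
    if arr.size == 0:
        raise PermdiffError("no node pairs to derive an automatic cutoff")
    return float(np.percentile(arr, 95))


def build_process_network(enrichments: Mapping[str, pd.DataFrame],
                          collection: GeneSetCollection,
                          min_shared: int = 3,
                          cutoff: Union[float, str] = 0.4) -> nx.Graph:
    """Build the Dice-weighted network over terms passing in any cluster.

    ``enrichments`` maps a cluster label to an ``enrich`` result frame.
    Nodes are the union of passing terms, annotated with the clusters
    that enriched them, their member-gene sets and the best (smallest)
    enrichment p across clusters.  An edge (i, j) is kept iff the terms
    share >= ``min_shared`` genes AND dice > cutoff (strict).  With
    ``cutoff="auto"`` the cutoff is the 95th percentile of the Dice
    coefficients over all node pairs.
    """
    node_clusters: dict[str, list[str]] = {}
    node_p: dict[str, float] = {}
    for cluster, frame in enrichments.items():
        passing = frame.index[frame["passes"]]
        for term in passing:
            node_clusters.setdefault(term, []).append(str(cluster))
            p = float(frame.loc[term, "p"])
            node_p[term] = min(p, node_p.get(term, 1.0))
    g = nx.Graph()
    if not node_clusters:
        warnings.warn("no passing terms; returning an empty network",
                      stacklevel=2)
        return g
    for term in sorted(node_clusters):
        members = collection.sets[term]
        g.add_node(term, clusters="|".join(sorted(set(node_clusters[term]))),
                   n_genes=len(members), p=node_p[term],
                   z=z_from_p(node_p[term]) if 0 < node_p[term] < 1 else np.inf)
    pairs = list(itertools.combinations(sorted(node_clusters), 2))
    coeffs = {(u, v): dice(set(collection.sets[u]), set(collection.sets[v]))
              for u, v in pairs}
    cut = auto_dice_cutoff(coeffs.values()) if cutoff == "auto" else float(cutoff)
    for (u, v), d in coeffs.items():
        shared = len(collection.sets[u] & collection.sets[v])
        if shared >= min_shared and d > cut:
            g.add_edge(u, v, dice=d, shared=shared)
    g.graph["dice_cutoff"] = cut
    g.graph["min_shared"] = min_shared
    return g
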