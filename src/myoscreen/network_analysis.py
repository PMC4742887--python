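"""Interaction-network classification of hit kinases relative to MRFs.

Hit kinases are placed on an undirected protein-interaction graph
(HPRD/BioGRID-style two-column edge lists) together with the myogenic
regulatory factors (MRFs: the MyoD and Mef2 families). A kinase is a
*direct* regulator of an MRF when the graph contains the edge, a
*semi-direct* regulator when the two share at least one intermediary
neighbor (one interaction node away), and *unconnected* otherwise. Kinases
absent from the graph altogether are flagged so they can be excluded from
network maps.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .screen_data import ScreenFormatError, ScreenValidationError, normalize_symbol

__all__ = [
    "DEFAULT_MRFS",
    "MOUSE_HUMAN_OVERRIDES",
    "MrfSet",
    "PairConnection",
    "RegulatorClassification",
    "read_edge_list",
    "merge_graphs",
    "classify_regulators",
    "summarize_network",
    "export_subnetwork",
    "read_sif",
]

logger = logging.getLogger(__name__)

#: Human symbols of the MyoD- and Mef2-family myogenic regulatory factors.
DEFAULT_MRFS = ("MYOD1", "MYOG", "MYF5", "MYF6", "MEF2A", "MEF2C", "MEF2D")

#: Mouse symbols whose human ortholog is not the plain uppercase form.
MOUSE_HUMAN_OVERRIDES: dict[str, str] = {
    "MYOD": "MYOD1",
    "MYOGENIN": "MYOG",
}

_HEADER_TOKENS = (
    "gene",
    "symbol",
    "interactor",
    "node",
    "protein",
    "source",
    "target",
    "entrez",
    "official",
)


@dataclass(frozen=True)
class MrfSet:
    """Ordered set of myogenic-regulatory-factor symbols."""

    symbols: tuple[str, ...] = DEFAULT_MRFS

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ScreenValidationError("MRF set must be non-empty")
        norm = [normalize_symbol(s) for s in self.symbols]
        if len(set(norm)) != len(norm):
            raise ScreenValidationError("MRF symbols must be unique")

    @property
    def normalized(self) -> tuple[str, ...]:
        return tuple(normalize_symbol(s) for s in self.symbols)


def _apply_map(symbol: str, symbol_map: Mapping[str, str] | None) -> str:
    key = normalize_symbol(symbol)
    if symbol_map:
        key = normalize_symbol(symbol_map.get(key, key))
    return key


def read_edge_list(
    path: str | Path,
    symbol_map: Mapping[str, str] | None = None,
    source: str | None = None,
) -> nx.Graph:
    """Read a two-column tab-separated edge list into an undirected graph.

    Extra columns are ignored, a header line is auto-detected, symbols are
    uppercased/trimmed (with an optional mouse-to-human override map applied
    first), and self-loops/duplicates are dropped with counts logged. Edge
    provenance is kept in the ``sources`` edge attribute.
    """
    path = Path(path)
    source = source or path.name
    if symbol_map:
        symbol_map = {normalize_symbol(k): v for k, v in symbol_map.items()}
    graph = nx.Graph()
    n_self_loops = n_duplicates = 0
    with path.open(encoding="utf-8") as fh:
        first = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ScreenFormatError(
                    f"{path}:{lineno}: expected >= 2 tab-separated columns"
                )
            if first:
                first = False
                lowered = (cols[0] + " " + cols[1]).lower()
                if any(tok in lowered for tok in _HEADER_TOKENS):
                    continue
            a = _apply_map(cols[0], symbol_map)
            b = _apply_map(cols[1], symbol_map)
            if not a or not b:
                continue
            if a == b:
                n_self_loops += 1
                continue
            if graph.has_edge(a, b):
                n_duplicates += 1
                graph.edges[a, b]["sources"].add(source)
                continue
            graph.add_edge(a, b, sources={source})
    if graph.number_of_edges() == 0:
        logger.warning("%s: empty edge list", path)
    if n_self_loops or n_duplicates:
        logger.info(
            "%s: dropped %d self-loops, merged %d duplicate edges",
            path,
            n_self_loops,
            n_duplicates,
        )
    return graph


def merge_graphs(*graphs: nx.Graph) -> nx.Graph:
    """Union of edge sets, merging per-edge source provenance."""
    merged = nx.Graph()
    for g in graphs:
        merged.add_nodes_from(g.nodes)
        for a, b, data in g.edges(data=True):
            if merged.has_edge(a, b):
                merged.edges[a, b]["sources"] |= set(data.get("sources", set()))
            else:
                merged.add_edge(a, b, sources=set(data.get("sources", set())))
    return merged


@dataclass(frozen=True)
class PairConnection:
    """Connection of one (kinase, MRF) pair."""

    kinase: str
    mrf: str
    connection: str  # direct | semi_direct | unconnected
    intermediaries: frozenset[str] = frozenset()


_LABEL_RANK = {"unconnected": 0, "semi_direct": 1, "direct": 2}


@dataclass
class RegulatorClassification:
    """Per-pair connections plus per-kinase summary labels.

    A kinase's label is its strongest connection over all MRFs
    (direct > semi_direct > unconnected); kinases with no edges at all in
    the graph are additionally flagged in ``absent_from_graph``.
    """

    pairs: dict[tuple[str, str], PairConnection]
    kinases: tuple[str, ...]
    mrfs: tuple[str, ...]
    absent_from_graph: frozenset[str]

    @property
    def kinase_labels(self) -> dict[str, str]:
        labels: dict[str, str] = {k: "unconnected" for k in self.kinases}
        for (k, _), pc in self.pairs.items():
            if _LABEL_RANK[pc.connection] > _LABEL_RANK[labels[k]]:
                labels[k] = pc.connection
        return labels

    def connected_pairs(self) -> list[PairConnection]:
        return [pc for pc in self.pairs.values() if pc.connection != "unconnected"]


def classify_regulators(
    graph: nx.Graph,
    kinases: Iterable[str],
    mrfs: MrfSet | Sequence[str] = DEFAULT_MRFS,
    allow_hub_intermediaries: bool = False,
) -> RegulatorClassification:
    """Label each (kinase, MRF) pair as direct, semi-direct or unconnected.

    Direct requires the kinase-MRF edge; semi-direct requires, for a pair
    without a direct edge, at least one common neighbor, recording all such
    intermediaries. By default intermediaries may not themselves be query
    kinases or MRFs (they form the distinct middle tier of the network
    maps); set ``allow_hub_intermediaries`` to permit them.
    """
    if not isinstance(mrfs, MrfSet):
        mrfs = MrfSet(tuple(mrfs))
    kin = tuple(sorted({normalize_symbol(k) for k in kinases}))
    mrf_syms = mrfs.normalized
    overlap = set(kin) & set(mrf_syms)
    if overlap:
        raise ScreenValidationError(
            f"kinase and MRF sets overlap: {sorted(overlap)}"
        )
    excluded = set() if allow_hub_intermediaries else set(kin) | set(mrf_syms)
    pairs: dict[tuple[str, str], PairConnection] = {}
    for k in kin:
        k_neighbors = set(graph.neighbors(k)) if k in graph else set()
        for m in mrf_syms:
            m_neighbors = set(graph.neighbors(m)) if m in graph else set()
            if m in k_neighbors:
                pairs[(k, m)] = PairConnection(k, m, "direct")
                continue
            intermediaries = (k_neighbors & m_neighbors) - excluded
            if intermediaries:
                pairs[(k, m)] = PairConnection(
                    k, m, "semi_direct", frozenset(intermediaries)
                )
            else:
                pairs[(k, m)] = PairConnection(k, m, "unconnected")
    absent = frozenset(
        k for k in kin if k not in graph or graph.degree(k) == 0
    )
    if absent:
        logger.info("%d kinases display no connections in the graph", len(absent))
    return RegulatorClassification(
        pairs=pairs, kinases=kin, mrfs=mrf_syms, absent_from_graph=absent
    )


def summarize_network(classification: RegulatorClassification) -> dict[str, pd.DataFrame]:
    """Three rankings: kinases by MRFs reached, MRFs by kinases connected,
    and intermediary nodes by distinct MRFs they link to hit kinases.

    Counting is per pair (multiple intermediaries for the same pair count
    once); ties are broken by count descending, then symbol ascending.
    """
    kin_counts: dict[str, int] = {}
    mrf_counts: dict[str, int] = {}
    inter_mrfs: dict[str, set[str]] = {}
    for pc in classification.connected_pairs():
        kin_counts[pc.kinase] = kin_counts.get(pc.kinase, 0) + 1
        mrf_counts[pc.mrf] = mrf_counts.get(pc.mrf, 0) + 1
        for v in pc.intermediaries:
            inter_mrfs.setdefault(v, set()).add(pc.mrf)

    def _ranked(counts: Mapping[str, int], col: str) -> pd.DataFrame:
        rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["symbol", col])

    return {
        "kinases": _ranked(kin_counts, "n_mrfs_reached"),
        "mrfs": _ranked(mrf_counts, "n_kinases_connected"),
        "intermediaries": _ranked(
            {v: len(ms) for v, ms in inter_mrfs.items()}, "n_mrfs_linked"
        ),
    }


def export_subnetwork(
    classification: RegulatorClassification,
    graph: nx.Graph,
    sif_path: str | Path,
    attrs_path: str | Path | None = None,
) -> None:
    """Write the kinase-MRF subnetwork as Cytoscape SIF + node attributes.

    The SIF contains the direct kinase-MRF edges (relation ``direct``) and,
    for each semi-direct pair, the kinase-intermediary and intermediary-MRF
    legs (relation ``via``). The node-attribute TSV labels each node as
    kinase, mrf or intermediary.
    """
    sif_path = Path(sif_path)
    edges: set[tuple[str, str, str]] = set()
    roles: dict[str, str] = {}
    for pc in classification.connected_pairs():
        roles[pc.kinase] = "kinase"
        roles[pc.mrf] = "mrf"
        if pc.connection == "direct":
            edges.add((pc.kinase, "direct", pc.mrf))
        else:
            for v in pc.intermediaries:
                roles.setdefault(v, "intermediary")
                edges.add((pc.kinase, "via", v))
                edges.add((v, "via", pc.mrf))
    with sif_path.open("w", encoding="utf-8") as fh:
        for a, rel, b in sorted(edges):
            fh.write(f"{a}\t{rel}\t{b}\n")
    if attrs_path is not None:
        with Path(attrs_path).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["node", "role"])
            for node in sorted(roles):
                writer.writerow([node, roles[node]])


def read_sif(path: str | Path) -> nx.Graph:
    """Re-read a SIF file as an undirected graph (relation kept per edge)."""
    graph = nx.Graph()
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ScreenFormatError(
                    f"{path}:{lineno}: SIF lines need node<TAB>relation<TAB>node"
                )
            a, rel, b = cols
            graph.add_edge(normalize_symbol(a), normalize_symbol(b), relation=rel)
    return graph
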