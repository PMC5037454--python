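"""Sequence similarity networks (SSNs) for class delineation and validation.

Nodes are sequences; an undirected edge joins two sequences whose pairwise
alignment E-value passes a log10(E) cutoff.  Self pairs are dropped and the
two directed hits of a pair collapse to one edge weighted by the minimum
(most significant) E-value, so edge construction is symmetric and stable
under duplicate removal.  Sweeping the cutoff from -5 toward -200 splits the
network into progressively finer connected components; the sweep is read as
converged when the component count stops changing materially between
consecutive cutoffs.  Components, their majority labels and purities are the
sequence-only view of the class structure, and a query can be classified by
the modal label of the component it joins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .pairwise import AlignmentHit
from .refdb import ClassLabel

__all__ = [
    "Network",
    "Cluster",
    "ClusterSet",
    "build_network",
    "components",
    "sweep_cutoffs",
    "ssn_classify",
    "to_edge_tsv",
    "to_graphml",
]

DEFAULT_CUTOFF_START = -5.0
DEFAULT_CUTOFF_STOP = -200.0
DEFAULT_CUTOFF_STEP = -5.0
#: Relative component-count change below which consecutive cutoffs are "stable".
STABILITY_TOLERANCE = 0.02


@dataclass(frozen=True)
class Network:
    """SSN at a fixed logE cutoff."""

    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> dict[frozenset, float]:
        return {
            frozenset((u, v)): d["logE"] for u, v, d in self.graph.edges(data=True)
        }

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class Cluster:
    """One connected component with its label composition."""

    members: frozenset[str]
    majority_label: ClassLabel | None
    purity: float  # fraction of LABELED members carrying the modal label

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple[Cluster, ...]

    def __len__(self) -> int:
        return len(self.clusters)

    def cluster_of(self, node: str) -> Cluster:
        for c in self.clusters:
            if node in c.members:
                return c
        raise KeyError(node)


def _log10e(e_value: float) -> float:
    return math.log10(e_value) if e_value > 0 else -math.inf


def build_network(
    hits: Iterable[AlignmentHit],
    cutoff_logE: float,
    nodes: Iterable[str] | None = None,
) -> Network:
    """Build the SSN at one cutoff from a directed all-vs-all hit table.

    Self hits are removed; each unordered pair keeps a single edge weighted
    by the minimum E-value of its directed hits; edges whose log10(E) exceeds
    the cutoff are excluded.  ``nodes`` optionally pre-seeds the node set so
    sequences with no qualifying edges still appear as singletons.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        g.add_nodes_from((h.query_id, h.subject_id))
        if h.query_id == h.subject_id:
            continue
        key = tuple(sorted((h.query_id, h.subject_id)))
        if key not in best or h.e_value < best[key]:
            best[key] = h.e_value
    for (u, v), e in best.items():
        logE = _log10e(e)
        if logE <= cutoff_logE:
            g.add_edge(u, v, logE=logE, evalue=e)
    return Network(graph=g, cutoff=cutoff_logE)


def components(
    net: Network, labels: Mapping[str, ClassLabel] | None = None
) -> ClusterSet:
    """Connected components with majority label and purity.

    Purity is the fraction of a component's labeled members that carry the
    component's modal label; components with no labeled member get purity 1
    and no majority label.
    """
    labels = labels or {}
    clusters = []
    for comp in nx.connected_components(net.graph):
        labeled = [labels[n] for n in comp if n in labels]
        if labeled:
            counts: dict[ClassLabel, int] = {}
            for l in labeled:
                counts[l] = counts.get(l, 0) + 1
            modal = max(sorted(counts, key=lambda l: l.subclass_code),
                        key=lambda l: counts[l])
            purity = counts[modal] / len(labeled)
        else:
            modal, purity = None, 1.0
        clusters.append(
            Cluster(members=frozenset(comp), majority_label=modal, purity=purity)
        )
    ordered = tuple(sorted(clusters, key=lambda c: (-len(c), sorted(c.members)[0])))
    return ClusterSet(clusters=ordered)


def sweep_cutoffs(
    hits: Sequence[AlignmentHit],
    start: float = DEFAULT_CUTOFF_START,
    stop: float = DEFAULT_CUTOFF_STOP,
    step: float = DEFAULT_CUTOFF_STEP,
    nodes: Iterable[str] | None = None,
    tolerance: float = STABILITY_TOLERANCE,
) -> list[tuple[float, int, bool]]:
    """Component counts along the cutoff grid, with a per-step stability flag.

    The grid runs from ``start`` down to ``stop`` inclusive in (negative)
    ``step`` increments.  A grid point is flagged stable when the relative
    change in component count from the previous point is below ``tolerance``
    — the quantitative reading of "no major changes in clustering".
    """
    if start <= stop:
        raise ValueError("start must be > stop (cutoffs decrease)")
    if step >= 0:
        raise ValueError("step must be negative")
    node_list = list(nodes) if nodes is not None else None
    cutoffs = []
    c = start
    while c >= stop - 1e-9:
        cutoffs.append(c)
        c += step
    out: list[tuple[float, int, bool]] = []
    prev = None
    for cutoff in cutoffs:
        n = len(components(build_network(hits, cutoff, nodes=node_list)))
        stable = prev is not None and abs(n - prev) / max(prev, 1) < tolerance
        out.append((cutoff, n, stable))
        prev = n
    return out


def ssn_classify(
    query_id: str,
    hits: Iterable[AlignmentHit],
    cutoff_logE: float,
    labels: Mapping[str, ClassLabel],
    nodes: Iterable[str] | None = None,
) -> ClassLabel | None:
    """Label a query by the modal label of the component it joins.

    ``hits`` must cover reference-vs-reference and query-vs-reference pairs.
    Returns ``None`` ("unassigned") when the query's component contains no
    labeled reference — e.g. an isolated query node.
    """
    all_nodes = set(nodes) if nodes is not None else set()
    all_nodes.add(query_id)
    net = build_network(hits, cutoff_logE, nodes=all_nodes)
    clusters = components(net, labels={k: v for k, v in labels.items() if k != query_id})
    cluster = clusters.cluster_of(query_id)
    return cluster.majority_label


def to_edge_tsv(net: Network) -> str:
    """Edge list as ``id1<TAB>id2<TAB>logE`` rows, deterministically ordered."""
    lines = ["id1\tid2\tlogE"]
    for u, v, d in sorted(
        ((min(a, b), max(a, b), d) for a, b, d in net.graph.edges(data=True))
    ):
        lines.append(f"{u}\t{v}\t{d['logE']:.4f}")
    return "\n".join(lines) + "\n"


def to_graphml(net: Network) -> str:
    """GraphML serialization for external network viewers."""
    import io

    buf = io.BytesIO()
    nx.write_graphml(net.graph, buf)
    return buf.getvalue().decode()
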