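"""Construction of the regulatory element interaction network (REIN).

Nodes are merged chromatin-loop anchors, edges are loops (a loop whose two
anchors merged into one node becomes a self-loop).  Nodes inherit regulatory
element labels by overlap, connected components are found by breadth-first
search and only large components are retained, and a balanced labelled
dataset is drawn (all silencers positive; all non-silencers and enhancers
plus a 10% per-component promoter subsample negative).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .genomic_io import (
    LABEL_PRIORITY,
    ChromatinLoop,
    ElementClass,
    GenomicInterval,
    RegulatoryElement,
)

__all__ = [
    "REINGraph",
    "LabeledDataset",
    "filter_loops",
    "merge_anchors",
    "build_graph",
    "normalize_element",
    "assign_labels",
    "extract_components",
    "sample_negatives",
]

UNLABELED = "unlabeled"


@dataclass
class REINGraph:
    """The regulatory element interaction network.

    ``nodes`` maps node id -> merged anchor interval; ``edges`` is a set of
    unordered node-id pairs stored as sorted tuples (self-pairs allowed);
    ``labels`` maps node id -> element-class value or ``"unlabeled"``;
    ``components`` maps node id -> component id once components are annotated.
    """

    nodes: dict[int, GenomicInterval] = field(default_factory=dict)
    edges: set[tuple[int, int]] = field(default_factory=set)
    labels: dict[int, str] = field(default_factory=dict)
    components: dict[int, int] = field(default_factory=dict)

    def n_nodes(self) -> int:
        return len(self.nodes)

    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node: int) -> set[int]:
        """Distinct neighbours of ``node`` (includes itself iff a self-loop)."""
        out: set[int] = set()
        for u, v in self.edges:
            if u == node:
                out.add(v)
            elif v == node:
                out.add(u)
        return out

    def degree(self, node: int) -> int:
        """Number of incident non-self edges."""
        return sum(1 for u, v in self.edges if node in (u, v) and u != v)

    def has_self_loop(self, node: int) -> bool:
        return (node, node) in self.edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def validate(self) -> None:
        """Assert the structural invariants of the network."""
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise AssertionError(f"edge ({u},{v}) has a non-node endpoint")
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.nodes.values():
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda i: i.start)
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise AssertionError(
                        f"overlapping node intervals on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": {
                str(k): [iv.chrom, iv.start, iv.end] for k, iv in self.nodes.items()
            },
            "edges": sorted(list(e) for e in self.edges),
            "labels": {str(k): v for k, v in self.labels.items()},
            "components": {str(k): v for k, v in self.components.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "REINGraph":
        payload = json.loads(Path(path).read_text())
        nodes = {
            int(k): GenomicInterval(c, s, e)
            for k, (c, s, e) in payload["nodes"].items()
        }
        edges = {tuple(sorted(map(int, e))) for e in payload["edges"]}
        labels = {int(k): v for k, v in payload["labels"].items()}
        components = {int(k): int(v) for k, v in payload["components"].items()}
        return cls(nodes, edges, labels, components)

    def export_bed(self, path: str | Path) -> None:
        """Write node intervals as BED4 (name = node id / label)."""
        order = sorted(self.nodes, key=lambda k: (self.nodes[k].chrom, self.nodes[k].start))
        with open(path, "w") as fh:
            for k in order:
                iv = self.nodes[k]
                label = self.labels.get(k, UNLABELED)
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{k}|{label}\n")


@dataclass
class LabeledDataset:
    """Positive (silencer) and negative node-id sets with per-node provenance."""

    positives: set[int]
    negatives: set[int]
    provenance: dict[int, str]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise AssertionError("positives and negatives intersect")


def filter_loops(
    loops: Iterable[ChromatinLoop], max_anchor_len: int = 1000
) -> list[ChromatinLoop]:
    """Keep loops whose anchors are BOTH strictly shorter than ``max_anchor_len``."""
    return [
        lp
        for lp in loops
        if lp.anchor_a.length() < max_anchor_len
        and lp.anchor_b.length() < max_anchor_len
    ]


def merge_anchors(
    anchors: Sequence[GenomicInterval],
) -> tuple[list[GenomicInterval], dict[GenomicInterval, GenomicInterval]]:
    """Merge overlapping anchors into their connected-overlap closure.

    Returns the merged intervals (sorted) and a map sending every input anchor
    to the single merged interval that covers it.  Chains of pairwise overlaps
    collapse into one interval; abutting-but-disjoint intervals do not merge.
    """
    merged: list[GenomicInterval] = []
    mapping: dict[GenomicInterval, GenomicInterval] = {}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for a in anchors:
        by_chrom.setdefault(a.chrom, []).append(a)
    for chrom in sorted(by_chrom):
        ivs = sorted(set(by_chrom[chrom]), key=lambda i: (i.start, i.end))
        groups: list[list[GenomicInterval]] = []
        cur: list[GenomicInterval] = []
        cur_end = -1
        for iv in ivs:
            if cur and iv.start < cur_end:  # strict: touching does not merge
                cur.append(iv)
                cur_end = max(cur_end, iv.end)
            else:
                if cur:
                    groups.append(cur)
                cur = [iv]
                cur_end = iv.end
        if cur:
            groups.append(cur)
        for grp in groups:
            m = GenomicInterval(chrom, grp[0].start, max(i.end for i in grp))
            merged.append(m)
            for iv in grp:
                mapping[iv] = m
    merged.sort(key=lambda i: (i.chrom, i.start))
    return merged, mapping


def build_graph(filtered_loops: Sequence[ChromatinLoop]) -> REINGraph:
    """Build the REIN from filtered loops.

    Nodes are the merged anchors of all loop anchors; each loop contributes one
    undirected edge between the merged nodes of its anchors (a self-loop when
    both anchors merged into the same node); duplicate loop-derived edges are
    collapsed.
    """
    anchors = [a for lp in filtered_loops for a in (lp.anchor_a, lp.anchor_b)]
    merged, mapping = merge_anchors(anchors)
    node_id = {iv: i for i, iv in enumerate(merged)}
    graph = REINGraph(nodes=dict(enumerate(merged)))
    graph.labels = {i: UNLABELED for i in graph.nodes}
    for lp in filtered_loops:
        u = node_id[mapping[lp.anchor_a]]
        v = node_id[mapping[lp.anchor_b]]
        graph.edges.add((u, v) if u <= v else (v, u))
    graph.validate()
    return graph


def normalize_element(
    element: RegulatoryElement | GenomicInterval, half_flank: int = 300
) -> GenomicInterval:
    """Re-centre an element to ``2 * half_flank`` nt around its midpoint.

    The window is ``[c - half_flank, c + half_flank)`` with
    ``c = floor((start + end) / 2)``; a window that would start before the
    chromosome origin is clamped at 0 with a warning (and is then shorter).
    """
    iv = element.interval if isinstance(element, RegulatoryElement) else element
    c = (iv.start + iv.end) // 2
    start, end = c - half_flank, c + half_flank
    if start < 0:
        warnings.warn(
            f"window for element at {iv.chrom}:[{iv.start},{iv.end}) clamped at "
            "chromosome start",
            stacklevel=2,
        )
        start = 0
    return GenomicInterval(iv.chrom, start, end)


def assign_labels(
    graph: REINGraph,
    normalized_elements: Sequence[RegulatoryElement],
    min_overlap: int = 300,
    priority: Sequence[ElementClass] = LABEL_PRIORITY,
) -> REINGraph:
    """Attach element-class labels to nodes by strict overlap.

    A node receives an element's class iff their overlap exceeds
    ``min_overlap`` nt; a node reached by several classes takes the highest
    class in ``priority``.  If one element clears the threshold on several
    nodes (possible only when nodes abut), the node with the larger overlap
    wins, ties going to the leftmost; labels then still follow priority.
    Nodes touched by nothing stay unlabeled.  Labels are assigned in place and
    the graph is returned.
    """
    rank = {cls: i for i, cls in enumerate(priority)}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[int]]] = {}
    for chrom in {iv.chrom for iv in graph.nodes.values()}:
        ids = [k for k, iv in graph.nodes.items() if iv.chrom == chrom]
        ids.sort(key=lambda k: graph.nodes[k].start)
        starts = np.array([graph.nodes[k].start for k in ids], dtype=np.int64)
        ends = np.array([graph.nodes[k].end for k in ids], dtype=np.int64)
        by_chrom[chrom] = (starts, ends, ids)

    best: dict[int, ElementClass] = {}
    for el in normalized_elements:
        entry = by_chrom.get(el.interval.chrom)
        if entry is None:
            continue
        starts, ends, ids = entry
        lo = int(np.searchsorted(ends, el.interval.start, side="right"))
        hi = int(np.searchsorted(starts, el.interval.end, side="left"))
        hits = [
            (graph.nodes[ids[i]].overlap(el.interval), ids[i])
            for i in range(lo, hi)
        ]
        hits = [(ov, k) for ov, k in hits if ov > min_overlap]
        if not hits:
            continue
        # at most one node can normally exceed half the element length;
        # resolve the abutting-node corner case by larger overlap, then leftmost
        hits.sort(key=lambda t: (-t[0], graph.nodes[t[1]].start))
        node = hits[0][1]
        cur = best.get(node)
        if cur is None or rank[el.element_class] < rank[cur]:
            best[node] = el.element_class
    for node, cls in best.items():
        graph.labels[node] = cls.value
    return graph


def extract_components(graph: REINGraph, min_size: int = 100) -> REINGraph:
    """Annotate BFS connected components and drop small ones.

    Components with strictly more than ``min_size`` nodes are retained; the
    rest are removed together with their edges.  Component ids are assigned in
    order of each component's leftmost interval.
    """
    g = graph.to_networkx()
    comps = []
    seen: set[int] = set()
    for start in graph.nodes:
        if start in seen:
            continue
        comp = set(nx.bfs_tree(g, start).nodes)
        seen |= comp
        comps.append(comp)
    kept = [c for c in comps if len(c) > min_size]
    kept.sort(
        key=lambda c: min(
            (graph.nodes[k].chrom, graph.nodes[k].start) for k in c
        )
    )
    out = REINGraph()
    for cid, comp in enumerate(kept):
        for k in comp:
            out.nodes[k] = graph.nodes[k]
            out.labels[k] = graph.labels.get(k, UNLABELED)
            out.components[k] = cid
    out.edges = {
        (u, v) for u, v in graph.edges if u in out.nodes and v in out.nodes
    }
    out.validate()
    total = sum(len(c) for c in kept)
    assert total == out.n_nodes()
    return out


def sample_negatives(
    graph: REINGraph,
    promoter_fraction: float = 0.10,
    seed: int = 0,
) -> LabeledDataset:
    """Draw the labelled dataset: silencers positive; all non-silencers and
    enhancers plus ``floor(promoter_fraction * n_promoters)`` promoters per
    component (seeded, without replacement) negative."""
    rng = np.random.default_rng(seed)
    positives = {
        k for k, lab in graph.labels.items() if lab == ElementClass.SILENCER.value
    }
    negatives: set[int] = set()
    provenance: dict[int, str] = {k: "silencer" for k in positives}
    comp_ids = sorted(set(graph.components.values())) if graph.components else [0]
    for cid in comp_ids:
        if graph.components:
            members = [k for k, c in graph.components.items() if c == cid]
        else:
            members = list(graph.nodes)
        for k in members:
            lab = graph.labels.get(k, UNLABELED)
            if lab in (
                ElementClass.NON_SILENCER.value,
                ElementClass.ENHANCER.value,
            ):
                negatives.add(k)
                provenance[k] = lab
        promoters = sorted(
            k
            for k in members
            if graph.labels.get(k) == ElementClass.PROMOTER.value
        )
        n_take = int(np.floor(promoter_fraction * len(promoters)))
        if n_take > 0:
            chosen = rng.choice(len(promoters), size=n_take, replace=False)
            for i in sorted(chosen):
                negatives.add(promoters[i])
                provenance[promoters[i]] = "sampled_promoter"
    return LabeledDataset(positives, negatives, provenance)
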