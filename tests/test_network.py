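"""Interaction-network construction: anchor filtering and merging, edge and
self-loop creation, label priority, component extraction, negative sampling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from silencerein.genomic_io import (
    ChromatinLoop,
    ElementClass,
    GenomicInterval,
    RegulatoryElement,
)
from silencerein.network import (
    REINGraph,
    assign_labels,
    build_graph,
    extract_components,
    filter_loops,
    merge_anchors,
    normalize_element,
    sample_negatives,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def loop(a0, a1, b0, b1, chrom="chr1"):
    return ChromatinLoop(iv(a0, a1, chrom), iv(b0, b1, chrom))


# ---------------------------------------------------------------- filtering


class TestFilterLoops:
    @pytest.mark.parametrize(
        "len_a,len_b,kept",
        [
            (800, 950, True),  # both under the limit
            (1000, 500, False),  # exactly at the limit is out (strict <)
            (1200, 1200, False),
        ],
    )
    def test_strict_anchor_length_rule(self, len_a, len_b, kept):
        lp = loop(0, len_a, 5000, 5000 + len_b)
        assert (filter_loops([lp]) == [lp]) is kept


# ---------------------------------------------------------------- merging


def brute_force_merge(intervals):
    """Fixpoint oracle: merge any overlapping pair until stable."""
    cur = {(i.chrom, i.start, i.end) for i in intervals}
    changed = True
    while changed:
        changed = False
        items = sorted(cur)
        for x in items:
            for z in items:
                if x == z or x[0] != z[0]:
                    continue
                if x[1] < z[2] and z[1] < x[2]:
                    cur.discard(x)
                    cur.discard(z)
                    cur.add((x[0], min(x[1], z[1]), max(x[2], z[2])))
                    changed = True
                    break
            if changed:
                break
    return sorted(cur)


class TestMergeAnchors:
    def test_two_overlapping_intervals_union(self):
        merged, mapping = merge_anchors([iv(100, 700), iv(600, 1200)])
        assert merged == [iv(100, 1200)]
        assert mapping[iv(100, 700)] == iv(100, 1200)

    def test_chain_merges_transitively(self):
        # first and third are disjoint but chained through the middle one
        chain = [iv(0, 100), iv(90, 200), iv(190, 300)]
        merged, _ = merge_anchors(chain)
        assert merged == [iv(0, 300)]
        assert [(m.chrom, m.start, m.end) for m in merged] == brute_force_merge(chain)

    def test_disjoint_intervals_untouched(self):
        merged, _ = merge_anchors([iv(0, 100), iv(200, 300)])
        assert merged == [iv(0, 100), iv(200, 300)]

    def test_abutting_intervals_do_not_merge(self):
        merged, _ = merge_anchors([iv(0, 100), iv(100, 200)])
        assert len(merged) == 2

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 300),
                st.integers(1, 80),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_fixpoint_oracle(self, raw):
        intervals = [GenomicInterval(c, s, s + ln) for c, s, ln in raw]
        merged, mapping = merge_anchors(intervals)
        assert [(m.chrom, m.start, m.end) for m in merged] == brute_force_merge(
            intervals
        )
        for src in intervals:
            tgt = mapping[src]
            assert tgt.chrom == src.chrom
            assert tgt.start <= src.start and src.end <= tgt.end

    def test_oracle_agreement_on_many_random_sets(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 10))
            intervals = [
                GenomicInterval(
                    "chr1", int(s), int(s) + int(ln)
                )
                for s, ln in zip(
                    rng.integers(0, 400, n), rng.integers(1, 100, n)
                )
            ]
            merged, _ = merge_anchors(intervals)
            assert [
                (m.chrom, m.start, m.end) for m in merged
            ] == brute_force_merge(intervals)


# ---------------------------------------------------------------- graph build


class TestBuildGraph:
    def test_independent_loops_give_four_nodes_two_edges(self):
        g = build_graph([loop(0, 100, 1000, 1100), loop(2000, 2100, 3000, 3100)])
        assert g.n_nodes() == 4 and g.n_edges() == 2

    def test_overlapping_anchor_pair_creates_self_loop(self):
        g = build_graph([loop(0, 600, 300, 900)])
        assert g.n_nodes() == 1
        assert g.has_self_loop(0)

    def test_duplicate_loops_collapse_to_one_edge(self):
        g = build_graph([loop(0, 100, 1000, 1100), loop(0, 100, 1000, 1100)])
        assert g.n_edges() == 1

    def test_counts_match_union_find_oracle(self, rng):
        # independent construction: union-find over anchor overlap closure
        loops = []
        for _ in range(60):
            s1, s2 = int(rng.integers(0, 3000)), int(rng.integers(0, 3000))
            loops.append(loop(s1, s1 + int(rng.integers(50, 200)),
                              s2, s2 + int(rng.integers(50, 200))))
        anchors = sorted(
            {(a.start, a.end) for lp in loops for a in (lp.anchor_a, lp.anchor_b)}
        )
        parent = list(range(len(anchors)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, a in enumerate(anchors):
            for j in range(i + 1, len(anchors)):
                b = anchors[j]
                if a[0] < b[1] and b[0] < a[1]:
                    parent[find(i)] = find(j)
        index = {a: find(i) for i, a in enumerate(anchors)}
        expected_nodes = len(set(index.values()))
        expected_edges = {
            tuple(
                sorted(
                    (
                        index[(lp.anchor_a.start, lp.anchor_a.end)],
                        index[(lp.anchor_b.start, lp.anchor_b.end)],
                    )
                )
            )
            for lp in loops
        }
        g = build_graph(loops)
        assert g.n_nodes() == expected_nodes
        assert g.n_edges() == len(expected_edges)

    def test_node_intervals_never_overlap(self, rng):
        loops = []
        for _ in range(100):
            s1, s2 = int(rng.integers(0, 5000)), int(rng.integers(0, 5000))
            loops.append(loop(s1, s1 + 120, s2, s2 + 120))
        build_graph(loops).validate()  # raises on any overlap


# ---------------------------------------------------------------- windows


class TestNormalizeElement:
    def test_recentred_to_600(self):
        assert normalize_element(iv(1000, 2000)) == iv(1200, 1800)

    def test_tiny_element_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = normalize_element(iv(100, 101))
        assert out == iv(0, 400)

    def test_already_centred_600_is_identity(self):
        assert normalize_element(iv(0, 600)) == iv(0, 600)


# ---------------------------------------------------------------- labelling


def graph_with_nodes(*intervals):
    g = REINGraph(nodes=dict(enumerate(intervals)))
    g.labels = {i: "unlabeled" for i in g.nodes}
    return g


def element(start, end, cls, chrom="chr1"):
    return RegulatoryElement(iv(start, end, chrom), ElementClass(cls))


class TestAssignLabels:
    def test_overlap_above_threshold_labels_node(self):
        g = graph_with_nodes(iv(0, 700))
        assign_labels(g, [element(350, 950, "silencer")])
        assert g.labels[0] == "silencer"

    def test_overlap_exactly_at_threshold_leaves_unlabeled(self):
        g = graph_with_nodes(iv(0, 700))
        assign_labels(g, [element(400, 1000, "silencer")])  # overlap == 300
        assert g.labels[0] == "unlabeled"

    def test_silencer_outranks_promoter_despite_smaller_overlap(self):
        g = graph_with_nodes(iv(0, 700))
        # promoter overlaps 400 nt, silencer only 310 nt — priority wins
        assign_labels(
            g,
            [element(0, 400, "promoter"), element(390, 990, "silencer")],
        )
        assert g.labels[0] == "silencer"

    def test_priority_is_order_sensitive(self):
        elements = [element(0, 400, "promoter"), element(290, 900, "silencer")]
        g1 = graph_with_nodes(iv(0, 700))
        assign_labels(g1, elements)
        assert g1.labels[0] == "silencer"
        g2 = graph_with_nodes(iv(0, 700))
        assign_labels(
            g2,
            elements,
            priority=(
                ElementClass.PROMOTER,
                ElementClass.ENHANCER,
                ElementClass.NON_SILENCER,
                ElementClass.SILENCER,
            ),
        )
        assert g2.labels[0] == "promoter"

    def test_element_over_two_abutting_nodes_labels_larger_overlap(self):
        g = graph_with_nodes(iv(0, 350), iv(350, 1000))
        # window [40, 640): 310 nt on node 0, 290 nt on node 1
        assign_labels(g, [element(40, 640, "enhancer")])
        assert g.labels[0] == "enhancer"
        assert g.labels[1] == "unlabeled"


# ---------------------------------------------------------------- components


def chain_component(start_id, n, base):
    """n nodes in a path, intervals disjoint."""
    nodes = {
        start_id + i: iv(base + 1000 * i, base + 1000 * i + 500) for i in range(n)
    }
    edges = {(start_id + i, start_id + i + 1) for i in range(n - 1)}
    return nodes, edges


class TestExtractComponents:
    def test_small_components_dropped_strictly(self):
        g = REINGraph()
        for sid, n, base in [(0, 150, 0), (1000, 50, 10_000_000)]:
            nodes, edges = chain_component(sid, n, base)
            g.nodes.update(nodes)
            g.edges.update(edges)
        g.labels = {k: "unlabeled" for k in g.nodes}
        out = extract_components(g, min_size=100)
        assert out.n_nodes() == 150
        assert set(out.components.values()) == {0}

    def test_exactly_min_size_component_dropped(self):
        g = REINGraph()
        nodes, edges = chain_component(0, 100, 0)
        g.nodes, g.edges = nodes, edges
        g.labels = {k: "unlabeled" for k in g.nodes}
        assert extract_components(g, min_size=100).n_nodes() == 0

    def test_connected_graph_is_one_component(self):
        g = REINGraph()
        nodes, edges = chain_component(0, 120, 0)
        g.nodes, g.edges = nodes, edges
        g.labels = {k: "unlabeled" for k in g.nodes}
        out = extract_components(g, min_size=100)
        assert set(out.components.values()) == {0}
        assert out.n_nodes() == 120

    def test_component_sizes_sum_to_node_count(self):
        g = REINGraph()
        for sid, n, base in [(0, 120, 0), (500, 130, 10_000_000)]:
            nodes, edges = chain_component(sid, n, base)
            g.nodes.update(nodes)
            g.edges.update(edges)
        g.labels = {k: "unlabeled" for k in g.nodes}
        out = extract_components(g, min_size=100)
        sizes = {}
        for cid in out.components.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        assert sum(sizes.values()) == out.n_nodes() == 250


# ---------------------------------------------------------------- negatives


def labelled_graph(counts_per_component):
    """counts_per_component: list of dicts class -> count."""
    g = REINGraph()
    nid = 0
    for cid, counts in enumerate(counts_per_component):
        for cls, n in counts.items():
            for _ in range(n):
                g.nodes[nid] = iv(nid * 1000, nid * 1000 + 500)
                g.labels[nid] = cls
                g.components[nid] = cid
                nid += 1
    return g


class TestSampleNegatives:
    def test_counts_follow_floor_rule(self):
        g = labelled_graph(
            [{"non_silencer": 5, "enhancer": 7, "promoter": 40, "silencer": 3}]
        )
        ds = sample_negatives(g, seed=0)
        assert len(ds.negatives) == 5 + 7 + 4  # floor(0.10 * 40) == 4
        assert len(ds.positives) == 3

    def test_no_promoters_means_only_other_negatives(self):
        g = labelled_graph([{"non_silencer": 2, "enhancer": 3}])
        assert len(sample_negatives(g, seed=0).negatives) == 5

    def test_floor_of_fractional_promoter_share(self):
        g = labelled_graph([{"promoter": 25}])
        ds = sample_negatives(g, seed=7)
        assert len(ds.negatives) == 2  # floor(2.5)

    def test_sampling_is_per_component(self):
        g = labelled_graph([{"promoter": 19}, {"promoter": 19}])
        # per component: floor(1.9) == 1 each; pooled would give floor(3.8) == 3
        assert len(sample_negatives(g, seed=0).negatives) == 2

    def test_seed_reproducibility_and_disjointness(self):
        g = labelled_graph(
            [{"promoter": 30, "silencer": 4, "enhancer": 2}] * 3
        )
        a = sample_negatives(g, seed=42)
        b = sample_negatives(g, seed=42)
        c = sample_negatives(g, seed=43)
        assert a.negatives == b.negatives
        assert a.negatives != c.negatives  # different seed, different draw
        assert not a.positives & a.negatives
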