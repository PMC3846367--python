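"""Lineage trees: parsimony construction, edge atomicity, measures,
serialization — checked against an exhaustive Steiner-minimum oracle."""

import itertools
import random
from io import StringIO

import networkx as nx
from Bio import Phylo

from igpipe.clone_builder import Clone, CloneKey
from igpipe.germline_assign import SegmentMatch, VDJAssignment
from igpipe.lineage import (
    apply_events, build_tree, events_from_rows, measure_tree, tree_cost,
    write_tree,
)


def make_clone(germline, members, clone_id="c0"):
    """Clone whose alignment is trivial (equal-length, substitution-only
    member sequences)."""
    assert all(len(m) == len(germline) for m in members)
    ms = []
    for i, m in enumerate(members):
        ms.append(VDJAssignment(
            read_id=f"m{i}", bases=m,
            v_match=SegmentMatch("V", 0, 0, 0, 0, 0, 0, 0),
            j_match=SegmentMatch("J", 0, 0, 0, 0, 0, 0, 0),
            d_match=None, junction="", germline_sequence=germline))
    clone = Clone(clone_id, CloneKey("V", "none", "J"), ms)
    clone.consensus_germline = germline
    clone.alignment = [germline] + list(members)
    clone.alignment_ids = ["germline"] + [f"m{i}" for i in range(len(members))]
    return clone


def steiner_minimum(germline, members):
    """Brute-force minimum-mutation tree cost: minimum spanning tree over
    root + members + every subset of candidate Steiner points drawn from
    the sub-hypercube spanned by the varying positions."""
    varying = [i for i in range(len(germline))
               if any(m[i] != germline[i] for m in members)]
    states = {}
    for i in varying:
        states[i] = sorted({germline[i]} | {m[i] for m in members})
    candidates = set()
    for combo in itertools.product(*(states[i] for i in varying)):
        s = list(germline)
        for i, c in zip(varying, combo):
            s[i] = c
        candidates.add("".join(s))
    terminals = {germline} | set(members)
    candidates -= terminals

    def mst_cost(nodes):
        nodes = list(nodes)
        if len(nodes) <= 1:
            return 0
        g = nx.Graph()
        for a, b in itertools.combinations(nodes, 2):
            g.add_edge(a, b, weight=sum(x != y for x, y in zip(a, b)))
        return int(sum(d["weight"]
                       for _, _, d in nx.minimum_spanning_edges(g)))

    best = mst_cost(terminals)
    lower = len(varying)
    max_extra = max(0, len(terminals) - 2)
    for k in range(1, max_extra + 1):
        if best == lower:
            break
        for extra in itertools.combinations(sorted(candidates), k):
            best = min(best, mst_cost(terminals | set(extra)))
            if best == lower:
                break
    return best


def random_perfect_phylogeny_instance(rng, length, n_members):
    """Members generated down a random mutation tree with every site
    mutated at most once overall (binary alphabet)."""
    germline = "".join(rng.choice("AT") for _ in range(length))
    free_sites = list(range(length))
    rng.shuffle(free_sites)
    seqs = [germline]
    members = []
    for _ in range(n_members):
        parent = rng.choice(seqs)
        child = parent
        for _ in range(rng.randint(0, 2)):
            if not free_sites:
                break
            site = free_sites.pop()
            flip = "T" if child[site] == "A" else "A"
            child = child[:site] + flip + child[site + 1:]
        seqs.append(child)
        members.append(child)
    return germline, members


class TestBuildTree:
    def test_nested_mutations_form_chain(self):
        clone = make_clone("AAAA", ["AAAT", "AAGT"])
        tree = build_tree(clone)
        assert tree_cost(tree) == 2
        m = measure_tree(tree)
        assert m.root_outdegree == 1 and m.max_leaf_depth == 2

    def test_single_unmutated_member_root_only(self):
        tree = build_tree(make_clone("AAAA", ["AAAA"]))
        assert tree_cost(tree) == 0
        assert tree.n_nodes == 1
        assert tree.graph.nodes[tree.root]["read_ids"] == ("m0",)

    def test_disjoint_mutations_form_star(self):
        clone = make_clone("AAAA", ["TAAA", "AATA"])
        tree = build_tree(clone)
        assert tree_cost(tree) == 2
        assert measure_tree(tree).root_outdegree == 2

    def test_multi_event_edges_expand_to_unit_chains(self):
        clone = make_clone("AAAA", ["ATTA"])
        tree = build_tree(clone)
        assert tree_cost(tree) == 2
        assert tree.n_nodes == 3  # root, one inferred midpoint, observed

    def test_edge_atomicity_everywhere(self):
        rng = random.Random(41)
        for _ in range(50):
            germline, members = random_perfect_phylogeny_instance(
                rng, rng.randint(3, 8), rng.randint(1, 4))
            tree = build_tree(make_clone(germline, members))
            for u, v in tree.graph.edges():
                diff = tree.node_events(v) ^ tree.node_events(u)
                assert len(diff) == 1

    def test_indel_events_are_atomic(self):
        clone = Clone("c1", CloneKey("V", "none", "J"), [
            VDJAssignment(
                read_id="m0", bases="ACTTGT",
                v_match=SegmentMatch("V", 0, 0, 0, 0, 0, 0, 0),
                j_match=SegmentMatch("J", 0, 0, 0, 0, 0, 0, 0),
                d_match=None, junction="", germline_sequence="ACGT")])
        clone.consensus_germline = "ACGT"
        clone.alignment = ["AC--GT", "ACTTGT"]
        clone.alignment_ids = ["germline", "m0"]
        tree = build_tree(clone)
        assert tree_cost(tree) == 1  # a 2-nt insertion is one event


class TestOracle:
    def test_exhaustive_small_instances(self):
        """Tree cost equals the brute-force Steiner minimum on all member
        multisets from single-mutation histories over short binary
        sequences."""
        length = 4
        germline = "AAAA"
        singles = [germline[:i] + "T" + germline[i + 1:] for i in range(length)]
        pool = [germline] + singles
        for members in itertools.combinations_with_replacement(pool, 3):
            uniq = sorted(set(members))
            tree = build_tree(make_clone(germline, list(members)))
            assert tree_cost(tree) == steiner_minimum(germline, uniq)

    def test_random_perfect_phylogeny_instances(self):
        rng = random.Random(42)
        for _ in range(120):
            germline, members = random_perfect_phylogeny_instance(
                rng, rng.randint(3, 8), rng.randint(1, 4))
            tree = build_tree(make_clone(germline, members))
            assert tree_cost(tree) == steiner_minimum(germline,
                                                      sorted(set(members)))

    def test_infinite_sites_cost_is_union_size(self):
        rng = random.Random(43)
        for _ in range(100):
            germline, members = random_perfect_phylogeny_instance(
                rng, 8, rng.randint(1, 4))
            clone = make_clone(germline, members)
            union = set()
            for i, m in enumerate(members):
                union |= events_from_rows(m, germline)
            tree = build_tree(clone)
            assert tree_cost(tree) == len(union)


class TestMeasures:
    def test_chain(self):
        tree = build_tree(make_clone("AAAA", ["TTTA"]))
        m = measure_tree(tree)
        assert (m.n_leaves, m.max_leaf_depth, m.trunk_length,
                m.root_outdegree) == (1, 3, 3, 1)

    def test_star(self):
        members = ["TAAAA", "ATAAA", "AATAA", "AAATA"]
        tree = build_tree(make_clone("AAAAA", members))
        m = measure_tree(tree)
        assert (m.n_leaves, m.trunk_length, m.root_outdegree) == (4, 0, 4)
        assert m.min_leaf_depth == m.max_leaf_depth == 1

    def test_root_only(self):
        tree = build_tree(make_clone("AAAA", ["AAAA"]))
        m = measure_tree(tree)
        assert (m.n_leaves, m.max_leaf_depth, m.trunk_length) == (0, 0, 0)


class TestSerialization:
    def test_adjacency_rows(self, tmp_path):
        tree = build_tree(make_clone("AAAA", ["AAAT", "AAGT"]))
        p = tmp_path / "t.adj.tsv"
        write_tree(tree, p, "adjacency_tsv")
        rows = p.read_text().strip().split("\n")
        assert len(rows) == 1 + 2  # header + one row per edge

    def test_dot_is_valid_digraph(self, tmp_path):
        tree = build_tree(make_clone("AAAA", ["TAAA", "AATA"]))
        p = tmp_path / "t.dot"
        write_tree(tree, p, "dot")
        text = p.read_text()
        assert text.startswith("digraph")
        assert text.count("->") == tree.n_edges
        assert text.rstrip().endswith("}")

    def test_newick_leaf_count(self, tmp_path):
        tree = build_tree(make_clone("AAAAA",
                                     ["TAAAA", "ATAAA", "AATAA"]))
        p = tmp_path / "t.nwk"
        write_tree(tree, p, "newick")
        phylo = Phylo.read(StringIO(p.read_text()), "newick")
        assert phylo.count_terminals() == measure_tree(tree).n_leaves


def test_apply_events_roundtrip():
    member_row = "ACTTAC-TGGT"
    germ_row__ = "AC-TACGTG-T"
    # sanity of the hand-built rows
    assert len(member_row) == len(germ_row__)
    ev = events_from_rows(member_row, germ_row__)
    assert apply_events(germ_row__.replace("-", ""), ev) == \
        member_row.replace("-", "")
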