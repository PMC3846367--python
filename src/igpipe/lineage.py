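"""Clonal lineage tree construction by parsimony.

Each clone's members are placed on a rooted tree whose root is the
consensus germline and whose every edge carries exactly one mutation event
(substitution, or an atomic insertion/deletion block). Unobserved common
ancestors are inferred by closing the members' mutation sets under pairwise
intersection; each node then attaches to the present proper subset of
maximal size, and edges spanning several events are expanded into chains of
inferred intermediates. Under the infinite-sites condition (no site mutated
twice within the clone) this construction is a minimum-mutation (Steiner)
tree; with homoplasy it is a deterministic heuristic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from igpipe import seqio
from igpipe.clone_builder import Clone

# A mutation event is a hashable tuple on ungapped-germline coordinates:
#   ("sub", pos, from_base, to_base)
#   ("ins", pos, inserted_bases)
#   ("del", pos, deleted_bases)
Event = tuple


def events_from_rows(member_row: str, germline_row: str) -> frozenset[Event]:
    """Mutation set of one member relative to the germline, read off the
    clone alignment. Indel blocks are atomic single events."""
    if len(member_row) != len(germline_row):
        raise ValueError("alignment rows differ in length")
    events: list[Event] = []
    gpos = 0
    i = 0
    n = len(member_row)
    while i < n:
        mc, gc = member_row[i], germline_row[i]
        if gc == "-" and mc != "-":
            j = i
            ins = []
            while j < n and germline_row[j] == "-" and member_row[j] != "-":
                ins.append(member_row[j])
                j += 1
            events.append(("ins", gpos, "".join(ins)))
            i = j
        elif mc == "-" and gc != "-":
            j = i
            dele = []
            start = gpos
            while j < n and member_row[j] == "-" and germline_row[j] != "-":
                dele.append(germline_row[j])
                gpos += 1
                j += 1
            events.append(("del", start, "".join(dele)))
            i = j
        else:
            if mc != gc and mc != "-":
                events.append(("sub", gpos, gc, mc))
            gpos += gc != "-"
            i += 1
    return frozenset(events)


def apply_events(germline: str, events: frozenset[Event]) -> str:
    """Sequence obtained by applying a mutation set to the ungapped
    germline. Events are applied right to left so earlier coordinates stay
    valid; at a shared coordinate the substitution/deletion acts on the
    germline base before an insertion lands in front of it."""
    seq = list(germline)
    order = sorted(events,
                   key=lambda e: (e[1], 0 if e[0] == "ins" else 1),
                   reverse=True)
    for ev in order:
        if ev[0] == "sub":
            seq[ev[1]] = ev[3]
        elif ev[0] == "del":
            del seq[ev[1] : ev[1] + len(ev[2])]
        else:
            seq[ev[1] : ev[1]] = list(ev[2])
    return "".join(seq)


@dataclass
class LineageTree:
    """Rooted arborescence; every edge carries exactly one mutation event."""

    clone_id: str
    graph: nx.DiGraph  # node attrs: events (frozenset), status, read_ids
    root: str = "root"

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def children(self, node: str) -> list[str]:
        return sorted(self.graph.successors(node))

    def node_events(self, node: str) -> frozenset[Event]:
        return self.graph.nodes[node]["events"]

    def edge_event(self, parent: str, child: str) -> Event:
        return self.graph.edges[parent, child]["event"]


def _event_sort_key(ev: Event):
    return (ev[1], ev[0], ev[2:])


def _fmt_event(ev: Event) -> str:
    if ev[0] == "sub":
        return f"{ev[2]}{ev[1]}{ev[3]}"
    if ev[0] == "ins":
        return f"ins{ev[1]}:{ev[2]}"
    return f"del{ev[1]}:{ev[2]}"


def build_tree(clone: Clone) -> LineageTree:
    """Build the lineage tree of a finalized clone.

    Steps: (1) express each member as its mutation set relative to the
    consensus germline; (2) close the set of nodes under pairwise
    intersection, to a fixed point (inferred ancestors); (3) attach every
    node to the largest proper subset present, ties preferring observed
    nodes then lexicographic node id, nodes with no proper subset to the
    root; (4) expand edges carrying k > 1 events into chains of k-1
    inferred intermediates, in ascending event position. Output is
    deterministic for a fixed clone.
    """
    germline_row = clone.germline_row
    member_sets: dict[frozenset[Event], list[str]] = {}
    for m in clone.members:
        ev = events_from_rows(clone.member_row(m.read_id), germline_row)
        member_sets.setdefault(ev, []).append(m.read_id)

    # (2) intersection closure
    nodes: set[frozenset[Event]] = set(member_sets) | {frozenset()}
    changed = True
    while changed:
        changed = False
        current = sorted(nodes, key=lambda s: (len(s), sorted(map(_fmt_event, s))))
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                inter = current[i] & current[j]
                if inter not in nodes:
                    nodes.add(inter)
                    changed = True

    # deterministic node ids: root, then by (size, formatted events)
    ordered = sorted(nodes, key=lambda s: (len(s), sorted(map(_fmt_event, s))))
    ids: dict[frozenset[Event], str] = {}
    for k, s in enumerate(ordered):
        if not s:
            ids[s] = "root"
        elif s in member_sets:
            ids[s] = f"obs{k:03d}"
        else:
            ids[s] = f"inf{k:03d}"

    g = nx.DiGraph()
    for s in ordered:
        nid = ids[s]
        status = ("root" if not s
                  else "observed" if s in member_sets else "inferred")
        g.add_node(nid, events=s, status=status,
                   read_ids=tuple(member_sets.get(s, ())))

    # (3) attach to the maximal proper subset
    for s in ordered:
        if not s:
            continue
        candidates = [t for t in nodes if t < s]
        parent = min(
            candidates,
            key=lambda t: (-len(t), t not in member_sets, ids[t]),
        )
        g.add_edge(ids[parent], ids[s],
                   events=sorted(s - parent, key=_event_sort_key))

    # (4) expand multi-event edges into chains of inferred intermediates
    chain_idx = 0
    for u, v in list(g.edges()):
        evs = g.edges[u, v]["events"]
        if len(evs) == 1:
            g.edges[u, v]["event"] = evs[0]
            del g.edges[u, v]["events"]
            continue
        g.remove_edge(u, v)
        prev = u
        acc = set(g.nodes[u]["events"])
        for ev in evs[:-1]:
            acc.add(ev)
            nid = f"mid{chain_idx:03d}"
            chain_idx += 1
            g.add_node(nid, events=frozenset(acc), status="inferred",
                       read_ids=())
            g.add_edge(prev, nid, event=ev)
            prev = nid
        g.add_edge(prev, v, event=evs[-1])

    assert nx.is_arborescence(g), "lineage tree must be a rooted tree"
    for u, v in g.edges():
        diff = g.nodes[v]["events"] ^ g.nodes[u]["events"]
        assert len(diff) == 1 and g.edges[u, v]["event"] in diff, \
            "every edge must carry exactly one mutation event"
    return LineageTree(clone.clone_id, g)


def tree_cost(tree: LineageTree) -> int:
    """Parsimony score: total mutation events on the tree == edge count."""
    return tree.n_edges


@dataclass
class TreeMeasures:
    clone_id: str
    n_nodes: int
    n_observed: int
    n_inferred: int
    n_leaves: int
    root_outdegree: int
    min_leaf_depth: int
    avg_leaf_depth: float
    max_leaf_depth: int
    trunk_length: int
    avg_internal_outdegree: float


def measure_tree(tree: LineageTree) -> TreeMeasures:
    """Graphical summary of a lineage tree.

    The trunk is the path from the root to the first branching node
    (outdegree >= 2), or the maximum depth if the tree never branches; the
    root alone does not count as a leaf.
    """
    g = tree.graph
    depth = nx.shortest_path_length(g, tree.root)
    leaves = [n for n in g.nodes if g.out_degree(n) == 0 and n != tree.root]
    internal = [n for n in g.nodes if g.out_degree(n) > 0]
    statuses = nx.get_node_attributes(g, "status")
    leaf_depths = [depth[n] for n in leaves]
    # trunk: walk from the root until a branching point
    trunk = 0
    node = tree.root
    max_depth = max(depth.values()) if depth else 0
    while True:
        succ = list(g.successors(node))
        if len(succ) >= 2:
            break
        if not succ:
            trunk = max_depth
            break
        trunk += 1
        node = succ[0]
    if g.out_degree(tree.root) >= 2:
        trunk = 0
    return TreeMeasures(
        clone_id=tree.clone_id,
        n_nodes=g.number_of_nodes(),
        n_observed=sum(1 for s in statuses.values() if s == "observed"),
        n_inferred=sum(1 for s in statuses.values() if s == "inferred"),
        n_leaves=len(leaves),
        root_outdegree=g.out_degree(tree.root),
        min_leaf_depth=min(leaf_depths) if leaf_depths else 0,
        avg_leaf_depth=(sum(leaf_depths) / len(leaf_depths)) if leaf_depths else 0.0,
        max_leaf_depth=max(leaf_depths) if leaf_depths else 0,
        trunk_length=trunk if leaves else 0,
        avg_internal_outdegree=(
            sum(g.out_degree(n) for n in internal) / len(internal)
            if internal else 0.0
        ),
    )


def _newick(tree: LineageTree, node: str) -> str:
    children = tree.children(node)
    if node == tree.root:
        if not children:
            return f"{node};"
        inner = ",".join(_newick(tree, c) for c in children)
        return f"({inner}){node};"
    if not children:
        return f"{node}:1"
    inner = ",".join(_newick(tree, c) for c in children)
    return f"({inner}){node}:1"


def write_tree(tree: LineageTree, path: str | Path, fmt: str) -> None:
    """Serialize a tree as an adjacency TSV, a Graphviz DOT digraph
    (observed nodes boxed, inferred oval) or Newick (unit branch lengths)."""
    path = Path(path)
    if fmt == "adjacency_tsv":
        rows = [
            {"parent_id": u, "child_id": v,
             "mutation": _fmt_event(tree.edge_event(u, v))}
            for u, v in sorted(tree.graph.edges())
        ]
        seqio.write_tsv(rows, path, ["parent_id", "child_id", "mutation"])
    elif fmt == "dot":
        lines = [f'digraph "{tree.clone_id}" {{']
        for n in sorted(tree.graph.nodes):
            shape = "box" if tree.graph.nodes[n]["status"] == "observed" else "oval"
            lines.append(f'  "{n}" [shape={shape}];')
        for u, v in sorted(tree.graph.edges()):
            lines.append(
                f'  "{u}" -> "{v}" [label="{_fmt_event(tree.edge_event(u, v))}"];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "newick":
        path.write_text(_newick(tree, tree.root) + "\n")
    else:
        raise ValueError(f"unknown tree format {fmt!r}")


def write_all_trees(trees: Sequence[LineageTree], out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    measures = []
    for tree in trees:
        write_tree(tree, out / f"{tree.clone_id}.adj.tsv", "adjacency_tsv")
        write_tree(tree, out / f"{tree.clone_id}.dot", "dot")
        write_tree(tree, out / f"{tree.clone_id}.nwk", "newick")
        measures.append(vars(measure_tree(tree)))
    seqio.write_tsv(measures, out / "tree_measures.tsv",
                    [f.name for f in dataclasses.fields(TreeMeasures)])
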