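"""Clonal grouping and consensus-germline reconstruction.

Sequences sharing the same V(D)J segment assignment are treated as one
clone — descendants of a single rearrangement event. Because the junction
(N-nucleotides) has no germline template, the clone's ancestral sequence is
reconstructed as: the library V and J segments verbatim over their matched
spans, plus a column-wise majority consensus of the members' junctions.
Members plus the consensus are then aligned together (center-star multiple
alignment), giving the frame used by indel screening and lineage trees, and
a per-clone Metadata summary is emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from igpipe import seqio
from igpipe._align import edit_distance, global_align
from igpipe.germline_assign import (
    AssignParams, AssignmentError, GermlineLibrary, VDJAssignment,
    assign_vdj, reading_frame_start,
)
from igpipe.seqio import Read

#: fixed symbol order for consensus tie-breaks (gap sorts last)
_SYMBOL_ORDER = {c: i for i, c in enumerate("ACGTN-")}


@dataclass(frozen=True)
class CloneKey:
    v_id: str
    d_id: str  # "none" when no D was called
    j_id: str

    def __str__(self) -> str:
        return f"{self.v_id}|{self.d_id}|{self.j_id}"


@dataclass
class Metadata:
    clone_id: str
    key: CloneKey
    n_sequences: int
    n_unique: int
    junction_length: int
    region_map: dict = field(default_factory=dict)
    functionality_counts: dict = field(default_factory=dict)


@dataclass
class Clone:
    clone_id: str
    key: CloneKey
    members: list[VDJAssignment]
    consensus_germline: str = ""
    consensus_region_map: dict = field(default_factory=dict)
    consensus_frame_start: int = 0
    alignment: list[str] = field(default_factory=list)  # consensus row first
    alignment_ids: list[str] = field(default_factory=list)
    metadata: Metadata | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    def member_row(self, read_id: str) -> str:
        return self.alignment[self.alignment_ids.index(read_id)]

    @property
    def germline_row(self) -> str:
        return self.alignment[self.alignment_ids.index("germline")]


def group_clones(assignments: Sequence[VDJAssignment],
                 include_d_in_key: bool = True) -> list[Clone]:
    """Exact partition by shared V(D)J key; clones ordered (and numbered)
    by sorted key for determinism."""
    groups: dict[CloneKey, list[VDJAssignment]] = {}
    for a in assignments:
        d_id = a.d_match.segment_id if (include_d_in_key and a.d_match) else "none"
        key = CloneKey(a.v_match.segment_id, d_id, a.j_match.segment_id)
        groups.setdefault(key, []).append(a)
    clones = []
    for i, key in enumerate(sorted(groups, key=str)):
        clones.append(Clone(f"clone{i:04d}", key, groups[key]))
    return clones


def align_clone(seqs: Sequence[str]) -> list[str]:
    """Center-star multiple alignment.

    The center is the sequence minimizing summed pairwise edit distance
    (ties: longest, then first in input order); every other sequence is
    globally aligned to the center (match +1, mismatch -1, gap -2) and the
    pairwise alignments are merged under "once a gap, always a gap".
    """
    if not seqs:
        raise ValueError("align_clone needs at least one sequence")
    n = len(seqs)
    if n == 1:
        return [seqs[0]]
    dist = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = edit_distance(seqs[i], seqs[j])
            dist[i][j] = dist[j][i] = d
    center = min(range(n), key=lambda i: (sum(dist[i]), -len(seqs[i]), i))

    # master gap structure of the center: insertions before each center pos
    ins_before = [0] * (len(seqs[center]) + 1)
    pairwise = []
    for i in range(n):
        if i == center:
            pairwise.append(None)
            continue
        aln = global_align(seqs[i], seqs[center])
        pairwise.append(aln)
        cpos = 0
        run = 0
        for cc in aln.aligned_b:
            if cc == "-":
                run += 1
            else:
                ins_before[cpos] = max(ins_before[cpos], run)
                run = 0
                cpos += 1
        ins_before[len(seqs[center])] = max(ins_before[len(seqs[center])], run)

    def pad_center() -> str:
        out = []
        for pos, c in enumerate(seqs[center]):
            out.append("-" * ins_before[pos])
            out.append(c)
        out.append("-" * ins_before[len(seqs[center])])
        return "".join(out)

    rows = []
    for i in range(n):
        if i == center:
            rows.append(pad_center())
            continue
        aln = pairwise[i]
        out = []
        cpos = 0
        pending = []  # member chars aligned to gaps before center pos cpos
        for mc, cc in zip(aln.aligned_a, aln.aligned_b):
            if cc == "-":
                pending.append(mc)
            else:
                out.append("".join(pending).rjust(ins_before[cpos], "-"))
                pending = []
                out.append(mc)
                cpos += 1
        out.append("".join(pending).rjust(ins_before[len(seqs[center])], "-"))
        rows.append("".join(out))
    assert len({len(r) for r in rows}) == 1
    return rows


def junction_consensus(junctions: Sequence[str]) -> str:
    """Majority-vote consensus of the member junctions.

    Junctions are center-star aligned; each column takes the majority
    symbol, with the gap a votable symbol (a majority gap drops the column)
    and ties resolved in the fixed order A < C < G < T < gap.
    """
    if not junctions:
        return ""
    if len(set(junctions)) == 1:
        return junctions[0]
    rows = align_clone(list(junctions))
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        winner = min(counts, key=lambda c: (-counts[c], _SYMBOL_ORDER.get(c, 9)))
        if winner != "-":
            out.append(winner)
    return "".join(out)


def build_consensus(clone: Clone, library: GermlineLibrary) -> str:
    """Consensus germline: library V and J over the widest matched spans,
    with the majority junction in between."""
    v_seg = library.get(clone.key.v_id)
    j_seg = library.get(clone.key.j_id)
    v_start = min(m.v_match.seg_start for m in clone.members)
    v_end = max(m.v_match.seg_end for m in clone.members)
    j_start = min(m.j_match.seg_start for m in clone.members)
    j_end = max(m.j_match.seg_end for m in clone.members)
    junction = junction_consensus([m.junction for m in clone.members])
    return v_seg.bases[v_start:v_end] + junction + j_seg.bases[j_start:j_end]


def finalize_clone(clone: Clone, library: GermlineLibrary,
                   params: AssignParams | None = None) -> Clone:
    """Compute the consensus, re-align members plus consensus (consensus
    row first), re-derive region boundaries on the consensus, and fill in
    Metadata."""
    clone.consensus_germline = build_consensus(clone, library)
    seqs = [clone.consensus_germline] + [m.bases for m in clone.members]
    rows = align_clone(seqs)
    clone.alignment = rows
    clone.alignment_ids = ["germline"] + [m.read_id for m in clone.members]

    # region boundaries on the consensus, by re-running segment assignment
    try:
        cons_assign = assign_vdj(
            Read("germline", clone.consensus_germline), library, params,
        )
        clone.consensus_region_map = cons_assign.region_map
        clone.consensus_frame_start = reading_frame_start(cons_assign, library)
    except AssignmentError:
        clone.consensus_region_map = {}
        clone.consensus_frame_start = 0

    func_counts: dict[str, int] = {}
    for m in clone.members:
        func_counts[m.functionality] = func_counts.get(m.functionality, 0) + 1
    junction = junction_consensus([m.junction for m in clone.members])
    clone.metadata = Metadata(
        clone_id=clone.clone_id,
        key=clone.key,
        n_sequences=len(clone.members),
        n_unique=len(clone.members),
        junction_length=len(junction),
        region_map=clone.consensus_region_map,
        functionality_counts=func_counts,
    )
    return clone


def build_clones(assignments: Sequence[VDJAssignment],
                 library: GermlineLibrary,
                 params: AssignParams | None = None,
                 include_d_in_key: bool = True) -> list[Clone]:
    """Group, then finalize every clone."""
    clones = group_clones(assignments, include_d_in_key)
    for clone in clones:
        finalize_clone(clone, library, params)
    return clones


def write_clone_outputs(clones: Sequence[Clone], out_dir: str | Path) -> None:
    """Per-clone directory with members FASTA, PIR alignment (consensus
    first) and metadata TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for clone in clones:
        cdir = out / clone.clone_id
        cdir.mkdir(exist_ok=True)
        seqio.write_fasta(
            ((m.read_id, m.bases) for m in clone.members),
            cdir / "members.fasta",
        )
        with open(cdir / "alignment.pir", "w") as fh:
            for rid, row in zip(clone.alignment_ids, clone.alignment):
                fh.write(f">DL;{rid}\n{rid}\n")
                for i in range(0, len(row), 60):
                    fh.write(row[i : i + 60] + "\n")
                fh.write("*\n")
        md = clone.metadata
        rows = [
            {"field": "clone_id", "value": md.clone_id},
            {"field": "v_id", "value": md.key.v_id},
            {"field": "d_id", "value": md.key.d_id},
            {"field": "j_id", "value": md.key.j_id},
            {"field": "n_sequences", "value": md.n_sequences},
            {"field": "n_unique", "value": md.n_unique},
            {"field": "junction_length", "value": md.junction_length},
        ]
        for name, (s, e) in sorted(md.region_map.items(), key=lambda kv: kv[1]):
            rows.append({"field": f"region_{name}", "value": f"{s}-{e}"})
        for func, cnt in sorted(md.functionality_counts.items()):
            rows.append({"field": f"n_{func}", "value": cnt})
        seqio.write_tsv(rows, cdir / "metadata.tsv", ["field", "value"])
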