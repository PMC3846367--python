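"""Homopolymer indel-artifact screening.

Pyrosequencing (454-style) misreads the length of homopolymer tracts, so
short insertions or deletions adjacent to runs of identical bases are far
more likely sequencing artifacts than genuine somatic-hypermutation indels
— and with no whole-gene template, the only reference to call them against
is the clone's own consensus germline. Each member is compared with the
consensus on the clone alignment; an indel is flagged artifactual when it
is short, sits in or next to a homopolymer run, and repeats the run base.
Sequences are partitioned into indel-free / artifact-indel / putative
genuine-indel sets; by default only indel-free sequences continue to tree
building. Bases are never edited, only set aside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from igpipe import seqio
from igpipe.clone_builder import Clone


@dataclass(frozen=True)
class HomopolymerRun:
    base: str
    start: int  # on the ungapped germline, 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IndelCall:
    read_id: str
    kind: str  # insertion or deletion
    position: int  # ungapped germline coordinate
    length: int
    bases: str
    artifact: bool = False
    nearest_run: HomopolymerRun | None = None


@dataclass
class IndelParams:
    min_run: int = 3
    flank: int = 1
    max_artifact_len: int = 2

    def __post_init__(self) -> None:
        if self.min_run < 2:
            raise ValueError("min_run must be >= 2")


def find_homopolymers(seq: str, min_run: int = 3) -> list[HomopolymerRun]:
    """All maximal runs of a single base with length >= ``min_run``,
    left to right."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run and seq[i] in "ACGT":
            runs.append(HomopolymerRun(seq[i], i, j))
        i = j
    return runs


def call_indels(member_row: str, germline_row: str,
                read_id: str = "") -> list[IndelCall]:
    """Read indels off a pair of gapped alignment rows.

    A maximal gap block in the germline row is an insertion (bases present
    in the member only); in the member row, a deletion. Positions are on
    ungapped germline coordinates (for insertions, the germline position
    following the block).
    """
    if len(member_row) != len(germline_row):
        raise ValueError("alignment rows differ in length")
    calls: list[IndelCall] = []
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
            calls.append(IndelCall(read_id, "insertion", gpos, len(ins),
                                   "".join(ins)))
            i = j
        elif mc == "-" and gc != "-":
            j = i
            dele = []
            start = gpos
            while j < n and member_row[j] == "-" and germline_row[j] != "-":
                dele.append(germline_row[j])
                gpos += 1
                j += 1
            calls.append(IndelCall(read_id, "deletion", start, len(dele),
                                   "".join(dele)))
            i = j
        else:
            gpos += gc != "-"
            i += 1
    return calls


def classify_artifact(indel: IndelCall, runs: Sequence[HomopolymerRun],
                      params: IndelParams | None = None) -> bool:
    """Artifact test: short indel, in or next to a homopolymer run, made of
    the run base. Sets ``indel.artifact`` and ``indel.nearest_run``.

    An insertion falling strictly inside a run is accepted regardless of
    the reported inserted base: when a point substitution sits in the same
    run, the pairwise alignment merges the two events and blames the
    substituted base for the gap, so the base-identity requirement is only
    enforced for indels at a run's flanks. Deletions inside a run remove
    run bases by construction, so the same check is equivalent for them.
    """
    params = params or IndelParams()
    if indel.length > params.max_artifact_len:
        indel.artifact = False
        return False
    span_end = indel.position + (indel.length if indel.kind == "deletion" else 0)
    for run in runs:
        if indel.position > run.end + params.flank:
            continue
        if span_end < run.start - params.flank:
            continue
        inside = run.start <= indel.position and span_end <= run.end
        if inside or all(c == run.base for c in indel.bases):
            indel.artifact = True
            indel.nearest_run = run
            return True
    indel.artifact = False
    return False


def screen_clone(clone: Clone,
                 params: IndelParams | None = None) -> dict[str, list[IndelCall]]:
    """Indel calls per member, classified against the clone consensus."""
    params = params or IndelParams()
    runs = find_homopolymers(clone.consensus_germline, params.min_run)
    germline_row = clone.germline_row
    out: dict[str, list[IndelCall]] = {}
    for member in clone.members:
        calls = call_indels(clone.member_row(member.read_id), germline_row,
                            member.read_id)
        for c in calls:
            classify_artifact(c, runs, params)
        out[member.read_id] = calls
    return out


@dataclass
class IndelPartition:
    indel_free: list[str]
    artifact_indel: list[str]
    genuine_indel: list[str]
    calls: list[IndelCall]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "indel_free": len(self.indel_free),
            "artifact_indel": len(self.artifact_indel),
            "genuine_indel": len(self.genuine_indel),
        }


def partition_by_indels(clones: Sequence[Clone],
                        params: IndelParams | None = None) -> IndelPartition:
    """Three-way, total and exclusive partition of all clone members:
    no indels at all / at least one artifact-classified indel / indels
    present but none artifactual."""
    free: list[str] = []
    artifact: list[str] = []
    genuine: list[str] = []
    all_calls: list[IndelCall] = []
    for clone in clones:
        per_member = screen_clone(clone, params)
        for read_id, calls in per_member.items():
            all_calls.extend(calls)
            if not calls:
                free.append(read_id)
            elif any(c.artifact for c in calls):
                artifact.append(read_id)
            else:
                genuine.append(read_id)
    return IndelPartition(free, artifact, genuine, all_calls)


def write_indel_outputs(partition: IndelPartition, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "read_id": c.read_id,
            "kind": c.kind,
            "position": c.position,
            "length": c.length,
            "bases": c.bases,
            "artifact": int(c.artifact),
            "run_base": c.nearest_run.base if c.nearest_run else "",
            "run_length": c.nearest_run.length if c.nearest_run else 0,
        }
        for c in partition.calls
    ]
    seqio.write_tsv(rows, out / "indels.tsv", [
        "read_id", "kind", "position", "length", "bases", "artifact",
        "run_base", "run_length",
    ])
    for name in ("indel_free", "artifact_indel", "genuine_indel"):
        with open(out / f"{name}.ids.txt", "w") as fh:
            for rid in getattr(partition, name):
                fh.write(rid + "\n")
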