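"""Duplicate collapsing: keep one representative per exact sequence.

PCR amplification copies molecules unevenly, so identical reads cannot be
trusted to reflect cell numbers; per sample, each distinct sequence is kept
once and its duplicates are listed against the representative. Identity is
exact string identity of the bases — a single substitution, insertion or
deletion makes a sequence unique. Quality strings are ignored for identity;
the representative keeps its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from igpipe import seqio
from igpipe.seqio import Read


@dataclass
class UniqueSet:
    """Unique sequences plus the representative -> duplicates map."""

    uniques: list[tuple[str, str]] = field(default_factory=list)
    duplicate_map: dict[str, list[str]] = field(default_factory=dict)
    reads: list[Read] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.uniques) + sum(len(v) for v in self.duplicate_map.values())

    def n_copies(self, representative_id: str) -> int:
        """1 + number of duplicates of the representative."""
        return 1 + len(self.duplicate_map.get(representative_id, []))


def collapse_duplicates(reads: Sequence[Read]) -> UniqueSet:
    """Collapse exact duplicates; the first occurrence (input order) is the
    representative, duplicates are listed in input order."""
    seen: dict[str, str] = {}  # bases -> representative read_id
    out = UniqueSet()
    for read in reads:
        rep = seen.get(read.bases)
        if rep is None:
            seen[read.bases] = read.read_id
            out.uniques.append((read.read_id, read.bases))
            out.reads.append(read)
        else:
            out.duplicate_map.setdefault(rep, []).append(read.read_id)
    return out


def write_unique_outputs(uset: UniqueSet, fasta_path: str | Path,
                         dups_path: str | Path) -> None:
    seqio.write_fasta(uset.uniques, fasta_path)
    rows = [
        {"representative_id": rep, "duplicate_id": dup}
        for rep, _ in uset.uniques
        for dup in uset.duplicate_map.get(rep, [])
    ]
    seqio.write_tsv(rows, dups_path, ["representative_id", "duplicate_id"])


def read_duplicate_map(path: str | Path) -> dict[str, list[str]]:
    dmap: dict[str, list[str]] = {}
    for row in seqio.read_tsv(path):
        dmap.setdefault(row["representative_id"], []).append(row["duplicate_id"])
    return dmap
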