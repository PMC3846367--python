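"""Tree-based somatic hypermutation statistics.

Counting mutations on lineage-tree edges — rather than per sequence —
counts a mutation shared by many descendants exactly once. Per edge the
substitution is classified replacement (amino-acid changing) or silent by
translating the parent and mutated codons in the clone's reading frame,
tallied per region (FR1..FR4, CDR1..CDR3); replacement events accumulate
into a 20x20 amino-acid substitution matrix, and each substitution is
tested against the canonical AID/polymerase-eta hotspot motifs (WRC/GYW
and WA/TW) in its parent-sequence context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from igpipe import seqio
from igpipe.clone_builder import Clone
from igpipe.lineage import Event, LineageTree, apply_events
from igpipe.seqio import translate

REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

_IUPAC = {"W": "AT", "R": "AG", "Y": "CT", "A": "A", "T": "T", "C": "C", "G": "G"}


@dataclass
class MutationRecord:
    clone_id: str
    parent_id: str
    child_id: str
    event: Event
    region: str  # region name or "" when unmapped
    rs_class: str  # replacement / silent / not_applicable
    parent_aa: str = ""
    child_aa: str = ""
    in_hotspot: bool = False
    motif: str = ""


def _region_of(pos: int, region_map: dict) -> str:
    for name, (s, e) in region_map.items():
        if s <= pos < e:
            return name
    return ""


def classify_rs(event: Event, parent_seq: str, frame_start: int,
                ) -> tuple[str, str, str]:
    """Classify one substitution as replacement or silent.

    Translates the codon containing the mutated position in the parent and
    in the mutated sequence; positions before the reading-frame start, in
    an incomplete trailing codon, or in a codon containing N are
    ``not_applicable``.
    """
    _, pos, from_base, to_base = event
    if pos < frame_start or parent_seq[pos] != from_base:
        return "not_applicable", "", ""
    codon_idx = (pos - frame_start) // 3
    cs = frame_start + 3 * codon_idx
    codon = parent_seq[cs : cs + 3]
    if len(codon) < 3 or "N" in codon or "-" in codon:
        return "not_applicable", "", ""
    mutated = codon[: pos - cs] + to_base + codon[pos - cs + 1 :]
    aa_p = translate(codon)
    aa_c = translate(mutated)
    if aa_p in ("X", "*") or aa_c in ("X", "*"):
        # nonsense codons have no row/column in the 20x20 matrix; keeping
        # them out of R/S preserves exact R == matrix-total conservation
        return "not_applicable", "", ""
    return ("silent" if aa_p == aa_c else "replacement"), aa_p, aa_c


def _matches(pattern: str, context: str) -> bool:
    return len(pattern) == len(context) and all(
        c in _IUPAC.get(p, "") for p, c in zip(pattern, context)
    )


def in_hotspot(parent_seq: str, pos: int) -> tuple[bool, str]:
    """Test the mutated position against SHM targeting motifs.

    WRC (mutated C) / GYW (mutated G) are the AID hotspots; WA (mutated A)
    / TW (mutated T) the polymerase-eta hotspots. W={A,T}, R={A,G},
    Y={C,T}. The mutated position is the underlined base of the motif.
    """
    base = parent_seq[pos]
    n = len(parent_seq)
    if base == "C" and pos >= 2 and _matches("WR", parent_seq[pos - 2 : pos]):
        return True, "WRC"
    if base == "G" and pos + 2 < n and _matches("YW", parent_seq[pos + 1 : pos + 3]):
        return True, "GYW"
    if base == "A" and pos >= 1 and _matches("W", parent_seq[pos - 1]):
        return True, "WA"
    if base == "T" and pos + 1 < n and _matches("W", parent_seq[pos + 1]):
        return True, "TW"
    return False, ""


def mutation_records(tree: LineageTree, clone: Clone,
                     frame_start: int) -> list[MutationRecord]:
    """One record per tree edge. Indel edges are recorded with
    ``rs_class="not_applicable"`` and excluded from R/S and hotspot
    accounting downstream."""
    germline = clone.consensus_germline
    records = []
    for parent, child in sorted(tree.graph.edges()):
        ev = tree.edge_event(parent, child)
        parent_seq = apply_events(germline, tree.node_events(parent))
        rec = MutationRecord(
            clone_id=clone.clone_id, parent_id=parent, child_id=child,
            event=ev, region=_region_of(ev[1], clone.consensus_region_map),
            rs_class="not_applicable",
        )
        if ev[0] == "sub":
            # positions are germline coordinates; classification needs the
            # parent context, valid while no upstream indel shifted it
            shifted = any(
                e[0] != "sub" and e[1] <= ev[1]
                for e in tree.node_events(parent)
            )
            if not shifted:
                rec.rs_class, rec.parent_aa, rec.child_aa = classify_rs(
                    ev, parent_seq, frame_start)
                rec.in_hotspot, rec.motif = in_hotspot(parent_seq, ev[1])
        records.append(rec)
    return records


@dataclass
class RSTable:
    """Replacement/silent counts per clone and region; the ratio is NA when
    no silent mutations were seen."""

    rows: list[dict] = field(default_factory=list)

    @property
    def total_r(self) -> int:
        return sum(r["R"] for r in self.rows)

    @property
    def total_s(self) -> int:
        return sum(r["S"] for r in self.rows)


def count_rs(records: Sequence[MutationRecord]) -> RSTable:
    """Tally R and S per (clone, region); every edge contributes once."""
    counts: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        if rec.rs_class not in ("replacement", "silent"):
            continue
        key = (rec.clone_id, rec.region or "unmapped")
        rs = counts.setdefault(key, [0, 0])
        rs[0 if rec.rs_class == "replacement" else 1] += 1
    table = RSTable()
    for (clone_id, region), (r, s) in sorted(counts.items()):
        table.rows.append({
            "clone": clone_id, "region": region, "R": r, "S": s,
            "ratio": (f"{r / s:.4f}" if s else "NA"),
        })
    return table


def hotspot_fraction(records: Sequence[MutationRecord]) -> dict:
    """Fraction of classified substitutions falling in a hotspot motif;
    NA when there are no substitutions."""
    subs = [r for r in records
            if r.event[0] == "sub" and r.rs_class != "not_applicable"]
    per_motif: dict[str, int] = {"WRC": 0, "GYW": 0, "WA": 0, "TW": 0}
    n_hot = 0
    for r in subs:
        if r.in_hotspot:
            n_hot += 1
            per_motif[r.motif] += 1
    return {
        "n_substitutions": len(subs),
        "n_in_hotspot": n_hot,
        "fraction": (n_hot / len(subs)) if subs else None,
        "per_motif": per_motif,
    }


def aa_substitution_counts(records: Sequence[MutationRecord]) -> dict:
    """20x20 replacement matrix: rows parent amino acid, columns child."""
    matrix = {p: {c: 0 for c in AA_ORDER} for p in AA_ORDER}
    for rec in records:
        if rec.rs_class == "replacement" and rec.parent_aa in matrix \
                and rec.child_aa in matrix[rec.parent_aa]:
            matrix[rec.parent_aa][rec.child_aa] += 1
    return matrix


def matrix_total(matrix: dict) -> int:
    return sum(sum(row.values()) for row in matrix.values())


def write_mutation_outputs(all_records: Sequence[MutationRecord],
                           out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = count_rs(all_records)
    seqio.write_tsv(table.rows, out / "rs_table.tsv",
                    ["clone", "region", "R", "S", "ratio"])
    matrix = aa_substitution_counts(all_records)
    rows = [dict({"parent_aa": p}, **{c: matrix[p][c] for c in AA_ORDER})
            for p in AA_ORDER]
    seqio.write_tsv(rows, out / "aa_matrix.tsv", ["parent_aa", *AA_ORDER])
    hs = hotspot_fraction(all_records)
    hs_rows = [
        {"measure": "n_substitutions", "value": hs["n_substitutions"]},
        {"measure": "n_in_hotspot", "value": hs["n_in_hotspot"]},
        {"measure": "fraction",
         "value": "NA" if hs["fraction"] is None else f"{hs['fraction']:.4f}"},
    ]
    for motif, cnt in hs["per_motif"].items():
        hs_rows.append({"measure": f"n_{motif}", "value": cnt})
    seqio.write_tsv(hs_rows, out / "hotspots.tsv", ["measure", "value"])
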