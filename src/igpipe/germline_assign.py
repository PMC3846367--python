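"""Template-free V(D)J identification by highest homology.

No whole-gene reference exists for a rearranged immunoglobulin gene, so each
read is annotated segment by segment: the germline V and J segments are
found by best local alignment against a segment library, the junction (the
non-templated N-nucleotides between them) is whatever the read carries in
between, and a D segment is only reported when a near-exact short match
lies inside the junction. From the matched segments a per-read germline
reconstruction and a framework/CDR region map are derived, and the read is
classified as functional, non-functional (frame shift or premature stop) or
indeterminate (J evidence too short to fix the reading frame).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from igpipe import seqio
from igpipe._align import local_align
from igpipe.seqio import Read, translate

V_REGIONS = ("fr1", "cdr1", "fr2", "cdr2", "fr3")


class AssignmentError(ValueError):
    """Raised when no V or J segment scores above threshold for a read."""


@dataclass(frozen=True)
class GermlineSegment:
    segment_id: str
    kind: str  # V, D or J
    bases: str
    frame_offset: int = 0  # V only: codon phase at segment position 0
    regions: dict | None = None  # V: name -> (start, end); 0-based half-open
    fr4_start: int | None = None  # J only

    def header(self) -> str:
        parts = [self.segment_id, f"kind={self.kind}"]
        if self.kind == "V":
            parts.append(f"frame={self.frame_offset}")
            for name in V_REGIONS:
                if self.regions and name in self.regions:
                    s, e = self.regions[name]
                    parts.append(f"{name}={s}..{e}")
        elif self.kind == "J" and self.fr4_start is not None:
            parts.append(f"fr4={self.fr4_start}")
        return "|".join(parts)


@dataclass
class GermlineLibrary:
    segments: list[GermlineSegment]

    def __post_init__(self) -> None:
        ids = [s.segment_id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment_id in germline library")
        if not self.by_kind("V") or not self.by_kind("J"):
            raise ValueError("library needs at least one V and one J segment")

    def by_kind(self, kind: str) -> list[GermlineSegment]:
        return [s for s in self.segments if s.kind == kind]

    def get(self, segment_id: str) -> GermlineSegment:
        for s in self.segments:
            if s.segment_id == segment_id:
                return s
        raise KeyError(segment_id)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GermlineLibrary":
        segs = []
        for header, seq in seqio.read_fasta(path):
            segs.append(_parse_header(header, seq))
        return cls(segs)

    def to_fasta(self, path: str | Path) -> None:
        seqio.write_fasta(((s.header(), s.bases) for s in self.segments), path)


def _parse_header(header: str, seq: str) -> GermlineSegment:
    fields = header.split("|")
    seg_id = fields[0].strip()
    kv = {}
    for f in fields[1:]:
        if "=" in f:
            k, v = f.split("=", 1)
            kv[k.strip()] = v.strip()
    kind = kv.get("kind", "")
    if kind not in ("V", "D", "J"):
        raise ValueError(f"segment {seg_id!r}: missing or bad kind annotation")
    regions = None
    fr4 = None
    frame = int(kv.get("frame", 0))
    if kind == "V":
        regions = {}
        for name in V_REGIONS:
            if name in kv:
                m = re.fullmatch(r"(\d+)\.\.(\d+)", kv[name])
                if not m:
                    raise ValueError(f"segment {seg_id!r}: bad interval {kv[name]!r}")
                regions[name] = (int(m.group(1)), int(m.group(2)))
    elif kind == "J" and "fr4" in kv:
        fr4 = int(kv["fr4"])
    return GermlineSegment(seg_id, kind, seq, frame, regions, fr4)


@dataclass
class SegmentMatch:
    segment_id: str
    score: int
    read_start: int
    read_end: int
    seg_start: int
    seg_end: int
    n_mismatches: int
    n_indels: int
    aligned_read: str = ""
    aligned_seg: str = ""

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start


@dataclass
class AssignParams:
    min_segment_score: int = 40
    min_d_length: int = 5
    min_j_overlap: int = 10


@dataclass
class VDJAssignment:
    read_id: str
    bases: str
    v_match: SegmentMatch
    j_match: SegmentMatch
    d_match: SegmentMatch | None
    junction: str
    germline_sequence: str
    region_map: dict = field(default_factory=dict)  # name -> (start, end) on read
    functionality: str = "indeterminate"

    @property
    def junction_interval(self) -> tuple[int, int]:
        return self.v_match.read_end, self.j_match.read_start


def align_segment(read: str, segment: GermlineSegment) -> SegmentMatch:
    """Best local alignment of a germline segment within a read
    (match +2, mismatch -3, gap open -5, gap extend -2)."""
    aln = local_align(read, segment.bases)
    return SegmentMatch(
        segment.segment_id, aln.score, aln.a_start, aln.a_end,
        aln.b_start, aln.b_end, aln.n_mismatches, aln.n_indels,
        aln.aligned_a, aln.aligned_b,
    )


def _extend_left(m: SegmentMatch, read: str, seg: str) -> None:
    """Ungapped extension of a match to the outer 5' boundary: a local
    alignment clips terminal mismatches, but bases of the read lying before
    the matched span still belong to the segment and must stay covered, or
    they would later surface as phantom insertions against the consensus."""
    d = min(m.read_start, m.seg_start)
    if d == 0:
        return
    r0, s0 = m.read_start - d, m.seg_start - d
    ext_read = read[r0 : m.read_start]
    ext_seg = seg[s0 : m.seg_start]
    mm = sum(1 for a, b in zip(ext_read, ext_seg) if a != b)
    m.read_start, m.seg_start = r0, s0
    m.n_mismatches += mm
    m.score += 2 * (d - mm) - 3 * mm
    m.aligned_read = ext_read + m.aligned_read
    m.aligned_seg = ext_seg + m.aligned_seg


def _extend_right(m: SegmentMatch, read: str, seg: str,
                  read_limit: int) -> None:
    """Mirror-image ungapped extension to the outer 3' boundary."""
    d = min(read_limit - m.read_end, len(seg) - m.seg_end)
    if d <= 0:
        return
    ext_read = read[m.read_end : m.read_end + d]
    ext_seg = seg[m.seg_end : m.seg_end + d]
    mm = sum(1 for a, b in zip(ext_read, ext_seg) if a != b)
    m.read_end += d
    m.seg_end += d
    m.n_mismatches += mm
    m.score += 2 * (d - mm) - 3 * mm
    m.aligned_read = m.aligned_read + ext_read
    m.aligned_seg = m.aligned_seg + ext_seg


def _best_match(read: str, segments: Sequence[GermlineSegment],
                offset: int = 0) -> SegmentMatch | None:
    """Highest-scoring segment; ties broken by longer matched read span,
    then lexicographic segment_id. ``offset`` shifts read coordinates."""
    best: SegmentMatch | None = None
    for seg in sorted(segments, key=lambda s: s.segment_id):
        m = align_segment(read, seg)
        if best is None or (m.score, m.read_span) > (best.score, best.read_span):
            best = m
    if best is None or best.score <= 0:
        return None
    best.read_start += offset
    best.read_end += offset
    return best


def _find_d(junction: str, d_segments: Sequence[GermlineSegment],
            min_d_length: int, junction_offset: int) -> SegmentMatch | None:
    """Conservative D call: the longest ungapped exact-or-1-mismatch match
    of a D segment inside the junction, at least ``min_d_length`` long."""
    best: tuple[int, int, str, int, SegmentMatch] | None = None
    for seg in sorted(d_segments, key=lambda s: s.segment_id):
        d = seg.bases
        max_l = min(len(d), len(junction))
        for length in range(max_l, min_d_length - 1, -1):
            for ds in range(len(d) - length + 1):
                chunk = d[ds : ds + length]
                for js in range(len(junction) - length + 1):
                    mm = sum(1 for a, b in zip(chunk, junction[js : js + length])
                             if a != b)
                    if mm > 1:
                        continue
                    key = (-length, mm, seg.segment_id, js)
                    if best is None or key < best[:4]:
                        best = key + (SegmentMatch(
                            seg.segment_id, 2 * (length - mm) - 3 * mm,
                            junction_offset + js, junction_offset + js + length,
                            ds, ds + length, mm, 0),)
    return best[4] if best else None


def _seg_to_read_map(m: SegmentMatch) -> dict[int, int]:
    """Map each segment coordinate in the matched span to its read
    coordinate (deleted segment bases map to the following read position)."""
    out: dict[int, int] = {}
    r, s = m.read_start, m.seg_start
    for ca, cb in zip(m.aligned_read, m.aligned_seg):
        if cb != "-":
            out[s] = r
            s += 1
            r += ca != "-"
        else:
            r += 1
    out[m.seg_end] = m.read_end
    return out


def _map_coord(cmap: dict[int, int], pos: int, lo: int, hi: int,
               read_lo: int, read_hi: int) -> int:
    pos = max(lo, min(hi, pos))
    return max(read_lo, min(read_hi, cmap.get(pos, read_hi if pos >= hi else read_lo)))


def build_region_map(v: GermlineSegment, v_match: SegmentMatch,
                     j: GermlineSegment, j_match: SegmentMatch) -> dict:
    """Project library region annotations through the alignments onto read
    coordinates. CDR3 runs from the end of V FR3 to the start of J FR4."""
    rmap: dict[str, tuple[int, int]] = {}
    vmap = _seg_to_read_map(v_match)
    if v.regions:
        for name in V_REGIONS:
            if name not in v.regions:
                continue
            s, e = v.regions[name]
            rs = _map_coord(vmap, s, v_match.seg_start, v_match.seg_end,
                            v_match.read_start, v_match.read_end)
            re_ = _map_coord(vmap, e, v_match.seg_start, v_match.seg_end,
                             v_match.read_start, v_match.read_end)
            if re_ > rs:
                rmap[name.upper()] = (rs, re_)
    jmap = _seg_to_read_map(j_match)
    if j.fr4_start is not None:
        fr4_read = _map_coord(jmap, j.fr4_start, j_match.seg_start,
                              j_match.seg_end, j_match.read_start,
                              j_match.read_end)
    else:
        fr4_read = j_match.read_start
    cdr3_start = rmap["FR3"][1] if "FR3" in rmap else v_match.read_end
    if fr4_read > cdr3_start:
        rmap["CDR3"] = (cdr3_start, fr4_read)
    if j_match.read_end > fr4_read:
        rmap["FR4"] = (fr4_read, j_match.read_end)
    return rmap


def assign_vdj(read: Read, library: GermlineLibrary,
               params: AssignParams | None = None) -> VDJAssignment:
    """Assign germline V, J and (optionally) D segments to one read.

    V is the best local alignment over all V segments; J is the best over
    the read suffix after the V match; D is searched inside the junction
    only. Raises :class:`AssignmentError` when V or J falls below
    ``min_segment_score``.
    """
    params = params or AssignParams()
    seq = read.bases
    v_best = _best_match(seq, library.by_kind("V"))
    if v_best is None or v_best.score < params.min_segment_score:
        raise AssignmentError(f"read {read.read_id!r}: no V segment above threshold")
    _extend_left(v_best, seq, library.get(v_best.segment_id).bases)
    suffix = seq[v_best.read_end :]
    j_best = _best_match(suffix, library.by_kind("J"), offset=v_best.read_end)
    if j_best is None or j_best.score < params.min_segment_score:
        raise AssignmentError(f"read {read.read_id!r}: no J segment above threshold")
    _extend_right(j_best, seq, library.get(j_best.segment_id).bases, len(seq))

    junction = seq[v_best.read_end : j_best.read_start]
    d_best = _find_d(junction, library.by_kind("D"), params.min_d_length,
                     v_best.read_end)

    v_seg = library.get(v_best.segment_id)
    j_seg = library.get(j_best.segment_id)
    germline = (
        v_seg.bases[v_best.seg_start : v_best.seg_end]
        + junction
        + j_seg.bases[j_best.seg_start : j_best.seg_end]
    )
    assignment = VDJAssignment(
        read_id=read.read_id,
        bases=seq,
        v_match=v_best,
        j_match=j_best,
        d_match=d_best,
        junction=junction,
        germline_sequence=germline,
        region_map=build_region_map(v_seg, v_best, j_seg, j_best),
    )
    assignment.functionality = classify_functionality(assignment, library, params)
    return assignment


def reading_frame_start(assignment: VDJAssignment,
                        library: GermlineLibrary) -> int:
    """First read position at codon phase 0, derived from the V segment's
    annotated frame and the matched V interval."""
    v_seg = library.get(assignment.v_match.segment_id)
    phase0 = (v_seg.frame_offset + assignment.v_match.seg_start) % 3
    return assignment.v_match.read_start + ((-phase0) % 3)


def classify_functionality(assignment: VDJAssignment,
                           library: GermlineLibrary,
                           params: AssignParams | None = None) -> str:
    """Call a rearrangement functional, non-functional or indeterminate.

    Indeterminate: the matched J span is shorter than ``min_j_overlap`` so
    the reading frame at the 3' end cannot be anchored. Non-functional: the
    junction shifts the J segment's FR4 out of the V-established frame, or
    the V-frame translation contains a stop codon before the end of FR4.
    """
    params = params or AssignParams()
    j_span = assignment.j_match.read_span
    if j_span < params.min_j_overlap:
        return "indeterminate"
    j_seg = library.get(assignment.j_match.segment_id)
    t0 = reading_frame_start(assignment, library)
    fr4 = j_seg.fr4_start if j_seg.fr4_start is not None else 0
    fr4_read = assignment.j_match.read_start + (fr4 - assignment.j_match.seg_start)
    if (fr4_read - t0) % 3 != 0:
        return "non_functional"
    aa = translate(assignment.bases[t0 : assignment.j_match.read_end])
    if "*" in aa:
        return "non_functional"
    return "functional"


def split_by_functionality(assignments: Iterable[VDJAssignment],
                           ) -> dict[str, list[VDJAssignment]]:
    """Total, exclusive three-way partition by functionality call."""
    out: dict[str, list[VDJAssignment]] = {
        "functional": [], "indeterminate": [], "non_functional": [],
    }
    for a in assignments:
        out[a.functionality].append(a)
    return out


def assign_all(reads: Iterable[Read], library: GermlineLibrary,
               params: AssignParams | None = None,
               ) -> tuple[list[VDJAssignment], list[str]]:
    """Assign every read; unassignable reads are set aside and their ids
    returned for reporting (they are excluded from clones but counted)."""
    assigned: list[VDJAssignment] = []
    failed: list[str] = []
    for read in reads:
        try:
            assigned.append(assign_vdj(read, library, params))
        except AssignmentError:
            failed.append(read.read_id)
    return assigned, failed


def _fmt_regions(region_map: dict) -> str:
    return ",".join(f"{k}:{s}-{e}" for k, (s, e) in sorted(
        region_map.items(), key=lambda kv: kv[1]))


def write_assignments(assignments: Iterable[VDJAssignment],
                      path: str | Path) -> int:
    rows = [
        {
            "read_id": a.read_id,
            "v_id": a.v_match.segment_id,
            "d_id": a.d_match.segment_id if a.d_match else "none",
            "j_id": a.j_match.segment_id,
            "junction": a.junction,
            "v_mismatches": a.v_match.n_mismatches,
            "j_mismatches": a.j_match.n_mismatches,
            "functionality": a.functionality,
            "regions": _fmt_regions(a.region_map),
        }
        for a in assignments
    ]
    return seqio.write_tsv(rows, path, [
        "read_id", "v_id", "d_id", "j_id", "junction", "v_mismatches",
        "j_mismatches", "functionality", "regions",
    ])
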