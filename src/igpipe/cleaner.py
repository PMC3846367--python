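"""Amplicon cleaning: dual-MID demultiplexing, chimera discard, primer
location and trimming by bounded-mismatch dynamic programming, and length
and mean-quality filters — with every discarded read accounted for.

Samples are coded by a *pair* of MID (multiplex identifier) tags, one at
each read end. A read whose MID pair is identifiable but not listed in the
sample sheet is most likely a PCR chimera joining molecules from two
samples, and is discarded as such. Primers are located so they can be
trimmed: mismatches inside primer annealing sites are PCR artifacts, not
somatic mutations, and must not survive into mutation analysis.

The filter cascade is fixed: MID pair -> chimera check -> primers ->
length -> quality. A read lands in exactly one output category, so the
report partitions the input exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from igpipe import seqio
from igpipe._align import _edit_row_final
from igpipe.seqio import AS_READ, REVERSE_COMPLEMENTED, Read, revcomp

#: discard categories, in cascade order
CATEGORIES = (
    "mid_unidentified",
    "chimera_discarded",
    "primer_unidentified",
    "length_discarded",
    "quality_discarded",
)


@dataclass(frozen=True)
class MIDTag:
    name: str
    bases: str


@dataclass
class SampleSheet:
    """Maps (forward MID, reverse MID) name pairs to sample ids."""

    entries: list[tuple[str, str, str]]  # (sample_id, fwd_mid, rev_mid)

    def __post_init__(self) -> None:
        pairs = [(f, r) for _, f, r in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate MID pair in sample sheet")

    def sample_for(self, fwd: str, rev: str) -> str | None:
        for sample_id, f, r in self.entries:
            if (f, r) == (fwd, rev):
                return sample_id
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        rows = seqio.read_tsv(path)
        return cls([(r["sample_id"], r["mid_fwd"], r["mid_rev"]) for r in rows])


@dataclass
class PrimerSet:
    forward_primers: list[tuple[str, str]]
    reverse_primers: list[tuple[str, str]]
    max_mismatches: int = 0

    @classmethod
    def from_tsv(cls, path: str | Path, max_mismatches: int = 0) -> "PrimerSet":
        fwd, rev = [], []
        for r in seqio.read_tsv(path):
            (fwd if r["end"] == "fwd" else rev).append((r["name"], r["sequence"]))
        return cls(fwd, rev, max_mismatches)


@dataclass
class CleanParams:
    min_length: int = 250
    max_length: int = 600
    min_mean_quality: float = 25.0
    mid_max_mismatches: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("need 0 < min_length <= max_length")
        if self.min_mean_quality < 0:
            raise ValueError("min_mean_quality must be >= 0")


@dataclass
class CleanReport:
    """Per-sample and total read counts; the categories partition the input."""

    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = ("input_reads", "retained") + CATEGORIES
        for k in keys:
            self.totals.setdefault(k, 0)

    def bump(self, sample: str, key: str) -> None:
        row = self.per_sample.setdefault(
            sample,
            {k: 0 for k in ("input_reads", "retained") + CATEGORIES},
        )
        row[key] += 1
        self.totals[key] += 1

    def check_partition(self) -> bool:
        rows = list(self.per_sample.values()) + [self.totals]
        return all(
            r["input_reads"] == r["retained"] + sum(r[c] for c in CATEGORIES)
            for r in rows
        )

    def to_rows(self) -> list[dict[str, object]]:
        rows: list[dict[str, object]] = []
        for sample in sorted(self.per_sample):
            for cat in ("input_reads",) + CATEGORIES + ("retained",):
                rows.append({"sample": sample, "category": cat,
                             "count": self.per_sample[sample][cat]})
        for cat in ("input_reads",) + CATEGORIES + ("retained",):
            rows.append({"sample": "TOTAL", "category": cat,
                         "count": self.totals[cat]})
        return rows


def load_mids(path: str | Path) -> list[MIDTag]:
    return [MIDTag(r["name"], r["sequence"].upper())
            for r in seqio.read_tsv(path)]


def _mismatches_at(seq: str, tag: str, start: int) -> int:
    window = seq[start : start + len(tag)]
    if len(window) < len(tag):
        return len(tag)
    return sum(1 for a, b in zip(window, tag) if a != b)


def _match_mid_pair(read: Read, mids: Sequence[MIDTag],
                    max_mm: int) -> tuple[str, str, Read] | None:
    """Try MIDs anchored at both termini of the read as-is (no revcomp retry).

    The 5' MID is matched forward at position 0; the 3' MID as its reverse
    complement anchored at the read's last base. Among qualifying tags the
    fewest-mismatch one wins, ties by sheet order.
    """
    best_f: tuple[int, int, MIDTag] | None = None
    best_r: tuple[int, int, MIDTag] | None = None
    for order, tag in enumerate(mids):
        if len(tag.bases) > len(read.bases):
            continue
        mm = _mismatches_at(read.bases, tag.bases, 0)
        if mm <= max_mm and (best_f is None or (mm, order) < best_f[:2]):
            best_f = (mm, order, tag)
        rc = revcomp(tag.bases)
        mm = _mismatches_at(read.bases, rc, len(read.bases) - len(rc))
        if mm <= max_mm and (best_r is None or (mm, order) < best_r[:2]):
            best_r = (mm, order, tag)
    if best_f is None or best_r is None:
        return None
    ftag, rtag = best_f[2], best_r[2]
    if len(ftag.bases) + len(rtag.bases) > len(read.bases):
        return None
    trimmed = read.trimmed(len(ftag.bases), len(read.bases) - len(rtag.bases))
    return ftag.name, rtag.name, trimmed


def find_mid_pair(read: Read, mids: Sequence[MIDTag],
                  mid_max_mismatches: int = 0,
                  sheet: SampleSheet | None = None,
                  ) -> tuple[str, str, Read, str] | None:
    """Identify the MID tag at each end of a read and trim both off.

    Tried as-read first, then on the reverse complement (success there
    reports orientation "reverse-complemented", with the returned read
    already orientation-normalized). When a sample sheet is supplied, an
    orientation whose MID pair is listed is preferred — a reversed read
    shows its pair swapped, which must not be mistaken for a chimera.
    ``None`` means the read goes to the ``mid_unidentified`` category.
    """
    hit_f = _match_mid_pair(read, mids, mid_max_mismatches)
    if hit_f is not None and (
        sheet is None or sheet.sample_for(hit_f[0], hit_f[1]) is not None
    ):
        return hit_f[0], hit_f[1], hit_f[2], AS_READ
    flipped = read.reverse_complemented()
    hit_r = _match_mid_pair(flipped, mids, mid_max_mismatches)
    if hit_r is not None and (
        sheet is None or sheet.sample_for(hit_r[0], hit_r[1]) is not None
    ):
        return hit_r[0], hit_r[1], hit_r[2], REVERSE_COMPLEMENTED
    # identifiable in some orientation but unlisted: surface the pair so the
    # chimera check downstream can categorize it
    if hit_f is not None:
        return hit_f[0], hit_f[1], hit_f[2], AS_READ
    if hit_r is not None:
        return hit_r[0], hit_r[1], hit_r[2], REVERSE_COMPLEMENTED
    return None


def check_chimera(forward_mid: str, reverse_mid: str,
                  sheet: SampleSheet) -> str | None:
    """Return the sample for a listed MID pair; ``None`` marks a chimera
    (both tags identifiable, combination not in the sheet)."""
    return sheet.sample_for(forward_mid, reverse_mid)


def match_primer(seq: str, primer: str, max_mismatches: int,
                 end: str) -> tuple[int, int, int] | None:
    """Locate ``primer`` in the terminal window of ``seq`` by bounded-cost
    edit-distance dynamic programming.

    The window is the first (``end="five_prime"``) or last
    (``end="three_prime"``) ``len(primer) + max_mismatches`` bases.
    Substitutions, insertions and deletions each cost 1. Returns
    ``(start, end, cost)`` on ``seq`` coordinates for the minimal-cost
    placement with cost <= ``max_mismatches``, ties broken by the placement
    closest to the read terminus, then by span length closest to the primer
    length. An exact substring hit in the window is found by direct scan
    first; the DP reproduces it identically.

    Returns ``None`` when no placement is within budget (the caller counts
    the read as ``primer_unidentified``).
    """
    if end not in ("five_prime", "three_prime"):
        raise ValueError(f"bad end: {end}")
    if not primer or len(primer) > len(seq):
        return None
    wlen = min(len(seq), len(primer) + max_mismatches)
    if end == "three_prime":
        # mirror: solve at the 5' end of the reversed strings
        hit = match_primer(seq[::-1][: wlen], primer[::-1], max_mismatches,
                           "five_prime")
        if hit is None:
            return None
        s, e, cost = hit
        return len(seq) - e, len(seq) - s, cost

    window = seq[:wlen]
    # fast path: exact match, leftmost occurrence
    idx = window.find(primer)
    if idx != -1:
        return idx, idx + len(primer), 0

    # sort key: (cost, start offset from terminus, |span - primer len|, end)
    best: tuple[int, int, int, int] | None = None
    for s in range(0, wlen):
        # final DP row gives edit_distance(primer, window[s:s+j]) for all j
        row = _edit_row_final(primer, window[s:])
        for off in range(1, len(row)):
            c = int(row[off])
            if c > max_mismatches:
                continue
            e = s + off
            key = (c, s, abs(off - len(primer)), e)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    cost, s, _, e = best
    return s, e, cost


def filter_length(read: Read, params: CleanParams) -> bool:
    """Length window check, inclusive at both ends."""
    return params.min_length <= len(read) <= params.max_length


def filter_quality(read: Read, params: CleanParams) -> bool:
    """Mean-Phred check over the trimmed read, inclusive threshold."""
    return read.mean_phred >= params.min_mean_quality


def _find_and_trim_primers(read: Read, primers: PrimerSet) -> Read | None:
    """Require a forward primer at the 5' end and a reverse primer (as its
    reverse complement) at the 3' end; trim everything outside the insert."""
    best5: tuple[int, int, int] | None = None
    for _, pseq in primers.forward_primers:
        hit = match_primer(read.bases, pseq.upper(), primers.max_mismatches,
                           "five_prime")
        if hit is not None and (best5 is None or hit[2] < best5[2]):
            best5 = hit
    if best5 is None:
        return None
    best3: tuple[int, int, int] | None = None
    for _, pseq in primers.reverse_primers:
        hit = match_primer(read.bases, revcomp(pseq.upper()),
                           primers.max_mismatches, "three_prime")
        if hit is not None and (best3 is None or hit[2] < best3[2]):
            best3 = hit
    if best3 is None:
        return None
    if best5[1] > best3[0]:
        return None  # primers overlap: no insert
    return read.trimmed(best5[1], best3[0])


@dataclass
class CleanResult:
    retained: dict[str, list[Read]]
    discards: dict[str, list[Read]]
    report: CleanReport


def clean_dataset(reads: Iterable[Read], sheet: SampleSheet,
                  mids: Sequence[MIDTag], primers: PrimerSet,
                  params: CleanParams) -> CleanResult:
    """Run the full cascade over a read stream.

    Reads that fail before a sample is known are charged to the pseudo-sample
    ``"unassigned"`` so the partition invariant holds per sample and in
    total.
    """
    report = CleanReport()
    retained: dict[str, list[Read]] = {s: [] for s, _, _ in sheet.entries}
    discards: dict[str, list[Read]] = {c: [] for c in CATEGORIES}

    for read in reads:
        hit = find_mid_pair(read, mids, params.mid_max_mismatches, sheet)
        if hit is None:
            report.bump("unassigned", "input_reads")
            report.bump("unassigned", "mid_unidentified")
            discards["mid_unidentified"].append(read)
            continue
        fwd, rev, trimmed, _orient = hit
        sample = check_chimera(fwd, rev, sheet)
        if sample is None:
            report.bump("unassigned", "input_reads")
            report.bump("unassigned", "chimera_discarded")
            discards["chimera_discarded"].append(read)
            continue
        report.bump(sample, "input_reads")
        insert = _find_and_trim_primers(trimmed, primers)
        if insert is None:
            report.bump(sample, "primer_unidentified")
            discards["primer_unidentified"].append(trimmed)
            continue
        if not filter_length(insert, params):
            report.bump(sample, "length_discarded")
            discards["length_discarded"].append(insert)
            continue
        if not filter_quality(insert, params):
            report.bump(sample, "quality_discarded")
            discards["quality_discarded"].append(insert)
            continue
        report.bump(sample, "retained")
        retained[sample].append(insert)
    return CleanResult(retained, discards, report)


def write_clean_outputs(result: CleanResult, out_dir: str | Path) -> None:
    """Write per-sample retained FASTQ, per-category discard FASTQ, and the
    TSV report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "discards").mkdir(exist_ok=True)
    for sample, rds in sorted(result.retained.items()):
        seqio.write_fastq(rds, out / f"{sample}.clean.fastq")
    for cat, rds in result.discards.items():
        seqio.write_fastq(rds, out / "discards" / f"{cat}.fastq")
    seqio.write_tsv(result.report.to_rows(), out / "clean_report.tsv",
                    ["sample", "category", "count"])
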