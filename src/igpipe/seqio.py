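"""Sequence I/O primitives: FASTQ/FASTA readers and writers, reverse
complement, translation.

All coordinates in this package are 0-based, half-open. Quality scores are
Phred+33 on disk and plain integers in memory.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.Seq import Seq

_DNA_ALPHABET = frozenset("ACGTN")

#: orientation states for a read
AS_READ = "as-read"
REVERSE_COMPLEMENTED = "reverse-complemented"


class FastqParseError(ValueError):
    """Raised for malformed FASTQ/FASTA input; names the offending record."""


@dataclass
class Read:
    """One sequencing read.

    Attributes
    ----------
    read_id : str
        Opaque identifier (FASTQ header without ``@``).
    bases : str
        Uppercase DNA over ``{A,C,G,T,N}``.
    quals : list[int]
        Per-base Phred scores, same length as ``bases``.
    orientation : str
        ``"as-read"`` or ``"reverse-complemented"``.
    """

    read_id: str
    bases: str
    quals: list[int] = field(default_factory=list)
    orientation: str = AS_READ

    def __post_init__(self) -> None:
        self.bases = self.bases.upper()
        if self.quals and len(self.quals) != len(self.bases):
            raise FastqParseError(
                f"read {self.read_id!r}: {len(self.quals)} quality values for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mean_phred(self) -> float:
        """Arithmetic mean Phred score (0.0 for an empty read)."""
        if not self.quals:
            return 0.0
        return statistics.fmean(self.quals)

    def trimmed(self, start: int, end: int) -> "Read":
        """Return a copy restricted to ``bases[start:end]`` (0-based, half-open)."""
        return Read(
            self.read_id,
            self.bases[start:end],
            self.quals[start:end],
            self.orientation,
        )

    def reverse_complemented(self) -> "Read":
        """Reverse-complement bases, reverse qualities, flip orientation."""
        flipped = (
            REVERSE_COMPLEMENTED if self.orientation == AS_READ else AS_READ
        )
        return Read(self.read_id, revcomp(self.bases), self.quals[::-1], flipped)


def revcomp(bases: str) -> str:
    """Reverse complement of a DNA string over ``{A,C,G,T,N}``.

    An involution: ``revcomp(revcomp(s)) == s``. Raises ``ValueError`` on
    characters outside the alphabet.
    """
    if not set(bases) <= _DNA_ALPHABET:
        bad = sorted(set(bases) - _DNA_ALPHABET)
        raise ValueError(f"non-IUPAC characters in sequence: {bad}")
    return str(Seq(bases).reverse_complement())


def translate(bases: str, frame: int = 0) -> str:
    """Translate DNA in the given frame (0, 1 or 2) with the standard code.

    The trailing partial codon is ignored; any codon containing ``N``
    translates to ``'X'``; stop codons are ``'*'``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    sub = bases[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    out = []
    for i in range(0, len(sub), 3):
        codon = sub[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)


def _decode_quals(qual_str: str, read_id: str) -> list[int]:
    quals = [ord(c) - 33 for c in qual_str]
    if any(q < 0 for q in quals):
        raise FastqParseError(
            f"read {read_id!r}: quality character below '!' — not Phred+33"
        )
    if all(q >= 31 for q in quals) and any(q > 60 for q in quals):
        # Phred+64 data decodes to uniformly high, often >60, values.
        raise FastqParseError(
            f"read {read_id!r}: quality values exceed 60 — looks like "
            "Phred+64, which is not supported (re-encode as Phred+33)"
        )
    return quals


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Yield :class:`Read` objects from a 4-line-record Phred+33 FASTQ file."""
    with open(path) as fh:
        record_idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            if header.strip() == "":
                continue
            if not header.startswith("@"):
                raise FastqParseError(
                    f"record {record_idx}: header does not start with '@'"
                )
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqParseError(f"record {record_idx}: truncated record")
            if not plus.startswith("+"):
                raise FastqParseError(
                    f"record {record_idx}: separator line does not start with '+'"
                )
            read_id = header[1:].strip().split()[0] if header[1:].strip() else ""
            bases = seq.strip().upper()
            qual_str = qual.rstrip("\n")
            if len(qual_str) != len(bases):
                raise FastqParseError(
                    f"record {record_idx} ({read_id!r}): sequence length "
                    f"{len(bases)} != quality length {len(qual_str)}"
                )
            yield Read(read_id, bases, _decode_quals(qual_str, read_id))
            record_idx += 1


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as 4-line FASTQ (Phred+33). Returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.quals) + "\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(header, sequence)`` pairs; header is the full line after ``>``."""
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks).upper()
                header = line[1:].strip()
                chunks = []
            elif line:
                chunks.append(line.strip())
    if header is not None:
        yield header, "".join(chunks).upper()


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 80) -> int:
    """Write ``(header, sequence)`` records, wrapping sequence at ``width``."""
    n = 0
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
            if not seq:
                fh.write("\n")
            n += 1
    return n


def read_fasta_qual(fasta_path: str | Path, qual_path: str | Path) -> Iterator[Read]:
    """Merge a FASTA file and a matching ``.qual`` file into Reads.

    The qual file holds whitespace-separated integer Phred scores under the
    same headers, in the same order.
    """
    quals: dict[str, list[int]] = {}
    header: str | None = None
    nums: list[int] = []
    with open(qual_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    quals[header] = nums
                header = line[1:].split()[0]
                nums = []
            elif line:
                nums.extend(int(x) for x in line.split())
    if header is not None:
        quals[header] = nums

    for full_header, seq in read_fasta(fasta_path):
        rid = full_header.split()[0]
        if rid not in quals:
            raise FastqParseError(f"read {rid!r}: no matching quality record")
        q = quals[rid]
        if len(q) != len(seq):
            raise FastqParseError(
                f"read {rid!r}: {len(q)} quality values for {len(seq)} bases"
            )
        yield Read(rid, seq, q)


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    """Read a header-rowed TSV into a list of dicts (all values strings)."""
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            return rows
        cols = header_line.rstrip("\n").split("\t")
        for line in fh:
            if line.strip() == "":
                continue
            vals = line.rstrip("\n").split("\t")
            rows.append(dict(zip(cols, vals)))
    return rows


def write_tsv(rows: Iterable[dict], path: str | Path,
              columns: list[str] | None = None) -> int:
    """Write dict rows as a header-rowed TSV with ``\\n`` line endings."""
    rows = list(rows)
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
            n += 1
    return n
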