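"""Cleaning cascade: MID demultiplexing, chimera discard, primer DP,
length/quality filters, and exact report accounting."""

import functools
import random

import pytest

from igpipe.cleaner import (
    CleanParams, CleanReport, MIDTag, PrimerSet, SampleSheet, check_chimera,
    clean_dataset, filter_length, filter_quality, find_mid_pair, match_primer,
)
from igpipe.seqio import Read, revcomp

MIDS = [MIDTag("A", "ACGTACGTAC"), MIDTag("B", "TTGGCCAATT"),
        MIDTag("C", "GACGACGACG"), MIDTag("D", "CTCTAGAGAG")]
SHEET = SampleSheet([("S1", "A", "B"), ("S2", "D", "C")])


def _mid(name):
    return next(m.bases for m in MIDS if m.name == name)


def _wrap(core, fwd="A", rev="B"):
    return _mid(fwd) + core + revcomp(_mid(rev))


class TestFindMidPair:
    def test_pair_found_and_trimmed(self):
        core = "ACGT" * 10
        read = Read("r", _wrap(core))
        f, r, trimmed, orient = find_mid_pair(read, MIDS)
        assert (f, r, orient) == ("A", "B", "as-read")
        assert trimmed.bases == core

    def test_unrecognizable_mid_fails(self):
        read = Read("r", "T" * 60)
        assert find_mid_pair(read, MIDS) is None

    def test_reversed_read_found_with_orientation(self):
        core = "ACGT" * 10
        read = Read("r", revcomp(_wrap(core)))
        hit = find_mid_pair(read, MIDS, sheet=SHEET)
        assert hit is not None
        f, r, trimmed, orient = hit
        assert (f, r, orient) == ("A", "B", "reverse-complemented")
        assert trimmed.bases == core

    def test_orientation_idempotence_with_sheet(self):
        """A read and its reverse complement clean to the same sample and
        sequence."""
        core = "ACGTTGCA" * 6
        fwd = find_mid_pair(Read("r", _wrap(core)), MIDS, sheet=SHEET)
        rev = find_mid_pair(Read("r", revcomp(_wrap(core))), MIDS, sheet=SHEET)
        assert fwd[:2] == rev[:2]
        assert fwd[2].bases == rev[2].bases


class TestChimera:
    def test_listed_pair_maps_to_sample(self):
        assert check_chimera("A", "B", SHEET) == "S1"

    def test_identifiable_but_unlisted_pair_is_chimera(self):
        assert check_chimera("A", "C", SHEET) is None

    def test_empty_sheet_everything_chimeric(self):
        empty = SampleSheet([])
        assert check_chimera("A", "B", empty) is None


def _brute_primer(seq, primer, max_mm, end):
    """Independent oracle: enumerate every placement in the terminal window
    and compute its Levenshtein cost; report the minimum."""
    @functools.lru_cache(maxsize=None)
    def lev(x, y):
        if not x:
            return len(y)
        if not y:
            return len(x)
        return min(lev(x[:-1], y) + 1, lev(x, y[:-1]) + 1,
                   lev(x[:-1], y[:-1]) + (x[-1] != y[-1]))
    wlen = min(len(seq), len(primer) + max_mm)
    window = seq[:wlen] if end == "five_prime" else seq[len(seq) - wlen:]
    best = None
    for s in range(wlen):
        for e in range(s + 1, wlen + 1):
            c = lev(primer, window[s:e])
            if c <= max_mm and (best is None or c < best):
                best = c
    return best


class TestMatchPrimer:
    def test_exact_at_start(self):
        assert match_primer("ACGTACGTTTTT", "ACGTACGT", 0, "five_prime") == (0, 8, 0)

    def test_one_substitution(self):
        assert match_primer("ACCTACGTTTTT", "ACGTACGT", 1, "five_prime") == (0, 8, 1)

    def test_hopeless_sequence_fails(self):
        assert match_primer("T" * 20, "ACGTACGT", 1, "five_prime") is None

    def test_three_prime_exact(self):
        seq = "T" * 12 + "ACGTACGT"
        assert match_primer(seq, "ACGTACGT", 0, "three_prime") == (12, 20, 0)

    def test_indel_tolerated_within_budget(self):
        # primer with one base deleted from the read
        seq = "ACGTCGT" + "T" * 12
        assert match_primer(seq, "ACGTACGT", 1, "five_prime") == (0, 7, 1)

    @pytest.mark.parametrize("end", ["five_prime", "three_prime"])
    def test_agrees_with_brute_force(self, end):
        rng = random.Random(21)
        for _ in range(300):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 40)))
            plen = rng.randint(4, 12)
            if rng.random() < 0.5:
                primer = "".join(rng.choice("ACGT") for _ in range(plen))
            else:  # planted, possibly corrupted, primer at the terminus
                primer = (seq[:plen] if end == "five_prime" else seq[-plen:])
                primer = "".join(
                    c if rng.random() > 0.2 else rng.choice("ACGT")
                    for c in primer)
            max_mm = rng.randint(0, 2)
            got = match_primer(seq, primer, max_mm, end)
            want = _brute_primer(seq, primer, max_mm, end)
            if want is None:
                assert got is None
            else:
                assert got is not None and got[2] == want


class TestFilters:
    @pytest.mark.parametrize("length,ok", [(400, True), (249, False),
                                           (250, True), (600, True),
                                           (601, False)])
    def test_length_window_inclusive(self, length, ok):
        read = Read("r", "A" * length, [30] * length)
        assert filter_length(read, CleanParams()) is ok

    @pytest.mark.parametrize("quals,ok", [([30, 30, 30], True),
                                          ([20, 20, 20], False),
                                          ([20, 30], True)])
    def test_quality_threshold_inclusive(self, quals, ok):
        read = Read("r", "A" * len(quals), quals)
        assert filter_quality(read, CleanParams()) is ok


def _primer_set():
    return PrimerSet([("PF", "ACGGTCTGACCTAGGAACCT")],
                     [("PR", "TGGCAATCCGGTACTGTTGG")], max_mismatches=2)


def _full_read(rid, insert, fwd="A", rev="B", qual=35):
    ps = _primer_set()
    seq = (_mid(fwd) + ps.forward_primers[0][1] + insert
           + revcomp(ps.reverse_primers[0][1]) + revcomp(_mid(rev)))
    return Read(rid, seq, [qual] * len(seq))


class TestCleanDataset:
    def test_defect_free_batch_all_retained(self):
        insert = "ACGT" * 75
        reads = [_full_read(f"r{i}", insert) for i in range(10)]
        res = clean_dataset(reads, SHEET, MIDS, _primer_set(),
                            CleanParams(100, 600, 25.0))
        assert res.report.totals["retained"] == 10
        assert all(res.report.totals[c] == 0 for c in (
            "mid_unidentified", "chimera_discarded", "primer_unidentified",
            "length_discarded", "quality_discarded"))
        assert [r.bases for r in res.retained["S1"]] == [insert] * 10

    def test_scrambled_mids_counted(self):
        insert = "ACGT" * 75
        good = [_full_read(f"g{i}", insert) for i in range(7)]
        bad = [Read(f"b{i}", "TGCA" * 80, [35] * 320) for i in range(3)]
        res = clean_dataset(good + bad, SHEET, MIDS, _primer_set(),
                            CleanParams(100, 600, 25.0))
        assert res.report.totals["mid_unidentified"] == 3
        assert res.report.totals["retained"] == 7

    def test_every_category_partitions(self):
        insert = "ACGT" * 75
        reads = [
            _full_read("ok", insert),
            _full_read("chim", insert, fwd="A", rev="C"),  # unlisted pair
            Read("nomid", "G" * 300, [35] * 300),
            _full_read("short", "ACGT" * 10),              # 40 nt insert
            _full_read("lowq", insert, qual=10),
        ]
        mid_a = _mid("A")
        noprim = mid_a + "T" * 300 + revcomp(_mid("B"))
        reads.append(Read("noprim", noprim, [35] * len(noprim)))
        res = clean_dataset(reads, SHEET, MIDS, _primer_set(),
                            CleanParams(100, 600, 25.0))
        t = res.report.totals
        assert t["input_reads"] == 6
        assert t["retained"] == 1
        assert t["chimera_discarded"] == 1
        assert t["mid_unidentified"] == 1
        assert t["length_discarded"] == 1
        assert t["quality_discarded"] == 1
        assert t["primer_unidentified"] == 1
        assert res.report.check_partition()

    def test_orientation_idempotence_end_to_end(self):
        insert = "ACGTTGCA" * 40
        fwd = _full_read("r", insert)
        rev = Read("r", revcomp(fwd.bases), fwd.quals[::-1])
        res_f = clean_dataset([fwd], SHEET, MIDS, _primer_set(), CleanParams())
        res_r = clean_dataset([rev], SHEET, MIDS, _primer_set(), CleanParams())
        assert [r.bases for r in res_f.retained["S1"]] == \
               [r.bases for r in res_r.retained["S1"]] == [insert]


def test_report_partition_identity_on_published_scale_counts():
    """The report structure reproduces the worked accounting arithmetic of
    a full 454 run: reads with both MIDs, minus primer failures, minus
    quality failures (none length-discarded), equals the retained total."""
    rep = CleanReport()
    rep.totals.update({
        "input_reads": 63283, "primer_unidentified": 2029,
        "quality_discarded": 707, "length_discarded": 0,
        "mid_unidentified": 0, "chimera_discarded": 0, "retained": 60547,
    })
    assert rep.check_partition()
    assert 63283 - 2029 - 707 == 60547
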