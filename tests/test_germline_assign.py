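"""Template-free V(D)J assignment: segment search, reconstruction,
functionality classification."""

import random

import pytest

from igpipe.germline_assign import (
    AssignParams, AssignmentError, align_segment, assign_all, assign_vdj,
    split_by_functionality,
)
from igpipe.seqio import Read
from igpipe.simulate import SimParams, simulate_repertoire

TOY_PARAMS = AssignParams(min_segment_score=12, min_d_length=4, min_j_overlap=6)


def _read(bases):
    return Read("r", bases, [35] * len(bases))


class TestAlignSegment:
    def test_verbatim_segment(self, mini_library):
        v1 = mini_library.get("V1*01")
        m = align_segment("TT" + v1.bases + "GG", v1)
        assert m.score == 2 * len(v1.bases)
        assert m.n_mismatches == 0

    def test_one_substitution(self, mini_library):
        v1 = mini_library.get("V1*01")
        mutated = "C" + v1.bases[1:]  # A->C at position 0
        m = align_segment(mutated, v1)
        # local alignment clips the terminal mismatch instead of paying it
        assert m.score == 2 * (len(v1.bases) - 1)


class TestAssignVdj:
    def test_clean_rearrangement(self, mini_library):
        read = _read("ATGGCCGCA" + "AAA" + "TTGACT")
        a = assign_vdj(read, mini_library, TOY_PARAMS)
        assert a.v_match.segment_id == "V1*01"
        assert a.j_match.segment_id == "J1*01"
        assert a.junction == "AAA"
        assert a.d_match is None
        assert a.germline_sequence == read.bases

    def test_d_found_in_junction(self, mini_library):
        read = _read("ATGGCCGCA" + "AGGGGA" + "TTGACT")
        a = assign_vdj(read, mini_library, TOY_PARAMS)
        assert a.junction == "AGGGGA"
        assert a.d_match is not None
        assert a.d_match.segment_id == "D1*01"

    def test_unrelated_read_fails(self, toy_library):
        rng = random.Random(5)
        read = _read("".join(rng.choice("ACGT") for _ in range(30)))
        with pytest.raises(AssignmentError):
            assign_vdj(read, toy_library)  # default min_segment_score

    def test_region_map_ordered_disjoint(self, toy_library):
        v = toy_library.by_kind("V")[0]
        j = toy_library.by_kind("J")[0]
        read = _read(v.bases + "ACGTACGTA" + j.bases)
        a = assign_vdj(read, toy_library)
        ivs = sorted(a.region_map.values())
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert s1 < e1 <= s2 < e2
        assert "CDR3" in a.region_map and "FR4" in a.region_map


class TestFunctionality:
    def test_in_frame_no_stop_is_functional(self, mini_library):
        a = assign_vdj(_read("ATGGCCGCA" + "AAA" + "TTGACT"),
                       mini_library, TOY_PARAMS)
        assert a.functionality == "functional"

    def test_stop_codon_in_junction(self, mini_library):
        a = assign_vdj(_read("ATGGCCGCA" + "TAA" + "TTGACT"),
                       mini_library, TOY_PARAMS)
        assert a.functionality == "non_functional"

    def test_frame_shift(self, mini_library):
        a = assign_vdj(_read("ATGGCCGCA" + "AA" + "TTGACT"),
                       mini_library, TOY_PARAMS)
        assert a.functionality == "non_functional"

    def test_short_j_is_indeterminate(self, mini_library):
        params = AssignParams(min_segment_score=8, min_d_length=4,
                              min_j_overlap=6)
        a = assign_vdj(_read("ATGGCCGCA" + "AAA" + "TTGA"),
                       mini_library, params)
        assert a.functionality == "indeterminate"

    def test_partition_total_and_exclusive(self, toy_library):
        params = SimParams(seed=3, n_samples=1, n_clones_per_sample=10,
                           clone_size_distribution=("fixed", 2),
                           substitution_rate=0.01, duplicate_rate=0.0,
                           artifact_indel_probability=0.0,
                           fraction_reversed=0.0)
        corpus = simulate_repertoire(params, toy_library)
        inserts = _strip_adapters(corpus, params)
        assignments, failed = assign_all(inserts, toy_library)
        assert not failed
        split = split_by_functionality(assignments)
        assert sum(len(v) for v in split.values()) == len(assignments)
        ids = [a.read_id for group in split.values() for a in group]
        assert len(ids) == len(set(ids))


def test_published_scale_partition_arithmetic():
    """Functionality partitions sum exactly (as in the full-scale run where
    17,763 indel-free sequences split 10,029 / 1 / 7,733)."""
    assert 10029 + 1 + 7733 == 17763


def _strip_adapters(corpus, params):
    """Recover the bare inserts from a defect-free simulated corpus using
    the truth table (cleaning is exercised elsewhere)."""
    out = []
    mid_by_sample = {s: (f, r) for s, f, r in corpus.sheet.entries}
    mids = {m.name: m.bases for m in corpus.mids}
    from igpipe.seqio import revcomp
    for read, t in zip(corpus.reads, corpus.truth):
        bases = read.bases
        if t.orientation == "reverse-complemented":
            bases = revcomp(bases)
        f, r = mid_by_sample[t.sample_id]
        lead = len(mids[f]) + len(params.forward_primer)
        tail = len(mids[r]) + len(params.reverse_primer)
        out.append(Read(read.read_id, bases[lead:-tail], [35] * (len(bases) - lead - tail)))
    return out


class TestRecovery:
    def test_unmutated_reads_reconstruct_exactly(self, toy_library):
        """With zero mutations the germline reconstruction equals the read
        and V/J alignments are mismatch-free."""
        params = SimParams(seed=11, n_samples=1, n_clones_per_sample=8,
                           clone_size_distribution=("fixed", 2),
                           substitution_rate=0.0, duplicate_rate=0.0,
                           artifact_indel_probability=0.0,
                           fraction_reversed=0.0)
        corpus = simulate_repertoire(params, toy_library)
        truth = corpus.truth_by_id()
        for read in _strip_adapters(corpus, params):
            a = assign_vdj(read, toy_library)
            t = truth[a.read_id]
            assert a.v_match.segment_id == t.v_id
            assert a.j_match.segment_id == t.j_id
            assert a.germline_sequence == read.bases
            assert a.v_match.n_mismatches == 0
            assert a.j_match.n_mismatches == 0
            assert a.junction == t.junction

    def test_segment_recovery_under_mutation(self, toy_library):
        """True V and J recovered for >= 95% of reads mutated at 5%."""
        params = SimParams(seed=12, n_samples=1, n_clones_per_sample=50,
                           clone_size_distribution=("fixed", 2),
                           substitution_rate=0.05, duplicate_rate=0.0,
                           artifact_indel_probability=0.0,
                           fraction_reversed=0.0)
        corpus = simulate_repertoire(params, toy_library)
        truth = corpus.truth_by_id()
        reads = _strip_adapters(corpus, params)
        assignments, failed = assign_all(reads, toy_library)
        ok = sum(a.v_match.segment_id == truth[a.read_id].v_id
                 and a.j_match.segment_id == truth[a.read_id].j_id
                 for a in assignments)
        assert ok / len(reads) >= 0.95
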