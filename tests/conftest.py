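"""Shared fixtures: a deterministic toy germline library and small
simulated corpora. Everything is generated programmatically at test time."""

from __future__ import annotations

import pytest

from igpipe.germline_assign import GermlineLibrary, GermlineSegment
from igpipe.simulate import SimParams, make_toy_library, simulate_repertoire


@pytest.fixture(scope="session")
def toy_library() -> GermlineLibrary:
    return make_toy_library(seed=0)


@pytest.fixture(scope="session")
def mini_library() -> GermlineLibrary:
    """Hand-built miniature library with known sequences, for worked
    examples: V of 3 codons, J of 2 codons with FR4 at its start."""
    return GermlineLibrary([
        GermlineSegment("V1*01", "V", "ATGGCCGCA", 0,
                        {"fr1": (0, 3), "cdr1": (3, 6), "fr2": (6, 9)}),
        GermlineSegment("V2*01", "V", "TTCTGGAAG", 0, {"fr1": (0, 9)}),
        GermlineSegment("J1*01", "J", "TTGACT", 0, None, 0),
        GermlineSegment("J2*01", "J", "GGCCAA", 0, None, 0),
        GermlineSegment("D1*01", "D", "GGGG"),
    ])


@pytest.fixture(scope="session")
def benign_corpus(toy_library):
    """Small corpus with mutations but no artifacts, duplicates or
    defects — downstream truth should be recovered exactly."""
    params = SimParams(
        seed=7, n_samples=2, n_clones_per_sample=6,
        clone_size_distribution=("fixed", 3),
        substitution_rate=0.02, artifact_indel_probability=0.0,
        duplicate_rate=0.0, fraction_reversed=0.3,
    )
    return params, simulate_repertoire(params, toy_library)
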