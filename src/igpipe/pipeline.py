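"""Pipeline orchestration: clean -> dedup -> assign -> clones -> indel
screen -> functionality split -> second clone pass -> trees -> mutation
statistics -> repertoire tables.

Stages communicate through documented on-disk formats, so any stage can be
re-run standalone from the previous stage's outputs; a run ledger records
input/output counts and the parameter snapshot per stage, and every read
is traceable to exactly one terminal fate.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

from igpipe import seqio
from igpipe.cleaner import (
    CleanParams, CleanResult, PrimerSet, SampleSheet, clean_dataset,
    load_mids, write_clean_outputs,
)
from igpipe.clone_builder import Clone, build_clones, write_clone_outputs
from igpipe.dedup import UniqueSet, collapse_duplicates, write_unique_outputs
from igpipe.germline_assign import (
    AssignParams, GermlineLibrary, VDJAssignment, assign_all,
    split_by_functionality, write_assignments,
)
from igpipe.indel_identifier import (
    IndelParams, IndelPartition, partition_by_indels, write_indel_outputs,
)
from igpipe.lineage import LineageTree, build_tree, write_all_trees
from igpipe.mutation_stats import mutation_records, write_mutation_outputs
from igpipe.repertoire import write_group_average, write_repertoire_outputs


@dataclass
class PipelineConfig:
    fastq: str
    sample_sheet: str
    mids: str
    primers: str
    library: str
    out_dir: str
    clean_params: CleanParams = field(default_factory=CleanParams)
    max_primer_mismatches: int = 2
    assign_params: AssignParams = field(default_factory=AssignParams)
    indel_params: IndelParams = field(default_factory=IndelParams)
    functionality_profile: str = "all"  # all / functional_only / non_functional_only
    include_d_in_key: bool = True

    def __post_init__(self) -> None:
        allowed = ("all", "functional_only", "non_functional_only")
        if self.functionality_profile not in allowed:
            raise ValueError(
                f"functionality_profile must be one of {allowed}")


@dataclass
class SampleResult:
    sample_id: str
    unique_set: UniqueSet
    assignments: list[VDJAssignment]
    failed_ids: list[str]
    clones_pass1: list[Clone]
    indel_partition: IndelPartition
    functionality: dict[str, list[VDJAssignment]]
    clones_final: list[Clone]
    trees: list[LineageTree]


@dataclass
class PipelineResult:
    clean: CleanResult
    samples: dict[str, SampleResult]
    ledger: list[dict]


def _ledger_row(stage: str, sample: str, n_in: int, n_out: int,
                note: str, t0: float) -> dict:
    # wall time is kept out of the TSV so that identical runs produce a
    # byte-identical ledger; timings go to a side log instead
    return {
        "stage": stage, "sample": sample, "input": n_in, "output": n_out,
        "note": note, "_seconds": time.perf_counter() - t0,
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order, writing each stage's outputs under
    ``out_dir`` and returning the in-memory results plus the ledger."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ledger: list[dict] = []

    # --- clean -----------------------------------------------------------
    t0 = time.perf_counter()
    sheet = SampleSheet.from_tsv(config.sample_sheet)
    mids = load_mids(config.mids)
    primers = PrimerSet.from_tsv(config.primers, config.max_primer_mismatches)
    library = GermlineLibrary.from_fasta(config.library)
    reads = list(seqio.read_fastq(config.fastq))
    clean = clean_dataset(reads, sheet, mids, primers, config.clean_params)
    write_clean_outputs(clean, out / "clean")
    assert clean.report.check_partition(), "clean report must partition input"
    ledger.append(_ledger_row(
        "clean", "ALL", len(reads), clean.report.totals["retained"],
        ";".join(f"{c}={clean.report.totals[c]}"
                 for c in clean.report.totals), t0))

    samples: dict[str, SampleResult] = {}
    vj_tables = []
    for sample_id in sorted(clean.retained):
        sample_reads = clean.retained[sample_id]
        sdir = out / "samples" / sample_id
        sdir.mkdir(parents=True, exist_ok=True)

        # --- dedup -------------------------------------------------------
        t0 = time.perf_counter()
        uset = collapse_duplicates(sample_reads)
        write_unique_outputs(uset, sdir / "unique.fasta", sdir / "dups.tsv")
        ledger.append(_ledger_row("dedup", sample_id, len(sample_reads),
                                  len(uset.uniques), "", t0))

        # --- assign ------------------------------------------------------
        t0 = time.perf_counter()
        assignments, failed = assign_all(uset.reads, library,
                                         config.assign_params)
        write_assignments(assignments, sdir / "assignments.tsv")
        ledger.append(_ledger_row("assign", sample_id, len(uset.uniques),
                                  len(assignments),
                                  f"unassigned={len(failed)}", t0))

        # --- first clone pass -------------------------------------------
        t0 = time.perf_counter()
        clones1 = build_clones(assignments, library, config.assign_params,
                               config.include_d_in_key)
        write_clone_outputs(clones1, sdir / "clones_pass1")
        ledger.append(_ledger_row("clones_pass1", sample_id,
                                  len(assignments), len(clones1), "", t0))

        # --- indel screen -----------------------------------------------
        t0 = time.perf_counter()
        partition = partition_by_indels(clones1, config.indel_params)
        write_indel_outputs(partition, sdir / "indels")
        counts = partition.counts
        ledger.append(_ledger_row(
            "indels", sample_id, len(assignments),
            counts["indel_free"],
            ";".join(f"{k}={v}" for k, v in counts.items()), t0))

        # --- functionality split (before the second pass) ---------------
        t0 = time.perf_counter()
        free_ids = set(partition.indel_free)
        free_assignments = [a for a in assignments if a.read_id in free_ids]
        func = split_by_functionality(free_assignments)
        for name, group in func.items():
            seqio.write_fasta(((a.read_id, a.bases) for a in group),
                              sdir / f"{name}.fasta")
        ledger.append(_ledger_row(
            "functionality", sample_id, len(free_assignments),
            len(func["functional"]),
            ";".join(f"{k}={len(v)}" for k, v in func.items()), t0))

        if config.functionality_profile == "functional_only":
            kept = func["functional"]
        elif config.functionality_profile == "non_functional_only":
            kept = func["non_functional"]
        else:
            kept = free_assignments

        # --- second clone pass on indel-free sequences -------------------
        t0 = time.perf_counter()
        clones2 = build_clones(kept, library, config.assign_params,
                               config.include_d_in_key)
        write_clone_outputs(clones2, sdir / "clones")
        ledger.append(_ledger_row("clones_final", sample_id, len(kept),
                                  len(clones2), "", t0))

        # --- trees (singleton unmutated clones are root-only; size-1
        # clones are kept in repertoire counts but skipped here) ----------
        t0 = time.perf_counter()
        trees = [build_tree(c) for c in clones2 if c.size >= 2]
        write_all_trees(trees, sdir / "trees")
        ledger.append(_ledger_row("trees", sample_id, len(clones2),
                                  len(trees), "", t0))

        # --- mutation statistics ----------------------------------------
        t0 = time.perf_counter()
        clone_by_id = {c.clone_id: c for c in clones2}
        records = []
        for tree in trees:
            clone = clone_by_id[tree.clone_id]
            records.extend(mutation_records(tree, clone,
                                            clone.consensus_frame_start))
        write_mutation_outputs(records, sdir / "mutations")
        ledger.append(_ledger_row("mutations", sample_id, len(trees),
                                  len(records), "", t0))

        # --- repertoire --------------------------------------------------
        t0 = time.perf_counter()
        table = write_repertoire_outputs(clones2, library,
                                         uset.duplicate_map,
                                         sdir / "repertoire")
        vj_tables.append(table)
        ledger.append(_ledger_row("repertoire", sample_id, len(clones2),
                                  len(table), "", t0))

        samples[sample_id] = SampleResult(
            sample_id, uset, assignments, failed, clones1, partition,
            func, clones2, trees,
        )

    if vj_tables:
        write_group_average(vj_tables, out / "repertoire_group")
    seqio.write_tsv(ledger, out / "ledger.tsv",
                    ["stage", "sample", "input", "output", "note"])
    with open(out / "timing.log", "w") as fh:
        for row in ledger:
            fh.write(f"{row['stage']}\t{row['sample']}\t"
                     f"{row['_seconds']:.2f}s\n")
    return PipelineResult(clean, samples, ledger)
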