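"""Repertoire tables: V-J gene usage and clonal size distributions.

Usage is tabulated on the full cartesian grid of V and J genes (allele
suffixes stripped), as clone counts and unique-sequence counts with
percentages of the sample totals. Cross-sample group averages are
unweighted means of the per-sample *percentages*, so each individual
contributes equally regardless of sequencing depth — the normalization of
choice when PCR bias makes raw depths incomparable. Clonal size
distributions report, per clone, the number of unique sequences and the
number of sequences including PCR duplicates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from igpipe.clone_builder import Clone
from igpipe.germline_assign import GermlineLibrary


def gene_name(segment_id: str) -> str:
    """Gene-level name: strip the ``*allele`` suffix."""
    return segment_id.split("*")[0]


def vj_table(clones: Sequence[Clone], library: GermlineLibrary) -> pd.DataFrame:
    """Long-format V x J grid (every combination, zero-filled) with clone
    and unique-sequence counts and their percentages of the sample totals.
    Percentages are 0 when the corresponding total is 0."""
    v_genes = sorted({gene_name(s.segment_id) for s in library.by_kind("V")})
    j_genes = sorted({gene_name(s.segment_id) for s in library.by_kind("J")})
    idx = pd.MultiIndex.from_product([v_genes, j_genes], names=["v_gene", "j_gene"])
    df = pd.DataFrame(0, index=idx, columns=["clones", "uniques"])
    for clone in clones:
        key = (gene_name(clone.key.v_id), gene_name(clone.key.j_id))
        df.loc[key, "clones"] += 1
        df.loc[key, "uniques"] += clone.size
    for col in ("clones", "uniques"):
        total = df[col].sum()
        df[f"{col}_pct"] = 100.0 * df[col] / total if total else 0.0
    return df.reset_index()


def average_percent(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Unweighted mean of per-sample percentages, cell by cell; all tables
    must share the same V x J grid."""
    if not tables:
        raise ValueError("need at least one table")
    ref = tables[0][["v_gene", "j_gene"]]
    for t in tables[1:]:
        if not ref.equals(t[["v_gene", "j_gene"]]):
            raise ValueError("V-J grids differ between samples")
    out = ref.copy()
    for col in ("clones_pct", "uniques_pct"):
        out[col] = sum(t[col].to_numpy() for t in tables) / len(tables)
    return out


def clonal_size_distribution(clones: Sequence[Clone],
                             duplicate_map: dict[str, list[str]],
                             ) -> pd.DataFrame:
    """Per clone: unique-sequence count and total sequence count (each
    member counts 1 plus its PCR duplicates)."""
    rows = []
    for clone in clones:
        n_seq = sum(1 + len(duplicate_map.get(m.read_id, []))
                    for m in clone.members)
        rows.append({"clone_id": clone.clone_id, "n_unique": clone.size,
                     "n_sequences": n_seq})
    return pd.DataFrame(rows, columns=["clone_id", "n_unique", "n_sequences"])


def write_repertoire_outputs(clones: Sequence[Clone],
                             library: GermlineLibrary,
                             duplicate_map: dict[str, list[str]],
                             out_dir: str | Path) -> pd.DataFrame:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = vj_table(clones, library)
    table[["v_gene", "j_gene", "clones", "clones_pct"]].to_csv(
        out / "vj_clones.tsv", sep="\t", index=False)
    table[["v_gene", "j_gene", "uniques", "uniques_pct"]].to_csv(
        out / "vj_uniques.tsv", sep="\t", index=False)
    clonal_size_distribution(clones, duplicate_map).to_csv(
        out / "clonal_sizes.tsv", sep="\t", index=False)
    return table


def write_group_average(tables: Sequence[pd.DataFrame],
                        out_dir: str | Path) -> pd.DataFrame:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    avg = average_percent(tables)
    avg.to_csv(out / "vj_group_average.tsv", sep="\t", index=False)
    return avg
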