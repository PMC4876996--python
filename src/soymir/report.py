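"""Library composition summaries, length distributions, and Venn analysis.

These reproduce, at whatever scale the input has, the standard overview
artifacts of a multi-library small-RNA study: a composition table (raw /
high-quality / clean reads, genome matching, exon/intron/intergenic
partition, precursor and mature miRNA matches, ncRNA classes, unknown), per
length histograms on unique and total scales, and the subset-membership
(Venn) partition of the combined unique sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .mapping import CategoryCounts
from .preprocess import CleanReadSet, StageCounts


def length_distribution(
    clean: CleanReadSet, min_len: int = 15, max_len: int = 30
) -> pd.DataFrame:
    """Per-length unique and total counts; index is insert length in nt."""
    idx = range(min_len, max_len + 1)
    unique = {L: 0 for L in idx}
    total = {L: 0 for L in idx}
    for seq, n in clean.counts.items():
        L = len(seq)
        if min_len <= L <= max_len:
            unique[L] += 1
            total[L] += n
    df = pd.DataFrame({"unique": unique, "total": total})
    df.index.name = "length_nt"
    return df


@dataclass
class VennSummary:
    """Subset-membership partition of the union of unique sequences."""

    membership: pd.DataFrame  # one row per non-empty library subset
    shared_unique_pct: float  # % of union uniques present in all libraries
    shared_total_pct: float  # % of summed counts carried by those sequences
    per_library_shared_total_pct: dict[str, float]


def venn(sets: Mapping[str, CleanReadSet]) -> VennSummary:
    """Exact subset partition over 2-4 libraries.

    The shared-by-all percentage on the unique scale divides by the union of
    unique sequences; on the total scale it divides the summed counts (over
    all libraries) of the shared sequences by the summed counts of all
    sequences.  A per-library variant (shared counts / library total) is also
    reported.
    """
    libs = list(sets)
    if not 2 <= len(libs) <= 4:
        raise ValueError("venn analysis needs 2-4 libraries")
    union: dict[str, int] = {}
    for lib in libs:
        for seq in sets[lib].counts:
            union[seq] = union.get(seq, 0) | (1 << libs.index(lib))

    subset_unique: dict[int, int] = {}
    subset_total: dict[int, int] = {}
    for seq, mask in union.items():
        subset_unique[mask] = subset_unique.get(mask, 0) + 1
        subset_total[mask] = subset_total.get(mask, 0) + sum(
            sets[lib].counts.get(seq, 0) for lib in libs
        )

    rows = []
    for r in range(1, len(libs) + 1):
        for combo in combinations(range(len(libs)), r):
            mask = sum(1 << i for i in combo)
            rows.append(
                {
                    "libraries": ",".join(libs[i] for i in combo),
                    "n_libraries": r,
                    "unique": subset_unique.get(mask, 0),
                    "total": subset_total.get(mask, 0),
                }
            )
    membership = pd.DataFrame(rows)

    full_mask = (1 << len(libs)) - 1
    n_union = len(union)
    shared_seqs = [s for s, m in union.items() if m == full_mask]
    all_counts = sum(st.total for st in sets.values())
    shared_counts = sum(
        sets[lib].counts.get(s, 0) for s in shared_seqs for lib in libs
    )
    per_library = {
        lib: 100.0
        * sum(sets[lib].counts.get(s, 0) for s in shared_seqs)
        / sets[lib].total
        if sets[lib].total
        else float("nan")
        for lib in libs
    }
    return VennSummary(
        membership=membership,
        shared_unique_pct=100.0 * len(shared_seqs) / n_union if n_union else 0.0,
        shared_total_pct=100.0 * shared_counts / all_counts if all_counts else 0.0,
        per_library_shared_total_pct=per_library,
    )


def composition_summary(
    stages: Mapping[str, StageCounts],
    category_counts: Mapping[str, CategoryCounts],
    mature_counts: Mapping[str, tuple[int, int]],  # lib -> (unique, total)
    precursor_read_counts: Mapping[str, tuple[int, int]],
    precursors_hit: Mapping[str, int],
    ncrna_removed: Mapping[str, pd.DataFrame],
    library_ids: Sequence[str],
) -> pd.DataFrame:
    """Composition table: one column pair (unique, total) per library.

    The bottom-row partition is clean = mature + ncRNA classes + unknown
    (mature matches take precedence over ncRNA classes in the subtraction
    order, so the three blocks are disjoint).
    """
    rows: dict[str, dict[str, object]] = {}

    def put(row: str, lib: str, unique, total) -> None:
        rows.setdefault(row, {})[f"{lib}_unique"] = unique
        rows.setdefault(row, {})[f"{lib}_total"] = total

    for lib in library_ids:
        st = stages[lib]
        cc = category_counts[lib]
        put("raw_reads", lib, None, st.raw)
        put("high_quality_reads", lib, None, st.high_quality)
        put("clean_reads_15_30nt", lib, st.clean_unique, st.clean_total)
        put("not_matching_genome", lib, cc.not_matching_unique, cc.not_matching_total)
        put("matching_genome", lib, cc.matching_unique, cc.matching_total)
        put("intergenic", lib, None, cc.intergenic_total)
        put("gene_transcripts", lib, None, cc.gene_total)
        put("exon", lib, None, cc.exon_total)
        put("intron", lib, None, cc.intron_total)
        pu, pt = precursor_read_counts[lib]
        put("matching_precursors", lib, pu, pt)
        put("corresponding_precursors", lib, precursors_hit[lib], None)
        mu, mt = mature_counts[lib]
        put("mature_mirnas", lib, mu, mt)
        removed = ncrna_removed[lib]
        put(
            "matching_ncrna",
            lib,
            int(removed["unique"].sum()),
            int(removed["total"].sum()),
        )
        for cls in removed.index:
            put(
                f"ncrna_{cls}",
                lib,
                int(removed.loc[cls, "unique"]),
                int(removed.loc[cls, "total"]),
            )
        unknown_total = st.clean_total - mt - int(removed["total"].sum())
        unknown_unique = st.clean_unique - mu - int(removed["unique"].sum())
        put("unknown_reads", lib, unknown_unique, unknown_total)

    df = pd.DataFrame(rows).T
    cols = [f"{lib}_{kind}" for lib in library_ids for kind in ("unique", "total")]
    return df[cols]
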