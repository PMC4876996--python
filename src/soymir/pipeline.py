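"""End-to-end orchestration: simulate -> preprocess -> map -> quantify ->
differential expression -> novel prediction -> reports.

``run_pipeline`` is deterministic given the configuration seed and writes
every stage product as TSV plus a machine-readable run manifest.  Each stage
can also be driven individually through the library API or the CLI.
"""

from __future__ import annotations

import json
import os
import sys
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .diffexpr import SignificanceParams, compare_libraries
from .mapping import (
    AnnotationSet,
    GenomeIndex,
    MappingResult,
    map_library,
    window_strand_ratio,
)
from .novel import (
    HairpinCandidate,
    MirCheckParams,
    candidates_table,
    find_candidates,
    pair_bidirectional,
    five_prime_composition,
)
from .preprocess import CleanReadSet, PreprocessParams, StageCounts, preprocess_fastq
from .quantify import (
    MiRNAReference,
    build_count_table,
    count_precursor_matches,
    filter_ncrna,
    matching_precursor_reads,
)
from .report import composition_summary, length_distribution, venn
from .simulate import SimConfig, SimulatedDataset, make_genome, write_dataset

DEFAULT_COMPARISONS = (("MON", "A32"), ("DP3", "JAC"), ("A32", "JAC"))


@dataclass
class PipelineResult:
    outdir: str
    clean_sets: dict[str, CleanReadSet]
    stages: dict[str, StageCounts]
    mapping: dict[str, MappingResult]
    count_table: pd.DataFrame
    totals: dict[str, int]
    comparisons: dict[str, pd.DataFrame]
    candidates: list[HairpinCandidate]
    bidirectional_pairs: list[tuple[HairpinCandidate, HairpinCandidate]]
    summary: pd.DataFrame
    venn_summary: object
    strand_ratio: tuple[int, int, float] | None
    dataset: SimulatedDataset | None = None


def _stage(msg: str, quiet: bool) -> None:
    if not quiet:
        print(f"[soymir] {msg}", file=sys.stderr)


def run_pipeline(
    config: SimConfig,
    outdir: str,
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS,
    sig_params: SignificanceParams | None = None,
    mircheck_params: MirCheckParams | None = None,
    write_outputs: bool = True,
    quiet: bool = False,
) -> PipelineResult:
    """Simulate a fourplex and run every downstream stage on it.

    ``comparisons`` lists (test, baseline) library pairs — the baseline plays
    the non-transgenic role (x, N1).  Raises at the first failing stage with
    the stage name in the message.
    """
    sig_params = sig_params or SignificanceParams()
    mircheck_params = mircheck_params or MirCheckParams()
    if write_outputs:
        os.makedirs(outdir, exist_ok=True)

    try:
        _stage("simulating dataset", quiet)
        dataset = make_genome(config)
        paths = write_dataset(dataset, outdir) if write_outputs else {}
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    pp_params = PreprocessParams(adapter=config.adapter,
                                 min_adapter_prefix=config.min_adapter_prefix)

    from .simulate import simulate_library, write_fastq  # local to avoid cycle

    clean_sets: dict[str, CleanReadSet] = {}
    stages: dict[str, StageCounts] = {}
    try:
        for lib in config.library_ids:
            _stage(f"preprocessing {lib}", quiet)
            if write_outputs:
                with open(paths[f"fastq:{lib}"]) as fh:
                    clean, st = preprocess_fastq(fh, pp_params, lib)
            else:
                import io

                buf = io.StringIO()
                write_fastq(simulate_library(dataset, lib, config), buf)
                buf.seek(0)
                clean, st = preprocess_fastq(buf, pp_params, lib)
            clean_sets[lib] = clean
            stages[lib] = st
    except Exception as exc:
        raise RuntimeError(f"stage preprocess failed: {exc}") from exc

    try:
        _stage("mapping", quiet)
        index = GenomeIndex(dataset.genome)
        annotation = AnnotationSet.from_gff3(
            paths["annotation"]
        ) if write_outputs else _annotation_from_text(dataset.gff3)
        mapping = {
            lib: map_library(clean_sets[lib], index, annotation)
            for lib in config.library_ids
        }
    except Exception as exc:
        raise RuntimeError(f"stage map failed: {exc}") from exc

    try:
        _stage("quantifying known miRNAs", quiet)
        known = {
            mid: rec
            for mid, rec in dataset.truth.mirnas.items()
            if rec.kind == "known"
        }
        ref = MiRNAReference(
            mature={mid: rec.mature for mid, rec in known.items()},
            precursors={
                mid.replace("miR", "MIR"): rec.precursor
                for mid, rec in known.items()
            },
        )
        count_table, totals = build_count_table(clean_sets, ref)
        mature_seqs = set(ref.seq_to_names)
        ncrna = {
            name: (cls, seq) for name, (cls, seq) in dataset.ncrna_fasta.items()
        }
        mature_counts = {}
        precursor_read_counts = {}
        precursors_hit_by_lib = {}
        ncrna_removed = {}
        unexplained_sets: dict[str, CleanReadSet] = {}
        for lib, clean in clean_sets.items():
            observed = [s for s in mature_seqs if s in clean.counts]
            mature_counts[lib] = (
                len(observed),
                sum(clean.counts[s] for s in observed),
            )
            precursor_read_counts[lib] = matching_precursor_reads(clean, ref)
            pc = count_precursor_matches(clean, ref)
            precursors_hit_by_lib[lib] = int((pc["total"] > 0).sum())
            nonmature = clean.subset(
                s for s in clean.counts if s not in mature_seqs
            )
            retained, removed = filter_ncrna(nonmature, ncrna)
            ncrna_removed[lib] = removed
            unexplained_sets[lib] = retained
    except Exception as exc:
        raise RuntimeError(f"stage quantify failed: {exc}") from exc

    try:
        _stage("differential expression", quiet)
        comparison_tables = {}
        for test, base in comparisons:
            comparison_tables[f"{test}_vs_{base}"] = compare_libraries(
                count_table, totals, test, base, sig_params
            )
    except Exception as exc:
        raise RuntimeError(f"stage diffexpr failed: {exc}") from exc

    try:
        _stage("novel miRNA prediction", quiet)
        unexplained: dict[str, dict[str, int]] = {}
        loci_all: dict[str, list] = {}
        for lib, retained in unexplained_sets.items():
            for seq, n in retained.counts.items():
                loci = mapping[lib].loci.get(seq)
                if not loci:
                    continue
                unexplained.setdefault(seq, {})[lib] = n
                loci_all.setdefault(seq, loci)
        candidates = find_candidates(
            unexplained,
            loci_all,
            dataset.genome,
            known_precursors=ref.precursors,
            params=mircheck_params,
        )
        pairs = pair_bidirectional(candidates)
    except Exception as exc:
        raise RuntimeError(f"stage novelmir failed: {exc}") from exc

    try:
        _stage("reports", quiet)
        summary = composition_summary(
            stages,
            {lib: mapping[lib].counts for lib in config.library_ids},
            mature_counts,
            precursor_read_counts,
            precursors_hit_by_lib,
            ncrna_removed,
            config.library_ids,
        )
        venn_summary = venn(clean_sets)
        strand_ratio = None
        if dataset.truth.rrna_unit:
            lib0 = config.library_ids[0]
            strand_ratio = window_strand_ratio(
                clean_sets[lib0],
                mapping[lib0].loci,
                (
                    dataset.truth.rrna_chrom,
                    dataset.truth.rrna_region[0],
                    dataset.truth.rrna_region[1],
                ),
                annotation,
            )
    except Exception as exc:
        raise RuntimeError(f"stage report failed: {exc}") from exc

    result = PipelineResult(
        outdir=outdir,
        clean_sets=clean_sets,
        stages=stages,
        mapping=mapping,
        count_table=count_table,
        totals=totals,
        comparisons=comparison_tables,
        candidates=candidates,
        bidirectional_pairs=pairs,
        summary=summary,
        venn_summary=venn_summary,
        strand_ratio=strand_ratio,
        dataset=dataset,
    )
    if write_outputs:
        _write_result_tables(result, config)
    return result


def _annotation_from_text(gff3_text: str):
    import io

    return AnnotationSet.from_gff3(io.StringIO(gff3_text))


def _write_result_tables(result: PipelineResult, config: SimConfig) -> None:
    out = result.outdir
    for lib, clean in result.clean_sets.items():
        with open(os.path.join(out, f"{lib}.clean.tsv"), "w") as fh:
            clean.to_tsv(fh)
        length_distribution(clean).to_csv(
            os.path.join(out, f"{lib}.lengths.tsv"), sep="\t"
        )
    result.count_table.to_csv(os.path.join(out, "mature_counts.tsv"), sep="\t")
    for name, table in result.comparisons.items():
        table.to_csv(os.path.join(out, f"diffexpr_{name}.tsv"), sep="\t")
        table[["norm_base", "norm_test"]].to_csv(
            os.path.join(out, f"scatter_{name}.tsv"), sep="\t"
        )
    candidates_table(result.candidates, config.library_ids).to_csv(
        os.path.join(out, "novel_candidates.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out, "novel_structures.txt"), "w") as fh:
        for cand in result.candidates:
            fh.write(
                f">{cand.locus_str} {cand.mature_rna}\n"
                f"{cand.precursor}\n{cand.fold.structure}\n"
            )
    result.summary.to_csv(os.path.join(out, "composition_summary.tsv"), sep="\t")
    result.venn_summary.membership.to_csv(
        os.path.join(out, "venn_membership.tsv"), sep="\t", index=False
    )
    if result.candidates:
        five_prime_composition(
            [c.mature for c in result.candidates]
        ).to_csv(os.path.join(out, "novel_5p_composition.tsv"), sep="\t")
    manifest = {
        "soymir_version": __version__,
        "seed": config.seed,
        "libraries": list(config.library_ids),
        "per_library_depth": config.per_library_depth,
        "count_mode": config.count_mode,
        "corruption_fraction": config.corruption_fraction,
        "shared_unique_pct": result.venn_summary.shared_unique_pct,
        "shared_total_pct": result.venn_summary.shared_total_pct,
        "n_novel_candidates": len(result.candidates),
        "n_bidirectional_pairs": len(result.bidirectional_pairs),
        "strand_ratio_window": result.strand_ratio,
    }
    with open(os.path.join(out, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
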