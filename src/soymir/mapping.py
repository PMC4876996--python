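"""Perfect-match genome mapping, annotation assignment and strand analysis.

Only exact full-length matches count (the published pipeline kept perfectly
matched reads only).  Mapping is exhaustive: every occurrence of the read on
the forward strand, and every position where the read's reverse complement
occurs (reported as a minus-strand locus on forward coordinates), is returned.
The index is a fixed-length seed table (default 12-mers, below the 15-nt
minimum query length) with full-length verification, so results equal a naive
scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .preprocess import CleanReadSet
from .seqs import DNA_ALPHABET, revcomp

CATEGORY_PRECEDENCE = {"exon": 0, "intron": 1, "intergenic": 2}


@dataclass(frozen=True, order=True)
class MatchLocus:
    """1-based inclusive interval on a named chromosome."""

    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad interval {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GenomeIndex:
    """Seed-and-verify exact-substring index over both strands.

    Stores only the forward chromosome sequences; minus-strand hits are found
    by locating the reverse complement of the query on the forward strand.
    Seeds containing 'N' are never indexed, so reads with 'N' cannot map.
    """

    def __init__(self, genome: Mapping[str, str], seed_len: int = 12):
        if not genome:
            raise ValueError("empty genome")
        self.seed_len = seed_len
        self.chromosomes = {name: seq.upper() for name, seq in genome.items()}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.chromosomes.items():
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i : i + seed_len]
                if "N" in kmer:
                    continue
                self._seeds.setdefault(kmer, []).append((name, i))

    def _forward_hits(self, query: str) -> list[tuple[str, int]]:
        k = self.seed_len
        hits = []
        for name, i in self._seeds.get(query[:k], ()):
            if self.chromosomes[name][i : i + len(query)] == query:
                hits.append((name, i))
        return hits

    def lookup(self, query: str) -> list[MatchLocus]:
        return map_read(query, self)


def build_index(genome: Mapping[str, str], seed_len: int = 12) -> GenomeIndex:
    return GenomeIndex(genome, seed_len=seed_len)


def map_read(sequence: str, index: GenomeIndex) -> list[MatchLocus]:
    """All perfect-match loci of ``sequence`` on both strands.

    Minus-strand loci are reported on forward coordinates.  A palindromic
    (reverse-complement-equal) sequence yields loci on both strands at the
    same interval.
    """
    seq = sequence.upper()
    if not set(seq) <= DNA_ALPHABET:
        return []
    if len(seq) < index.seed_len:
        raise ValueError(
            f"query ({len(seq)} nt) shorter than seed length {index.seed_len}"
        )
    loci = [
        MatchLocus(chrom, "+", i + 1, i + len(seq))
        for chrom, i in index._forward_hits(seq)
    ]
    rc = revcomp(seq)
    loci += [
        MatchLocus(chrom, "-", i + 1, i + len(seq))
        for chrom, i in index._forward_hits(rc)
    ]
    return sorted(loci)


# --------------------------------------------------------------------------
# annotation


def read_gff3(path_or_handle) -> pd.DataFrame:
    """Read a GFF3 file into a frame of (chrom, source, feature, start, end,
    strand, attributes).  Comment and directive lines are skipped."""
    df = pd.read_csv(
        path_or_handle,
        sep="\t",
        comment="#",
        header=None,
        names=[
            "chrom",
            "source",
            "feature",
            "start",
            "end",
            "score",
            "strand",
            "frame",
            "attributes",
        ],
        dtype={"chrom": str},
    )
    return df


class AnnotationSet:
    """Gene/exon intervals with derived introns and interval-overlap queries.

    Annotation strand is ignored for exon/intron/intergenic assignment (the
    composition table does not stratify these by strand); feature strand is
    kept for the strand-bias analysis.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, str, str]]):
        # intervals: (chrom, start, end, strand, feature in {gene, exon})
        self.genes: dict[str, IntervalTree] = {}
        self.exons: dict[str, IntervalTree] = {}
        self.gene_strands: dict[str, IntervalTree] = {}
        for chrom, start, end, strand, feature in intervals:
            if feature not in {"gene", "exon"}:
                continue
            tree = (self.genes if feature == "gene" else self.exons).setdefault(
                chrom, IntervalTree()
            )
            tree.addi(start, end + 1, strand)  # half-open internally
            if feature == "gene":
                self.gene_strands.setdefault(chrom, IntervalTree()).addi(
                    start, end + 1, strand
                )

    @classmethod
    def from_gff3(cls, path_or_handle) -> "AnnotationSet":
        df = read_gff3(path_or_handle)
        rows = df[df["feature"].isin(["gene", "exon"])]
        return cls(
            (r.chrom, int(r.start), int(r.end), r.strand, r.feature)
            for r in rows.itertuples()
        )

    def category_of_locus(self, locus: MatchLocus) -> str:
        """exon if the locus overlaps any exon, else intron if it overlaps a
        gene, else intergenic."""
        if locus.chrom not in self.genes and locus.chrom not in self.exons:
            raise KeyError(f"unknown chromosome {locus.chrom!r}")
        q = (locus.start, locus.end + 1)
        exons = self.exons.get(locus.chrom)
        if exons is not None and exons.overlap(*q):
            return "exon"
        genes = self.genes.get(locus.chrom)
        if genes is not None and genes.overlap(*q):
            return "intron"
        return "intergenic"

    def feature_strand(self, chrom: str, start: int, end: int) -> str | None:
        """Strand of an annotated gene overlapping the window, if any."""
        tree = self.gene_strands.get(chrom)
        if tree is None:
            return None
        hits = tree.overlap(start, end + 1)
        if not hits:
            return None
        return sorted(iv.data for iv in hits)[0]

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self.genes or chrom in self.exons


def assign_category(loci: list[MatchLocus], annotation: AnnotationSet) -> str:
    """Single category for a (possibly multi-mapped) read.

    Per-locus categories are combined with precedence exon > intron >
    intergenic so that every mapped read is counted once in the disjoint
    composition-table partition.
    """
    if not loci:
        raise ValueError("assign_category requires at least one locus")
    best = "intergenic"
    for locus in loci:
        cat = annotation.category_of_locus(locus)
        if CATEGORY_PRECEDENCE[cat] < CATEGORY_PRECEDENCE[best]:
            best = cat
        if best == "exon":
            break
    return best


# --------------------------------------------------------------------------
# per-library mapping summaries


@dataclass
class CategoryCounts:
    """Disjoint partition of a library's clean reads by genomic category."""

    library_id: str
    matching_total: int = 0
    matching_unique: int = 0
    not_matching_total: int = 0
    not_matching_unique: int = 0
    intergenic_total: int = 0
    gene_total: int = 0
    exon_total: int = 0
    intron_total: int = 0

    def validate(self) -> None:
        assert self.intergenic_total + self.gene_total == self.matching_total
        assert self.exon_total + self.intron_total == self.gene_total


@dataclass
class MappingResult:
    library_id: str
    loci: dict[str, list[MatchLocus]]  # only mapped sequences appear
    categories: dict[str, str]
    counts: CategoryCounts


def map_library(
    clean: CleanReadSet,
    index: GenomeIndex,
    annotation: AnnotationSet | None = None,
) -> MappingResult:
    """Map every unique clean sequence and tally the category partition."""
    loci_map: dict[str, list[MatchLocus]] = {}
    categories: dict[str, str] = {}
    counts = CategoryCounts(library_id=clean.library_id)
    for seq, n in clean.counts.items():
        loci = map_read(seq, index)
        if not loci:
            counts.not_matching_total += n
            counts.not_matching_unique += 1
            continue
        loci_map[seq] = loci
        counts.matching_total += n
        counts.matching_unique += 1
        if annotation is not None:
            cat = assign_category(loci, annotation)
            categories[seq] = cat
            if cat == "intergenic":
                counts.intergenic_total += n
            else:
                counts.gene_total += n
                if cat == "exon":
                    counts.exon_total += n
                else:
                    counts.intron_total += n
    return MappingResult(
        library_id=clean.library_id,
        loci=loci_map,
        categories=categories,
        counts=counts,
    )


def window_strand_ratio(
    clean: CleanReadSet,
    loci_map: Mapping[str, list[MatchLocus]],
    window: tuple[str, int, int],
    annotation: AnnotationSet | None = None,
) -> tuple[int, int, float]:
    """Sense/antisense read totals within a genomic window.

    Strand is taken relative to the annotated feature strand in the window;
    with no annotated feature the forward genome strand is the reference.  A
    read contributes its collapsed count once per strand on which it has at
    least one locus inside the window.  Returns (sense_total, antisense_total,
    antisense/sense ratio; NaN when the window is empty or one-sided-empty).
    """
    chrom, start, end = window
    if start > end:
        raise ValueError("invalid window")
    ref_strand = None
    if annotation is not None:
        ref_strand = annotation.feature_strand(chrom, start, end)
    if ref_strand is None:
        ref_strand = "+"
    sense = antisense = 0
    for seq, loci in loci_map.items():
        strands = {
            l.strand
            for l in loci
            if l.chrom == chrom and l.start <= end and l.end >= start
        }
        n = clean.counts.get(seq, 0)
        if ref_strand in strands:
            sense += n
        if ({"+", "-"} - {ref_strand}) & strands:
            antisense += n
    ratio = antisense / sense if sense else float("nan")
    return sense, antisense, ratio


def chromosomal_distribution(
    clean: CleanReadSet,
    loci_map: Mapping[str, list[MatchLocus]],
    bin_size: int = 1000,
) -> pd.DataFrame:
    """Binned per-chromosome, per-strand locus counts.

    A multi-locus read's collapsed count is split equally across its loci
    (assigned to the bin containing the locus start), so bin totals sum to the
    library's mapped total.
    """
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    rows: dict[tuple[str, int, str], float] = {}
    for seq, loci in loci_map.items():
        n = clean.counts.get(seq, 0) / len(loci)
        for locus in loci:
            b = (locus.start - 1) // bin_size * bin_size + 1
            key = (locus.chrom, b, locus.strand)
            rows[key] = rows.get(key, 0.0) + n
    df = pd.DataFrame(
        [(c, b, s, n) for (c, b, s), n in sorted(rows.items())],
        columns=["chrom", "bin_start", "strand", "count"],
    )
    return df
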