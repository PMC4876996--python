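"""Synthetic four-library soybean-seed small-RNA surrogate with planted truth.

The generator builds a miniature genome (a few ~30-kb chromosomes named in
GmNN style), an annotation with gene/exon models, a tandem ribosomal-RNA
repeat region that sources ~75% of every library's reads with a ~1:100
antisense:sense strand bias, planted known miRNA hairpins with
library-specific abundances (some differential), planted novel hairpin loci
(including one bidirectional sense/antisense pair and one conserved variant
of a known precursor), classified non-miRNA ncRNA genes, genomic "filler"
fragments, reads that match nothing, and corrupted reads that exercise the
preprocessing filters.  Every read source is recorded in a
:class:`PlantedTruth` so each downstream stage has a closed-loop oracle.

Libraries are keyed MON / A32 / DP3 / JAC after the four seed libraries the
pipeline emulates (two transgenic lines and their near-isogenic parents).
Each library's random stream is derived from (seed, library index), so a
single library can be regenerated independently and reproducibly.

``count_mode="exact"`` (default) emits each source exactly at its planted
count, making the downstream quantification recoverable bit-for-bit;
``count_mode="multinomial"`` resamples the composition multinomially for
sampling-noise studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .fold import fold_hairpin
from .mapping import MatchLocus
from .novel import mircheck
from .seqs import revcomp, to_rna

DEFAULT_LIBRARIES = ("MON", "A32", "DP3", "JAC")
# TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

# insert-length weights over 15..30 nt: 21-nt and 24-nt classes dominate,
# 24-mers broadest (seed small-RNA length profile)
_LENGTH_WEIGHTS = np.array(
    [1, 1, 2, 3, 5, 14, 40, 10, 8, 55, 12, 5, 3, 2, 1, 1], dtype=float
)
_LENGTHS = np.arange(15, 31)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _default_de_spec() -> tuple[tuple[str, str, float], ...]:
    """Planted differential-expression design.

    Fold changes multiply a miRNA's base abundance in one library: 4-fold
    shifts on abundant matures (the clearly callable cases) plus one 1.6-fold
    near-threshold case that the |log2| > 1 gate must leave uncalled.
    """
    return (
        ("gma-miR-s01", "MON", 0.25),
        ("gma-miR-s04", "MON", 0.25),
        ("gma-miR-s02", "A32", 4.0),
        ("gma-miR-s05", "DP3", 4.0),
        ("gma-miR-s06", "DP3", 0.25),
        ("gma-miR-s07", "MON", 1.6),
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic fourplex."""

    seed: int = 0
    library_ids: tuple[str, ...] = DEFAULT_LIBRARIES
    n_chromosomes: int = 3
    chrom_length: int = 30_000
    rrna_unit_length: int = 250
    rrna_copies: int = 12
    rrna_read_fraction: float = 0.75
    rrna_antisense_fraction: float = 0.01
    n_known_mirnas: int = 20
    n_novel_hairpins: int = 4  # distinct precursor loci (one bidirectional)
    per_library_depth: int = 100_000
    de_spec: tuple[tuple[str, str, float], ...] = field(
        default_factory=_default_de_spec
    )
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    corruption_fraction: float = 0.04
    unmatched_fraction: float = 0.11
    quality_error_profile: tuple[float, ...] = ()
    count_mode: str = "exact"  # or "multinomial"
    min_adapter_prefix: int = 7

    def __post_init__(self) -> None:
        for name in (
            "rrna_read_fraction",
            "rrna_antisense_fraction",
            "corruption_fraction",
            "unmatched_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.per_library_depth <= 0:
            raise ValueError("per_library_depth must be positive")
        for _mid, lib, fold in self.de_spec:
            if fold <= 0:
                raise ValueError("fold changes must be positive")
            if lib not in self.library_ids:
                raise ValueError(f"de_spec references unknown library {lib!r}")
        if self.count_mode not in {"exact", "multinomial"}:
            raise ValueError("count_mode must be 'exact' or 'multinomial'")
        if any(not 0 <= p <= 1 for p in self.quality_error_profile):
            raise ValueError("quality_error_profile entries must be in [0, 1]")

    @property
    def adapter_prefix(self) -> str:
        return self.adapter[: self.min_adapter_prefix]

    @classmethod
    def from_yaml(cls, handle) -> "SimConfig":
        raw = yaml.safe_load(handle) or {}
        if "de_spec" in raw:
            raw["de_spec"] = tuple(tuple(item) for item in raw["de_spec"])
        for key in ("library_ids", "quality_error_profile"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, handle) -> None:
        d = self.__dict__.copy()
        d["library_ids"] = list(d["library_ids"])
        d["quality_error_profile"] = list(d["quality_error_profile"])
        d["de_spec"] = [list(item) for item in d["de_spec"]]
        yaml.safe_dump(d, handle, sort_keys=False)


@dataclass
class MiRNARecord:
    """One planted hairpin (known or novel) with its genomic locus."""

    mirna_id: str
    kind: str  # "known" | "novel"
    mature: str  # DNA
    precursor: str  # DNA, as transcribed (5'->3' on the locus strand)
    locus: MatchLocus  # precursor locus, forward coordinates
    arm: str  # "5p" | "3p"
    arm_len: int
    n_mismatches: int
    names: tuple[str, ...] = ()
    conserved_from: str | None = None
    antisense_of: str | None = None  # partner id for a bidirectional pair

    @property
    def mature_rna(self) -> str:
        return to_rna(self.mature)


@dataclass
class PlantedTruth:
    """Ground truth for one simulated dataset."""

    config: SimConfig
    mirnas: dict[str, MiRNARecord]
    id_counts: dict[str, dict[str, int]]  # lib -> mirna_id -> clean count
    rrna_chrom: str
    rrna_region: tuple[int, int]  # 1-based inclusive
    rrna_unit: str
    rrna_counts: dict[str, tuple[int, int]]  # lib -> (sense, antisense)
    ncrna_genes: dict[str, tuple[str, str, MatchLocus]]  # name -> (class, seq, locus)
    ncrna_counts: dict[str, dict[str, int]]  # lib -> class -> count (non-rRNA)
    filler_counts: dict[str, dict[str, int]]  # lib -> category -> count
    unmatched_counts: dict[str, int]
    corrupted_counts: dict[str, int]
    clean_totals: dict[str, int]
    gene_models: list[tuple[str, int, int, str, list[tuple[int, int]]]]
    # (chrom, start, end, strand, [(exon_start, exon_end), ...])

    def seq_counts(self, library_id: str) -> dict[str, int]:
        """Planted clean count per distinct mature sequence (known + novel);
        identical matures registered under several ids are aggregated."""
        out: dict[str, int] = {}
        for mid, n in self.id_counts[library_id].items():
            seq = self.mirnas[mid].mature
            out[seq] = out.get(seq, 0) + n
        return out

    def known_seq_counts(self, library_id: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for mid, n in self.id_counts[library_id].items():
            rec = self.mirnas[mid]
            if rec.kind == "known":
                out[rec.mature] = out.get(rec.mature, 0) + n
        return out

    def category_of(self, chrom: str, start: int, end: int) -> str:
        """exon / intron / intergenic / rRNA-repeat for a genomic interval."""
        if chrom == self.rrna_chrom and not (
            end < self.rrna_region[0] or start > self.rrna_region[1]
        ):
            return "rRNA-repeat"
        for g_chrom, g_start, g_end, _strand, exons in self.gene_models:
            if g_chrom != chrom or end < g_start or start > g_end:
                continue
            for e_start, e_end in exons:
                if not (end < e_start or start > e_end):
                    return "exon"
            return "intron"
        return "intergenic"


@dataclass
class SimulatedDataset:
    genome: dict[str, str]
    gff3: str
    truth: PlantedTruth
    ncrna_fasta: dict[str, tuple[str, str]]  # name -> (class, seq)


# --------------------------------------------------------------------------
# helpers


def _rng_for(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=key))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _draw_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    p = _LENGTH_WEIGHTS / _LENGTH_WEIGHTS.sum()
    return rng.choice(_LENGTHS, size=n, p=p)


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Substitute n_mut distinct positions with a different base."""
    if n_mut == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_mut, replace=False):
        choices = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


class _ChromLayout:
    """Sequential feature placement on one chromosome with random gaps."""

    def __init__(self, rng: np.random.Generator, length: int, margin: int = 300):
        self.rng = rng
        self.length = length
        self.cursor = margin
        self.placed: list[tuple[int, int]] = []  # 0-based [start, end)

    def place(self, feat_len: int) -> int:
        gap = 150 + int(self.rng.integers(0, 200))
        start = self.cursor + gap
        if start + feat_len > self.length - 100:
            raise ValueError(
                f"planted features exceed chromosome length {self.length}"
            )
        self.cursor = start + feat_len
        self.placed.append((start, start + feat_len))
        return start


def _free_spans(layout: _ChromLayout, min_len: int = 80) -> list[tuple[int, int]]:
    """0-based half-open intervals untouched by any placed feature."""
    spans = []
    prev = 0
    for start, end in sorted(layout.placed):
        if start - prev >= min_len:
            spans.append((prev, start))
        prev = max(prev, end)
    if layout.length - prev >= min_len:
        spans.append((prev, layout.length))
    return spans


# --------------------------------------------------------------------------
# genome construction


def _build_hairpin(
    rng: np.random.Generator,
    mature: str,
    arm: str,
    left_pad: int,
    right_pad: int,
    loop_len: int,
    n_mismatches: int,
) -> tuple[str, int, int]:
    """Assemble precursor = arm5 + loop + arm3 around ``mature``.

    Returns (precursor, mature_offset0, arm_len); the mature sits on the
    requested arm, ``left_pad`` bases from the arm's outer end.  At least one
    substitution is always placed inside the mature's partner window (real
    miRNA/miRNA* duplexes are never perfect, and a perfect duplex would make
    the mature read map ambiguously to both strands of its own locus).
    """
    mature_arm = (
        _random_dna(rng, left_pad) + mature + _random_dna(rng, right_pad)
    )
    arm_len = len(mature_arm)
    comp = list(revcomp(mature_arm))
    # forced mismatch opposite an interior mature base
    i_mat = left_pad + 1 + int(rng.integers(max(1, len(mature) - 2)))
    j = arm_len - 1 - i_mat
    comp[j] = [b for b in "ACGT" if b != comp[j]][int(rng.integers(3))]
    other_arm = _mutate(rng, "".join(comp), max(0, n_mismatches - 1))
    loop = _random_dna(rng, loop_len)
    if arm == "5p":
        precursor = mature_arm + loop + other_arm
        offset0 = left_pad
    else:
        precursor = other_arm + loop + mature_arm
        offset0 = len(other_arm) + loop_len + left_pad
    return precursor, offset0, len(mature_arm)



def _hairpin_screens_ok(precursor: str, mature: str) -> bool:
    """True when the planted hairpin will survive the discovery screens:
    the mature occurs once-stranded (its reverse complement is absent) and
    the folded precursor passes the duplex criteria at its exact extent."""
    pos = precursor.find(mature)
    if pos < 0 or revcomp(mature) in precursor:
        return False
    ok, _reason = mircheck(fold_hairpin(precursor), pos + 1, pos + len(mature))
    return ok


def _insert_trims_cleanly(insert: str, adapter: str, prefix: str) -> bool:
    """True when the leftmost adapter-prefix match in insert+adapter sits
    exactly at the junction (matches straddling the junction would trim the
    insert short)."""
    return (insert + adapter).find(prefix) == len(insert)


def _random_mature(
    rng: np.random.Generator,
    length: int,
    forbidden: set[str],
    avoid: Sequence[str],
    adapter: str,
    adapter_prefix: str,
) -> str:
    """Random mature of the given length, 5' U or A, avoiding the adapter
    prefix, duplicates, and occurrence inside ``avoid`` sequences."""
    while True:
        seq = ("TA"[int(rng.integers(2))]) + _random_dna(rng, length - 1)
        if seq in forbidden or not _insert_trims_cleanly(seq, adapter, adapter_prefix):
            continue
        if any(seq in a or revcomp(seq) in a for a in avoid):
            continue
        return seq


def make_genome(config: SimConfig) -> SimulatedDataset:
    """Build genome FASTA content, GFF3 annotation and planted truth."""
    rng = _rng_for(config, 0)
    prefix = config.adapter_prefix
    chrom_names = [f"Gm{i + 1:02d}" for i in range(config.n_chromosomes)]

    # background
    genome = {name: bytearray(_random_dna(rng, config.chrom_length), "ascii")
              for name in chrom_names}
    layouts = {
        name: _ChromLayout(rng, config.chrom_length) for name in chrom_names
    }

    def paste(chrom: str, start0: int, seq: str) -> None:
        genome[chrom][start0 : start0 + len(seq)] = seq.encode()

    # --- rRNA tandem repeat on the last chromosome -------------------------
    rrna_chrom = chrom_names[-1]
    rrna_unit = ""
    rrna_region = (0, 0)
    if config.rrna_copies > 0:
        while True:
            rrna_unit = _random_dna(rng, config.rrna_unit_length)
            doubled = rrna_unit * 2
            if prefix not in doubled and prefix not in revcomp(doubled):
                break
        region_seq = rrna_unit * config.rrna_copies
        start0 = layouts[rrna_chrom].place(len(region_seq))
        paste(rrna_chrom, start0, region_seq)
        rrna_region = (start0 + 1, start0 + len(region_seq))

    # --- gene models (2 per chromosome, 3 exons each) ----------------------
    gene_models: list[tuple[str, int, int, str, list[tuple[int, int]]]] = []
    exon_len, intron_len = 250, 350
    for chrom in chrom_names:
        for g in range(2):
            span = 3 * exon_len + 2 * intron_len
            start0 = layouts[chrom].place(span)
            strand = "+" if (g % 2 == 0) else "-"
            exons = []
            pos = start0
            for _ in range(3):
                exons.append((pos + 1, pos + exon_len))
                pos += exon_len + intron_len
            gene_models.append((chrom, start0 + 1, start0 + span, strand, exons))

    # --- classified non-miRNA ncRNA genes ---------------------------------
    ncrna_specs = [("trna-1", "tRNA", 75), ("snoRNA-1", "snoRNA", 120),
                   ("snRNA-1", "other", 180)]
    ncrna_genes: dict[str, tuple[str, str, MatchLocus]] = {}
    for i, (name, cls, length) in enumerate(ncrna_specs):
        chrom = chrom_names[i % max(1, config.n_chromosomes - 1)]
        while True:
            seq = _random_dna(rng, length)
            if prefix not in seq and prefix not in revcomp(seq):
                break
        start0 = layouts[chrom].place(length)
        paste(chrom, start0, seq)
        ncrna_genes[name] = (
            cls,
            seq,
            MatchLocus(chrom, "+", start0 + 1, start0 + length),
        )

    avoid_for_mature = [rrna_unit * 2] + [s for _c, s, _l in ncrna_genes.values()]

    # --- known miRNA hairpins ----------------------------------------------
    mirnas: dict[str, MiRNARecord] = {}
    mature_set: set[str] = set()
    host_chroms = chrom_names[:-1] if config.n_chromosomes > 1 else chrom_names

    def plant_hairpin(
        mirna_id: str,
        kind: str,
        mature: str,
        arm: str,
        strand: str,
        chrom: str,
        names: tuple[str, ...],
        left_pad: int | None = None,
        right_pad: int | None = None,
        precursor_override: tuple[str, int, int] | None = None,
    ) -> MiRNARecord:
        if precursor_override is None:
            for _attempt in range(100):
                lp = left_pad if left_pad is not None else 8 + int(rng.integers(0, 5))
                rp = right_pad if right_pad is not None else 20 + int(rng.integers(0, 8))
                n_mm = int(rng.integers(0, 3))
                precursor, offset0, arm_len = _build_hairpin(
                    rng, mature, arm, lp, rp, 9 + int(rng.integers(0, 4)), n_mm
                )
                if _hairpin_screens_ok(precursor, mature):
                    break
            else:  # pragma: no cover - probabilistically unreachable
                raise RuntimeError(f"could not plant a clean hairpin for {mirna_id}")
        else:
            precursor, offset0, arm_len = precursor_override
            n_mm = 2
        start0 = layouts[chrom].place(len(precursor))
        segment = precursor if strand == "+" else revcomp(precursor)
        paste(chrom, start0, segment)
        rec = MiRNARecord(
            mirna_id=mirna_id,
            kind=kind,
            mature=mature,
            precursor=precursor,
            locus=MatchLocus(chrom, strand, start0 + 1, start0 + len(precursor)),
            arm=arm,
            arm_len=arm_len,
            n_mismatches=n_mm,
            names=names,
        )
        mirnas[mirna_id] = rec
        mature_set.add(mature)
        return rec

    shared_seq: str | None = None
    for i in range(config.n_known_mirnas):
        mid = f"gma-miR-s{i + 1:02d}"
        if i == 2 and shared_seq is not None:
            mature = shared_seq  # s03 shares s02's mature (family aggregation)
        else:
            length = int(rng.choice([20, 21, 21, 22, 24, 24]))
            mature = _random_mature(rng, length, mature_set, avoid_for_mature, config.adapter, prefix)
        if i == 1:
            shared_seq = mature
        arm = "3p" if i % 4 == 3 else "5p"
        strand = "-" if i % 5 == 4 else "+"
        chrom = host_chroms[i % len(host_chroms)]
        plant_hairpin(mid, "known", mature, arm, strand, chrom, names=(mid,))

    # --- novel hairpins -----------------------------------------------------
    # N1: bidirectional locus — a second mature transcribed from the minus
    # strand of the same hairpin interval.
    m2 = None
    for _attempt in range(100):
        m1 = _random_mature(rng, 21, mature_set, avoid_for_mature, config.adapter, prefix)
        pre1, off1, arm_len1 = _build_hairpin(
            rng, m1, "5p", 8, 36, 10, n_mismatches=2
        )
        if not _hairpin_screens_ok(pre1, m1):
            continue
        pre1_rc_try = revcomp(pre1)
        # near the outer end of the antisense 5' arm, so both hairpins of the
        # pair trim to almost the same genomic interval
        for pos in range(2, 9):
            cand = pre1_rc_try[pos : pos + 24]
            if (
                cand[0] in "TA"
                and cand not in mature_set
                and cand != m1
                and _insert_trims_cleanly(cand, config.adapter, prefix)
                and _hairpin_screens_ok(pre1_rc_try, cand)
            ):
                m2 = (cand, pos)
                break
        if m2 is not None:
            break
    n1_chrom = host_chroms[0]
    start0 = layouts[n1_chrom].place(len(pre1))
    paste(n1_chrom, start0, pre1)
    rec_n1a = MiRNARecord(
        "gma-miR-N1a", "novel", m1, pre1,
        MatchLocus(n1_chrom, "+", start0 + 1, start0 + len(pre1)),
        arm="5p", arm_len=arm_len1, n_mismatches=2, names=("gma-miR-N1a",),
        antisense_of="gma-miR-N1b",
    )
    mirnas[rec_n1a.mirna_id] = rec_n1a
    mature_set.add(m1)
    # the 24-nt antisense mature sits on the 5' arm of the reverse-complement
    # hairpin, clear of m1's duplex region (selected during the retry above)
    pre1_rc = revcomp(pre1)
    assert m2 is not None, "bidirectional antisense mature placement failed"
    rec_n1b = MiRNARecord(
        "gma-miR-N1b", "novel", m2[0], pre1_rc,
        MatchLocus(n1_chrom, "-", start0 + 1, start0 + len(pre1)),
        arm="5p", arm_len=arm_len1, n_mismatches=2, names=("gma-miR-N1b",),
        antisense_of="gma-miR-N1a",
    )
    mirnas[rec_n1b.mirna_id] = rec_n1b
    mature_set.add(m2[0])

    # N2: one mature planted at two loci (same precursor sequence twice)
    for _attempt in range(100):
        m3 = _random_mature(
            rng, 24, mature_set, avoid_for_mature, config.adapter, prefix
        )
        pre2, off2, arm_len2 = _build_hairpin(rng, m3, "5p", 10, 24, 11, 1)
        if _hairpin_screens_ok(pre2, m3):
            break
    for tag, chrom in (("a", host_chroms[0]), ("b", host_chroms[-1])):
        start0 = layouts[chrom].place(len(pre2))
        paste(chrom, start0, pre2)
        mirnas[f"gma-miR-N2{tag}"] = MiRNARecord(
            f"gma-miR-N2{tag}", "novel", m3, pre2,
            MatchLocus(chrom, "+", start0 + 1, start0 + len(pre2)),
            arm="5p", arm_len=arm_len2, n_mismatches=1,
            names=(f"gma-miR-N2{tag}",),
        )
    mature_set.add(m3)

    # N3: conserved novel — compensatory mutations of the first known hairpin
    # (structure preserved, ungapped identity kept >= 80%) with a new mature.
    template = mirnas["gma-miR-s01"]
    t_arm = template.arm_len
    t_loop = len(template.precursor) - 2 * t_arm
    for _attempt in range(100):
        arm5 = list(template.precursor[:t_arm])
        arm3 = list(template.precursor[t_arm + t_loop :])
        n_sub = max(1, int(round(0.06 * t_arm)))
        for pos in rng.choice(t_arm, size=n_sub, replace=False):
            new = [b for b in "ACGT" if b != arm5[pos]][int(rng.integers(3))]
            arm5[int(pos)] = new
            arm3[t_arm - 1 - int(pos)] = revcomp(new)
        loop = _random_dna(rng, t_loop)
        pre3 = "".join(arm5) + loop + "".join(arm3)
        m4_off = 2
        for off in range(2, max(3, t_arm - 22)):
            cand22 = pre3[off : off + 22]
            if (
                _insert_trims_cleanly(cand22, config.adapter, prefix)
                and cand22 not in mature_set
            ):
                m4_off = off
                break
        m4 = pre3[m4_off : m4_off + 22]
        if m4[0] not in "TA":
            arm5[m4_off] = "T"
            arm3[t_arm - 1 - m4_off] = "A"
            pre3 = "".join(arm5) + loop + "".join(arm3)
            m4 = pre3[m4_off : m4_off + 22]
        if revcomp(m4) in pre3:
            # break a perfect mature/star duplex inherited from the template
            # so the mature maps to one strand only
            j = t_arm - 1 - (m4_off + 10)
            arm3[j] = [b for b in "ACGT" if b != arm3[j]][1]
            pre3 = "".join(arm5) + loop + "".join(arm3)
            m4 = pre3[m4_off : m4_off + 22]
        identity = sum(a == b for a, b in zip(pre3, template.precursor)) / len(
            pre3
        )
        if (
            identity >= 0.80
            and m4 not in mature_set
            and _insert_trims_cleanly(m4, config.adapter, prefix)
            and _hairpin_screens_ok(pre3, m4)
        ):
            break
    else:  # pragma: no cover - probabilistically unreachable
        raise RuntimeError("could not derive a conserved novel hairpin")
    chrom = host_chroms[1 % len(host_chroms)]
    start0 = layouts[chrom].place(len(pre3))
    paste(chrom, start0, pre3)
    mirnas["gma-miR-N3"] = MiRNARecord(
        "gma-miR-N3", "novel", m4, pre3,
        MatchLocus(chrom, "+", start0 + 1, start0 + len(pre3)),
        arm="5p", arm_len=t_arm, n_mismatches=template.n_mismatches,
        names=("gma-miR-N3",), conserved_from="gma-MIR-s01",
    )
    mature_set.add(m4)

    # N4: plain novel hairpin on the minus strand
    m5 = _random_mature(rng, 24, mature_set, avoid_for_mature, config.adapter, prefix)
    rec_n4 = plant_hairpin(
        "gma-miR-N4", "novel", m5, "5p", "-", host_chroms[-1],
        names=("gma-miR-N4",), left_pad=9, right_pad=22,
    )

    genome_str = {name: bytes(seq).decode() for name, seq in genome.items()}

    # --- planted counts -----------------------------------------------------
    truth = _assign_counts(
        config, mirnas, rrna_chrom, rrna_region, rrna_unit, ncrna_genes,
        gene_models,
    )

    gff3 = _render_gff3(gene_models)
    ncrna_fasta = {name: (cls, seq) for name, (cls, seq, _l) in ncrna_genes.items()}
    # the rRNA repeat unit is a classified record too (doubled to cover reads
    # spanning unit junctions)
    if rrna_unit:
        ncrna_fasta["rRNA-repeat-unit"] = ("rRNA", rrna_unit * 2)
    return SimulatedDataset(
        genome=genome_str, gff3=gff3, truth=truth, ncrna_fasta=ncrna_fasta
    )


# per-1e5-depth planted clean counts of the novel matures (by id)
_NOVEL_BASE = {
    "gma-miR-N1a": {"MON": 3, "A32": 5, "DP3": 0, "JAC": 2},
    "gma-miR-N1b": {"MON": 1, "A32": 1, "DP3": 10, "JAC": 1},
    "gma-miR-N2a": {"MON": 4, "A32": 2, "DP3": 5, "JAC": 14},
    "gma-miR-N3": {"MON": 18, "A32": 8, "DP3": 9, "JAC": 7},
    "gma-miR-N4": {"MON": 1, "A32": 3, "DP3": 0, "JAC": 1},
}


def known_base_abundance(i: int) -> int:
    """Base clean count (per 1e5 depth) of the i-th known mature."""
    return int(round(2500 * 0.65**i)) + 10


def _assign_counts(
    config: SimConfig,
    mirnas: Mapping[str, MiRNARecord],
    rrna_chrom: str,
    rrna_region: tuple[int, int],
    rrna_unit: str,
    ncrna_genes,
    gene_models,
) -> PlantedTruth:
    depth = config.per_library_depth
    scale = depth / 100_000
    fold = {
        (mid, lib): f for mid, lib, f in config.de_spec
    }
    id_counts: dict[str, dict[str, int]] = {}
    rrna_counts: dict[str, tuple[int, int]] = {}
    ncrna_counts: dict[str, dict[str, int]] = {}
    filler_counts: dict[str, dict[str, int]] = {}
    unmatched_counts: dict[str, int] = {}
    corrupted_counts: dict[str, int] = {}
    clean_totals: dict[str, int] = {}

    known_ids = sorted(
        (mid for mid, r in mirnas.items() if r.kind == "known"),
    )
    for lib in config.library_ids:
        corrupted = int(round(config.corruption_fraction * depth))
        clean_target = depth - corrupted
        counts: dict[str, int] = {}
        # known matures: s03 shares s02's sequence and carries no abundance of
        # its own (one statistical unit per distinct sequence)
        for i, mid in enumerate(known_ids):
            if i == 2 and mirnas[mid].mature == mirnas[known_ids[1]].mature:
                counts[mid] = 0
                continue
            base = known_base_abundance(i)
            counts[mid] = int(round(base * fold.get((mid, lib), 1.0) * scale))
        for mid, per_lib in _NOVEL_BASE.items():
            if mid in mirnas:
                base = per_lib.get(lib, 1)
                counts[mid] = max(
                    int(round(base * scale)), 1 if base > 0 else 0
                )
        # same mature at two loci (N2a/N2b): abundance belongs to the
        # sequence; record it once under N2a
        if "gma-miR-N2b" in mirnas:
            counts["gma-miR-N2b"] = 0
        id_counts[lib] = counts

        n_rrna = int(round(config.rrna_read_fraction * clean_target)) if rrna_unit else 0
        n_anti = int(round(config.rrna_antisense_fraction * n_rrna))
        rrna_counts[lib] = (n_rrna - n_anti, n_anti)
        nc = {
            "tRNA": int(round(1000 * scale)),
            "snoRNA": int(round(400 * scale)),
            "other": int(round(400 * scale)),
        }
        ncrna_counts[lib] = nc
        n_unmatched = int(round(config.unmatched_fraction * clean_target))
        used = (
            sum(counts.values()) + n_rrna + sum(nc.values()) + n_unmatched
        )
        remainder = clean_target - used
        if remainder < 0:
            # at very small depths the fixed-count sources can crowd out the
            # genome-absent reads; shrink those first before giving up
            adjust = min(n_unmatched, -remainder)
            n_unmatched -= adjust
            remainder += adjust
        if remainder < 0:
            raise ValueError(
                "per-library composition exceeds depth; increase "
                "per_library_depth or reduce source fractions"
            )
        n_exon = int(round(0.35 * remainder))
        n_intron = int(round(0.25 * remainder))
        filler_counts[lib] = {
            "exon": n_exon,
            "intron": n_intron,
            "intergenic": remainder - n_exon - n_intron,
        }
        unmatched_counts[lib] = n_unmatched
        corrupted_counts[lib] = corrupted
        clean_totals[lib] = clean_target

    return PlantedTruth(
        config=config,
        mirnas=dict(mirnas),
        id_counts=id_counts,
        rrna_chrom=rrna_chrom,
        rrna_region=rrna_region,
        rrna_unit=rrna_unit,
        rrna_counts=rrna_counts,
        ncrna_genes=dict(ncrna_genes),
        ncrna_counts=ncrna_counts,
        filler_counts=filler_counts,
        unmatched_counts=unmatched_counts,
        corrupted_counts=corrupted_counts,
        clean_totals=clean_totals,
        gene_models=list(gene_models),
    )


def _render_gff3(gene_models) -> str:
    lines = ["##gff-version 3"]
    for gi, (chrom, start, end, strand, exons) in enumerate(gene_models, 1):
        gid = f"gene{gi:02d}"
        lines.append(
            f"{chrom}\tsoymir\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}"
        )
        for ei, (e_start, e_end) in enumerate(exons, 1):
            lines.append(
                f"{chrom}\tsoymir\texon\t{e_start}\t{e_end}\t.\t{strand}\t.\t"
                f"ID={gid}.e{ei};Parent={gid}"
            )
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# library simulation


def simulate_library(
    dataset: SimulatedDataset,
    library_id: str,
    config: SimConfig | None = None,
) -> list[tuple[str, str, str]]:
    """FASTQ records (id, sequence, quality) for one library.

    Reads are insert + 3' adapter, padded with random bases to the fixed read
    length and truncated there; qualities are Phred+33.  In ``exact`` count
    mode each planted source contributes exactly its truth count; in
    ``multinomial`` mode the composition is resampled with those counts as
    weights.  A ``corruption_fraction`` of reads is corrupted (no adapter,
    too many low-quality bases, or an 'N' in the insert) to exercise the
    preprocessing filters.
    """
    config = config or dataset.truth.config
    truth = dataset.truth
    if library_id not in config.library_ids:
        raise KeyError(f"unknown library_id {library_id!r}")
    lib_index = config.library_ids.index(library_id)
    rng = _rng_for(config, 1, lib_index)
    prefix = config.adapter_prefix
    adapter_seq = config.adapter

    inserts: list[str] = []
    # planted matures
    for mid, n in sorted(truth.id_counts[library_id].items()):
        if n:
            inserts.extend([truth.mirnas[mid].mature] * n)
    # rRNA repeat fragments with strand bias
    n_sense, n_anti = truth.rrna_counts[library_id]
    if n_sense or n_anti:
        region = truth.rrna_unit * config.rrna_copies
        for count, anti in ((n_sense, False), (n_anti, True)):
            produced = 0
            while produced < count:
                L = int(_draw_lengths(rng, 1)[0])
                s = int(rng.integers(0, len(region) - L + 1))
                frag = region[s : s + L]
                if anti:
                    frag = revcomp(frag)
                if not _insert_trims_cleanly(frag, adapter_seq, prefix):
                    continue
                inserts.append(frag)
                produced += 1
    # non-miRNA ncRNA fragments
    class_seqs: dict[str, list[str]] = {}
    for name, (cls, seq, _locus) in truth.ncrna_genes.items():
        class_seqs.setdefault(cls, []).append(seq)
    for cls, n in sorted(truth.ncrna_counts[library_id].items()):
        seqs = class_seqs.get(cls, [])
        if not seqs or n == 0:
            continue
        lengths = _draw_lengths(rng, n)
        for L in lengths:
            while True:
                source = seqs[int(rng.integers(len(seqs)))]
                Lc = min(int(L), len(source))
                s = int(rng.integers(0, len(source) - Lc + 1))
                frag = source[s : s + Lc]
                if _insert_trims_cleanly(frag, adapter_seq, prefix):
                    inserts.append(frag)
                    break
    # genomic filler by category
    inserts.extend(_filler_inserts(rng, dataset, library_id))
    # reads matching nothing in the genome
    inserts.extend(
        _unmatched_inserts(
            rng, dataset, truth.unmatched_counts[library_id], adapter_seq, prefix
        )
    )

    if config.count_mode == "multinomial":
        idx = rng.choice(len(inserts), size=len(inserts), replace=True)
        inserts = [inserts[i] for i in idx]

    adapter = config.adapter
    read_len = config.read_length
    records: list[tuple[str, str]] = []
    for ins in inserts:
        read = ins + adapter
        if len(read) < read_len:
            read += _random_dna(rng, read_len - len(read))
        records.append((read[:read_len], "clean"))

    # corrupted reads
    n_corrupt = truth.corrupted_counts[library_id]
    kinds = ["noadapter", "lowqual", "ncontain"]
    for i in range(n_corrupt):
        kind = kinds[i % 3]
        if kind == "noadapter":
            while True:
                seq = _random_dna(rng, read_len)
                if prefix not in seq:
                    break
            records.append((seq, "noadapter"))
        elif kind == "lowqual":
            ins = _random_dna(rng, 21)
            seq = (ins + adapter + _random_dna(rng, read_len))[:read_len]
            records.append((seq, "lowqual"))
        else:
            while True:
                ins = _random_dna(rng, 21)
                if _insert_trims_cleanly(ins, adapter, prefix):
                    break
            ins = list(ins)
            ins[int(rng.integers(len(ins)))] = "N"
            seq = ("".join(ins) + adapter + _random_dna(rng, read_len))[:read_len]
            records.append((seq, "ncontain"))

    order = rng.permutation(len(records))
    out: list[tuple[str, str, str]] = []
    profile = config.quality_error_profile
    for rank, idx in enumerate(order):
        seq, kind = records[int(idx)]
        qual = ["I"] * len(seq)  # Phred 40
        if kind == "lowqual":
            for pos in rng.choice(len(seq), size=5, replace=False):
                qual[int(pos)] = "+"  # Phred 10
        elif profile:
            for pos, p in enumerate(profile[: len(seq)]):
                if p and rng.random() < p:
                    qual[pos] = "+"
        out.append((f"{library_id}_{rank:07d}", seq, "".join(qual)))
    return out


def _filler_inserts(
    rng: np.random.Generator, dataset: SimulatedDataset, library_id: str
) -> list[str]:
    truth = dataset.truth
    config = truth.config
    prefix = config.adapter_prefix
    matures = {r.mature for r in truth.mirnas.values()}
    ncrna_seqs = [s for _c, s in dataset.ncrna_fasta.values()]

    exon_ivs: list[tuple[str, int, int]] = []
    intron_ivs: list[tuple[str, int, int]] = []
    for chrom, g_start, g_end, _strand, exons in truth.gene_models:
        prev_end = None
        for e_start, e_end in exons:
            exon_ivs.append((chrom, e_start, e_end))
            if prev_end is not None:
                intron_ivs.append((chrom, prev_end + 1, e_start - 1))
            prev_end = e_end
    intergenic_ivs = _intergenic_spans(dataset)

    out: list[str] = []
    for category, ivs in (
        ("exon", exon_ivs),
        ("intron", intron_ivs),
        ("intergenic", intergenic_ivs),
    ):
        n = truth.filler_counts[library_id][category]
        produced = 0
        while produced < n:
            chrom, start, end = ivs[int(rng.integers(len(ivs)))]
            L = int(_draw_lengths(rng, 1)[0])
            if end - start + 1 < L:
                continue
            s = int(rng.integers(start, end - L + 2))
            frag = dataset.genome[chrom][s - 1 : s - 1 + L]
            if not _insert_trims_cleanly(frag, config.adapter, prefix) or frag in matures:
                continue
            rc = revcomp(frag)
            if any(frag in ref or rc in ref for ref in ncrna_seqs):
                continue
            out.append(frag)
            produced += 1
    return out


def _intergenic_spans(dataset: SimulatedDataset) -> list[tuple[str, int, int]]:
    """1-based inclusive spans free of genes, hairpins, ncRNA genes and the
    rRNA repeat, shrunk so any 15-30-nt fragment inside stays clear."""
    truth = dataset.truth
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in dataset.genome}
    for chrom, g_start, g_end, _s, _e in truth.gene_models:
        occupied[chrom].append((g_start, g_end))
    for rec in truth.mirnas.values():
        occupied[rec.locus.chrom].append((rec.locus.start, rec.locus.end))
    for _cls, _seq, locus in truth.ncrna_genes.values():
        occupied[locus.chrom].append((locus.start, locus.end))
    if truth.rrna_unit:
        occupied[truth.rrna_chrom].append(truth.rrna_region)
    spans = []
    pad = 35
    for chrom, ivs in occupied.items():
        length = len(dataset.genome[chrom])
        prev = 1
        for start, end in sorted(ivs):
            if start - pad - prev >= 100:
                spans.append((chrom, prev + pad, start - pad))
            prev = max(prev, end)
        if length - pad - prev >= 100:
            spans.append((chrom, prev + pad, length - pad))
    return spans


def _unmatched_inserts(
    rng: np.random.Generator,
    dataset: SimulatedDataset,
    n: int,
    adapter: str,
    prefix: str,
) -> list[str]:
    haystack = "N".join(dataset.genome.values())
    haystack = haystack + "N" + revcomp(haystack)
    out: list[str] = []
    lengths = _draw_lengths(rng, n)
    for L in lengths:
        while True:
            seq = _random_dna(rng, int(L))
            if not _insert_trims_cleanly(seq, adapter, prefix):
                continue
            if seq in haystack:
                continue
            out.append(seq)
            break
    return out


# --------------------------------------------------------------------------
# file output


def write_fasta(sequences: Mapping[str, str], handle, width: int = 70) -> None:
    for name, seq in sequences.items():
        handle.write(f">{name}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i : i + width] + "\n")


def write_fastq(records: Iterable[tuple[str, str, str]], handle) -> None:
    for rid, seq, qual in records:
        handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, str]:
    """Write genome/annotation/references/libraries/truth; returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    truth = dataset.truth
    config = truth.config
    paths: dict[str, str] = {}

    p = os.path.join(outdir, "genome.fa")
    with open(p, "w") as fh:
        write_fasta(dataset.genome, fh)
    paths["genome"] = p

    p = os.path.join(outdir, "annotation.gff3")
    with open(p, "w") as fh:
        fh.write(dataset.gff3)
    paths["annotation"] = p

    known = {
        mid: rec for mid, rec in truth.mirnas.items() if rec.kind == "known"
    }
    p = os.path.join(outdir, "mature.fa")
    with open(p, "w") as fh:
        write_fasta({mid: to_rna(rec.mature) for mid, rec in known.items()}, fh)
    paths["mature"] = p

    p = os.path.join(outdir, "precursors.fa")
    with open(p, "w") as fh:
        write_fasta(
            {
                mid.replace("miR", "MIR"): to_rna(rec.precursor)
                for mid, rec in known.items()
            },
            fh,
        )
    paths["precursors"] = p

    p = os.path.join(outdir, "ncrna.fa")
    with open(p, "w") as fh:
        for name, (cls, seq) in dataset.ncrna_fasta.items():
            fh.write(f">{name} class={cls}\n{seq}\n")
    paths["ncrna"] = p

    for lib in config.library_ids:
        records = simulate_library(dataset, lib, config)
        p = os.path.join(outdir, f"{lib}.fastq")
        with open(p, "w") as fh:
            write_fastq(records, fh)
        paths[f"fastq:{lib}"] = p

    p = os.path.join(outdir, "truth_counts.tsv")
    with open(p, "w") as fh:
        libs = list(config.library_ids)
        fh.write("mirna_id\tkind\tmature\tlocus\t" + "\t".join(libs) + "\n")
        for mid, rec in sorted(truth.mirnas.items()):
            counts = "\t".join(str(truth.id_counts[lib][mid]) for lib in libs)
            locus = (
                f"{rec.locus.chrom}_{rec.locus.strand}_"
                f"{rec.locus.start}_{rec.locus.end}"
            )
            fh.write(f"{mid}\t{rec.kind}\t{rec.mature}\t{locus}\t{counts}\n")
    paths["truth"] = p

    p = os.path.join(outdir, "sim_config.yaml")
    with open(p, "w") as fh:
        config.to_yaml(fh)
    paths["config"] = p
    return paths
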