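"""Novel miRNA candidate discovery from unexplained mapped reads.

A read that survives preprocessing, maps perfectly to the genome, and is
neither a known mature miRNA nor a known non-coding RNA fragment can seed a
candidate.  For each of its loci two genomic windows are cut (the read at the
5' end with a downstream flank, and at the 3' end with an upstream flank),
folded by base-pair maximization, and screened with plant-miRNA hairpin
criteria (mature on a single arm outside the terminal loop, few unpaired
mature bases in the miRNA/miRNA* duplex, small bulge asymmetry, a minimum
hairpin span).  Candidates are then annotated for conservation against known
precursors (ungapped identity) and paired across strands to detect
bidirectional loci.  Star-strand read evidence is not required (the
double-strand testing step is omitted, matching the published procedure);
the miRNA* is inferred from the fold with the canonical 2-nt 3' overhang.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .fold import FoldResult, fold_hairpin
from .mapping import MatchLocus
from .seqs import revcomp, to_rna

_LOCUS_RE = re.compile(r"^(?P<chrom>[^_]+)_(?P<strand>[+-])_(?P<start>\d+)_(?P<end>\d+)$")


@dataclass
class MirCheckParams:
    """Plant-miRNA hairpin acceptance thresholds.

    Defaults follow the canonical plant criteria: a 20-24-nt mature with at
    most 4 unpaired bases in the duplex, at most 2 nt of asymmetric bulge,
    and a hairpin of at least 60 nt.
    """

    mature_len: tuple[int, int] = (20, 24)
    max_unpaired_mature: int = 4
    max_bulge_asymmetry: int = 2
    min_hairpin_len: int = 60
    min_paired_in_duplex: int = 14
    require_mature_one_arm: bool = True

    def __post_init__(self) -> None:
        if min(
            self.mature_len[0],
            self.max_unpaired_mature,
            self.max_bulge_asymmetry,
            self.min_hairpin_len,
            self.min_paired_in_duplex,
        ) < 0:
            raise ValueError("all thresholds must be non-negative")


@dataclass
class HairpinCandidate:
    """A mature read plus the folded precursor window that passed screening."""

    mature: str  # DNA
    arm: str  # "5p" | "3p"
    precursor: str  # DNA, trimmed to the hairpin extent
    fold: FoldResult
    locus: MatchLocus  # trimmed precursor locus (forward coordinates)
    counts: dict[str, int] = field(default_factory=dict)
    conserved_to: str | None = None

    @property
    def mature_rna(self) -> str:
        return to_rna(self.mature)

    @property
    def locus_str(self) -> str:
        return locus_string(
            self.locus.chrom, self.locus.strand, self.locus.start, self.locus.end
        )

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def locus_string(chrom: str, strand: str, start: int, end: int) -> str:
    """Precursor-location string, 1-based inclusive: Gm02_+_39925524_39925657."""
    MatchLocus(chrom, strand, start, end)  # validate
    return f"{chrom}_{strand}_{start}_{end}"


def parse_locus_string(s: str) -> MatchLocus:
    m = _LOCUS_RE.match(s)
    if not m:
        raise ValueError(f"malformed locus string {s!r}")
    return MatchLocus(
        m["chrom"], m["strand"], int(m["start"]), int(m["end"])
    )


def candidate_windows(
    locus: MatchLocus, genome: Mapping[str, str], flank: int = 200
) -> list[tuple[str, MatchLocus]]:
    """Two precursor windows around a mature locus.

    One window extends downstream of the read (read on the 5' side), one
    upstream (read on the 3' side), both truncated at chromosome edges.
    Minus-strand loci yield reverse-complemented window sequences, so the
    returned sequence is always the transcribed orientation with the mature
    on the expected side.
    """
    chrom_seq = genome[locus.chrom]
    n = len(chrom_seq)
    out = []
    if locus.strand == "+":
        spans = [
            (locus.start, min(n, locus.end + flank)),  # mature at 5' end
            (max(1, locus.start - flank), locus.end),  # mature at 3' end
        ]
    else:
        # transcribed 5'->3' on the minus strand: downstream = smaller coords
        spans = [
            (max(1, locus.start - flank), locus.end),
            (locus.start, min(n, locus.end + flank)),
        ]
    for start, end in spans:
        seq = chrom_seq[start - 1 : end]
        if locus.strand == "-":
            seq = revcomp(seq)
        out.append((seq, MatchLocus(locus.chrom, locus.strand, start, end)))
    return out


def _mature_position_in_window(
    window_seq: str, mature: str
) -> tuple[int, int] | None:
    pos = window_seq.find(mature)
    if pos < 0:
        return None
    return pos + 1, pos + len(mature)  # 1-based inclusive


def mircheck(
    fold: FoldResult,
    mature_start: int,
    mature_end: int,
    params: MirCheckParams | None = None,
) -> tuple[bool, str | None]:
    """Screen a folded candidate precursor; (True, None) or (False, reason).

    ``mature_start``/``mature_end`` are 1-based inclusive positions of the
    mature within ``fold.sequence``.  The first violated criterion is
    reported, in order: mature length, single-arm placement (no mature base
    in the terminal loop), unpaired mature bases, duplex bulge asymmetry,
    hairpin span.
    """
    params = params or MirCheckParams()
    m_len = mature_end - mature_start + 1
    lo, hi = params.mature_len
    if not lo <= m_len <= hi:
        return False, "mature-length"

    partner = fold.partner
    mature_pos = list(range(mature_start, mature_end + 1))
    paired = [i for i in mature_pos if i in partner]

    if params.require_mature_one_arm:
        for a, b in fold.hairpin_loops():
            if any(a < i < b for i in mature_pos):
                return False, "mature-in-terminal-loop"
        if not paired:
            return False, "mature-not-on-single-arm"
        sides = {
            "3p" if partner[i] < mature_start else "5p"
            for i in paired
            if not mature_start <= partner[i] <= mature_end
        }
        if len(sides) != 1:
            return False, "mature-not-on-single-arm"
        arm = sides.pop()
    else:
        arm = "5p"

    n_unpaired = m_len - len(paired)
    if n_unpaired > params.max_unpaired_mature:
        return False, "unpaired-mature-bases"
    if len(paired) < params.min_paired_in_duplex:
        return False, "duplex-too-short"

    # asymmetric bulge within the duplex: compare gaps between consecutive
    # paired mature bases on the mature and star sides
    asym = 0
    for i1, i2 in zip(paired, paired[1:]):
        gap_m = i2 - i1 - 1
        j1, j2 = partner[i1], partner[i2]
        gap_s = abs(j1 - j2) - 1
        asym += abs(gap_m - gap_s)
    if asym > params.max_bulge_asymmetry:
        return False, "bulge-asymmetry"

    # hairpin span: outermost pair enclosing the mature/star duplex, else the
    # duplex extent itself
    duplex_pos = paired + [partner[i] for i in paired]
    dmin, dmax = min(duplex_pos), max(duplex_pos)
    span = dmax - dmin + 1
    for a, b in fold.pairs:
        if a <= dmin and b >= dmax and b - a + 1 > span:
            span = b - a + 1
    if span < params.min_hairpin_len:
        return False, "hairpin-too-short"
    return True, None


def _trim_to_hairpin(
    window_seq: str,
    window_locus: MatchLocus,
    fold: FoldResult,
    mature_span: tuple[int, int],
) -> tuple[str, MatchLocus, tuple[int, int]] | None:
    """Cut the window down to the outermost pair enclosing the mature duplex."""
    partner = fold.partner
    paired = [
        i for i in range(mature_span[0], mature_span[1] + 1) if i in partner
    ]
    if not paired:
        return None
    duplex = paired + [partner[i] for i in paired]
    lo, hi = min(duplex), max(duplex)
    lo = min(lo, mature_span[0])
    hi = max(hi, mature_span[1])
    for a, b in sorted(fold.pairs):
        if a <= lo and b >= hi:
            lo, hi = min(lo, a), max(hi, b)
            break
    seq = fold.sequence[lo - 1 : hi]
    if window_locus.strand == "+":
        start = window_locus.start + lo - 1
        end = window_locus.start + hi - 1
    else:
        # window sequence is the reverse complement of the forward segment
        end = window_locus.end - lo + 1
        start = window_locus.end - hi + 1
    return seq, MatchLocus(window_locus.chrom, window_locus.strand, start, end), (
        mature_span[0] - lo + 1,
        mature_span[1] - lo + 1,
    )


def conservativeness(
    candidate_precursor: str,
    known_precursors: Mapping[str, str],
    min_identity: float = 0.80,
) -> str | None:
    """Best known precursor with ungapped identity >= ``min_identity`` over
    the shorter sequence, sliding the shorter along the longer; else None."""
    best_name, best_ident = None, min_identity
    cand = candidate_precursor.upper()
    for name, ref in known_precursors.items():
        ref = ref.upper()
        short, long_ = (cand, ref) if len(cand) <= len(ref) else (ref, cand)
        n = len(short)
        for off in range(len(long_) - n + 1):
            matches = sum(a == b for a, b in zip(short, long_[off : off + n]))
            ident = matches / n
            if ident > best_ident or (ident == best_ident and best_name is None):
                best_name, best_ident = name, ident
    return best_name


def pair_bidirectional(
    candidates: Sequence[HairpinCandidate], min_reciprocal_overlap: float = 0.80
) -> list[tuple[HairpinCandidate, HairpinCandidate]]:
    """Sense/antisense candidate pairs: same chromosome, opposite strands,
    precursor intervals overlapping reciprocally >= the given fraction."""
    pairs = []
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            if a.locus.chrom != b.locus.chrom or a.locus.strand == b.locus.strand:
                continue
            ov = min(a.locus.end, b.locus.end) - max(a.locus.start, b.locus.start) + 1
            if ov <= 0:
                continue
            if (
                ov / a.locus.length >= min_reciprocal_overlap
                and ov / b.locus.length >= min_reciprocal_overlap
            ):
                pairs.append((a, b))
    return pairs


def five_prime_composition(mature_seqs: Iterable[str]) -> pd.DataFrame:
    """Counts and fractions of the first nucleotide (RNA alphabet) of each
    mature candidate."""
    seqs = list(mature_seqs)
    if not seqs:
        raise ValueError("no candidates given")
    counts = {b: 0 for b in "UACG"}
    for s in seqs:
        counts[to_rna(s)[0]] += 1
    df = pd.DataFrame(
        {"count": counts, "fraction": {b: c / len(seqs) for b, c in counts.items()}}
    )
    df.index.name = "nt"
    return df


def _scan_subwindows(
    window_seq: str,
    window_locus: MatchLocus,
    mature_at_start: bool,
    m_len: int,
    params: MirCheckParams,
    step: int = 10,
):
    """Fold nested sub-windows (ascending length) anchored at the mature.

    Base-pair maximization over a long window with random flank can scatter
    the mature's pairing partners into the flank even when a clean hairpin
    exists at a shorter extent, so candidate extents are scanned from the
    minimum hairpin length upward and the first extent whose fold passes the
    hairpin criteria is kept (the most compact passing hairpin).
    """
    n = len(window_seq)
    start_len = max(params.min_hairpin_len, m_len + 40)
    lengths = list(range(start_len, n + 1, step))
    if not lengths or lengths[-1] != n:
        lengths.append(n)
    for L in lengths:
        if L < m_len or L > n:
            continue
        sub = window_seq[:L] if mature_at_start else window_seq[-L:]
        span = (1, m_len) if mature_at_start else (L - m_len + 1, L)
        fold = fold_hairpin(sub)
        ok, _reason = mircheck(fold, span[0], span[1], params)
        if ok:
            chrom, strand = window_locus.chrom, window_locus.strand
            # for a minus-strand locus the transcribed window is the reverse
            # complement of the forward segment: its prefix maps to the
            # forward suffix
            prefix_side = mature_at_start if strand == "+" else not mature_at_start
            if prefix_side:
                sub_locus = MatchLocus(
                    chrom, strand, window_locus.start, window_locus.start + L - 1
                )
            else:
                sub_locus = MatchLocus(
                    chrom, strand, window_locus.end - L + 1, window_locus.end
                )
            return sub, sub_locus, fold, span
    return None


def find_candidates(
    unexplained: Mapping[str, Mapping[str, int]],
    loci_map: Mapping[str, list[MatchLocus]],
    genome: Mapping[str, str],
    known_precursors: Mapping[str, str] | None = None,
    params: MirCheckParams | None = None,
    min_support: int = 5,
    flank: int = 200,
    max_loci: int = 10,
) -> list[HairpinCandidate]:
    """Screen unexplained reads into hairpin candidates.

    ``unexplained`` maps read sequence -> per-library counts (combined over
    libraries for seeding, as the published pipeline pools libraries before
    prediction); ``loci_map`` holds each read's perfect-match loci.  Reads
    with total support below ``min_support``, mature-length outside range, or
    more loci than ``max_loci`` (repeat-like) are skipped.  One candidate is
    reported per (mature, trimmed hairpin locus).
    """
    params = params or MirCheckParams()
    lo, hi = params.mature_len
    out: dict[tuple[str, str], HairpinCandidate] = {}
    for seq, counts in unexplained.items():
        if not lo <= len(seq) <= hi:
            continue
        if sum(counts.values()) < min_support:
            continue
        loci = loci_map.get(seq, [])
        if not loci or len(loci) > max_loci:
            continue
        for locus in loci:
            windows = candidate_windows(locus, genome, flank)
            for w_idx, (window_seq, window_locus) in enumerate(windows):
                hit = _scan_subwindows(
                    window_seq, window_locus, w_idx == 0, len(seq), params
                )
                if hit is None:
                    continue
                sub_seq, sub_locus, fold, span = hit
                trimmed = _trim_to_hairpin(sub_seq, sub_locus, fold, span)
                if trimmed is None:
                    continue
                pre_seq, pre_locus, m_span = trimmed
                pre_fold = fold_hairpin(pre_seq)
                ok2, _r2 = mircheck(pre_fold, m_span[0], m_span[1], params)
                if not ok2:
                    continue
                partner = pre_fold.partner
                paired = [
                    i
                    for i in range(m_span[0], m_span[1] + 1)
                    if i in partner
                ]
                arm = "5p" if partner[paired[0]] > m_span[1] else "3p"
                key = (seq, f"{pre_locus.chrom}:{pre_locus.strand}")
                cand = HairpinCandidate(
                    mature=seq,
                    arm=arm,
                    precursor=pre_seq,
                    fold=pre_fold,
                    locus=pre_locus,
                    counts=dict(counts),
                    conserved_to=(
                        conservativeness(pre_seq, known_precursors)
                        if known_precursors
                        else None
                    ),
                )
                full_key = (seq, cand.locus_str)
                if full_key not in out:
                    out[full_key] = cand
                break  # first passing window for this locus
    return sorted(
        out.values(), key=lambda c: (-c.total, c.locus_str, c.mature)
    )


def candidates_table(
    candidates: Sequence[HairpinCandidate], library_ids: Sequence[str]
) -> pd.DataFrame:
    """Shortlist table: mature (RNA), length, per-library counts, total,
    precursor location string, conservation."""
    rows = []
    for c in candidates:
        row = {
            "mature": c.mature_rna,
            "length_nt": len(c.mature),
            "total": c.total,
        }
        for lib in library_ids:
            row[lib] = c.counts.get(lib, 0)
        row["precursor_location"] = c.locus_str
        row["precursor_conservativeness"] = c.conserved_to or "None"
        rows.append(row)
    return pd.DataFrame(rows)
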