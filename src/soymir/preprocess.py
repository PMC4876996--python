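"""Raw FASTQ -> collapsed clean reads.

Screening rules, in order, for every raw read:

1. quality screen — a read with more than ``max_low_quality_bases`` (default 4)
   Phred scores strictly below ``low_quality_threshold`` (default 15) is
   discarded;
2. 3' adapter trim — the insert is the prefix before the leftmost exact match
   of the first ``min_adapter_prefix`` nt of the adapter; reads with no adapter
   match, an empty insert (adapter contaminant) or an 'N' in the insert are
   dropped;
3. collapse — identical 15-30-nt inserts are merged with summed counts.

The result is a :class:`CleanReadSet`: unique sequences with abundances, the
"Unique"/"Total" pair reported per library.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .seqs import DNA_ALPHABET

logger = logging.getLogger(__name__)


@dataclass
class RawRead:
    id: str
    sequence: str
    quality: Sequence[int]  # Phred scores, same length as sequence


@dataclass
class PreprocessParams:
    """Screening thresholds; defaults follow the published screening rules."""

    adapter: str
    low_quality_threshold: int = 15
    max_low_quality_bases: int = 4
    min_adapter_prefix: int = 7
    min_len: int = 15
    max_len: int = 30
    phred_offset: int = 33

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if min(self.low_quality_threshold, self.max_low_quality_bases) < 0:
            raise ValueError("thresholds must be non-negative")
        if len(self.adapter) < self.min_adapter_prefix:
            raise ValueError(
                f"adapter ({len(self.adapter)} nt) shorter than "
                f"min_adapter_prefix ({self.min_adapter_prefix})"
            )

    @property
    def adapter_prefix(self) -> str:
        return self.adapter[: self.min_adapter_prefix].upper()


@dataclass
class CleanReadSet:
    """Collapsed unique clean sequences with per-sequence abundance."""

    library_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def unique(self) -> int:
        return len(self.counts)

    def __contains__(self, seq: str) -> bool:
        return seq in self.counts

    def subset(self, keep: Iterable[str]) -> "CleanReadSet":
        keep = set(keep)
        return CleanReadSet(
            self.library_id, {s: c for s, c in self.counts.items() if s in keep}
        )

    def to_fasta(self, handle) -> None:
        """Collapsed-read FASTA with ``>seq{i}_x{count}`` headers."""
        for i, (seq, count) in enumerate(
            sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])), start=1
        ):
            handle.write(f">seq{i}_x{count}\n{seq}\n")

    def to_tsv(self, handle) -> None:
        handle.write("sequence\tcount\n")
        for seq, count in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            handle.write(f"{seq}\t{count}\n")

    @classmethod
    def from_tsv(cls, handle, library_id: str) -> "CleanReadSet":
        counts: dict[str, int] = {}
        header = next(handle, None)
        if header is None:
            return cls(library_id, counts)
        for line in handle:
            seq, count = line.rstrip("\n").split("\t")
            counts[seq] = int(count)
        return cls(library_id, counts)


@dataclass
class StageCounts:
    """Per-library read tallies mirroring the composition-table top rows."""

    library_id: str
    raw: int = 0
    high_quality: int = 0
    clean_total: int = 0
    clean_unique: int = 0


def quality_screen(read: RawRead, params: PreprocessParams) -> bool:
    """True (keep) unless *more than* ``max_low_quality_bases`` scores are
    strictly below ``low_quality_threshold``.  Empty reads are discarded."""
    if not read.sequence:
        logger.debug("discarding empty read %s", read.id)
        return False
    n_low = sum(q < params.low_quality_threshold for q in read.quality)
    return n_low <= params.max_low_quality_bases


def trim_adapter(sequence: str, params: PreprocessParams) -> str | None:
    """Insert before the leftmost exact adapter-prefix match, or None.

    None means the read is dropped: no adapter match, empty insert (pure
    adapter contaminant), or an 'N' inside the insert.
    """
    pos = sequence.find(params.adapter_prefix)
    if pos <= 0:  # -1: no adapter; 0: read begins with adapter (contaminant)
        return None
    insert = sequence[:pos]
    if "N" in insert:
        return None
    return insert


def collapse(inserts: Iterable[str], params: PreprocessParams) -> CleanReadSet:
    """Length-filter inserts to [min_len, max_len] over {A,C,G,T} and merge
    identical sequences with summed counts."""
    counter: Counter[str] = Counter()
    lo, hi = params.min_len, params.max_len
    for ins in inserts:
        if lo <= len(ins) <= hi and set(ins) <= DNA_ALPHABET:
            counter[ins] += 1
    return CleanReadSet(library_id="", counts=dict(counter))


def _iter_fastq(handle) -> Iterator[tuple[str, str, str]]:
    yield from FastqGeneralIterator(handle)


def preprocess_fastq(
    handle,
    params: PreprocessParams,
    library_id: str,
) -> tuple[CleanReadSet, StageCounts]:
    """Run the full screen -> trim -> collapse chain on one FASTQ stream.

    The quality screen is applied on encoded quality strings directly for
    speed; the per-read rule is identical to :func:`quality_screen`.
    """
    stages = StageCounts(library_id=library_id)
    low_chars = [
        chr(params.phred_offset + q) for q in range(params.low_quality_threshold)
    ]
    counter: Counter[str] = Counter()
    lo, hi = params.min_len, params.max_len
    prefix = params.adapter_prefix
    for _title, seq, qual in _iter_fastq(handle):
        stages.raw += 1
        if not seq:
            continue
        n_low = 0
        for c in low_chars:
            n_low += qual.count(c)
            if n_low > params.max_low_quality_bases:
                break
        if n_low > params.max_low_quality_bases:
            continue
        stages.high_quality += 1
        seq = seq.upper()
        pos = seq.find(prefix)
        if pos <= 0:
            continue
        insert = seq[:pos]
        if "N" in insert:
            continue
        if lo <= len(insert) <= hi and set(insert) <= DNA_ALPHABET:
            counter[insert] += 1
    clean = CleanReadSet(library_id=library_id, counts=dict(counter))
    stages.clean_total = clean.total
    stages.clean_unique = clean.unique
    return clean, stages


def preprocess_reads(
    reads: Iterable[RawRead],
    params: PreprocessParams,
    library_id: str = "",
) -> tuple[CleanReadSet, StageCounts]:
    """In-memory variant of :func:`preprocess_fastq` over RawRead objects."""
    stages = StageCounts(library_id=library_id)
    inserts = []
    for read in reads:
        stages.raw += 1
        if not quality_screen(read, params):
            continue
        stages.high_quality += 1
        insert = trim_adapter(read.sequence.upper(), params)
        if insert is not None:
            inserts.append(insert)
    clean = collapse(inserts, params)
    clean.library_id = library_id
    stages.clean_total = clean.total
    stages.clean_unique = clean.unique
    return clean, stages
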