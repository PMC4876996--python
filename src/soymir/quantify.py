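"""Quantification of clean reads against known mature miRNAs and precursors.

A clean read is counted as a known mature miRNA only when its sequence equals
a registered mature sequence exactly, full length.  Identical mature sequences
registered under several names (one sequence shared by a family) form a single
statistical unit: one count-table row annotated with every name.  Precursor
matching is exact-substring.  The non-coding-RNA screen replaces a BLAST/Rfam
search with exact substring matching against a supplied classified ncRNA
FASTA, in both orientations (a strandless homology search removes antisense
fragments too).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .preprocess import CleanReadSet
from .seqs import revcomp, to_dna

NCRNA_CLASSES = ("rRNA", "tRNA", "snoRNA", "other")


@dataclass
class MiRNAReference:
    """Known mature miRNAs and stem-loop precursors, DNA-normalized."""

    mature: dict[str, str]  # name -> sequence
    precursors: dict[str, str]  # name -> sequence
    seq_to_names: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.mature.items():
            if not 15 <= len(seq) <= 30:
                raise ValueError(f"mature {name} length {len(seq)} outside 15-30")
        if not self.seq_to_names:
            for name, seq in self.mature.items():
                self.seq_to_names.setdefault(seq, []).append(name)

    @classmethod
    def from_fasta(cls, mature_handle, precursor_handle) -> "MiRNAReference":
        mature = {
            rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(mature_handle, "fasta")
        }
        precursors = {
            rec.id: to_dna(str(rec.seq))
            for rec in SeqIO.parse(precursor_handle, "fasta")
        }
        return cls(mature=mature, precursors=precursors)


def count_mature(clean: CleanReadSet, ref: MiRNAReference) -> pd.DataFrame:
    """One row per distinct mature sequence present in the reference.

    Columns: ``names`` (comma-joined mature names sharing the sequence) and
    ``count`` (collapsed abundance in this library; 0 if unobserved).
    """
    rows = []
    for seq, names in sorted(ref.seq_to_names.items()):
        rows.append((seq, ",".join(sorted(names)), clean.counts.get(seq, 0)))
    return pd.DataFrame(rows, columns=["sequence", "names", "count"]).set_index(
        "sequence"
    )


def build_count_table(
    clean_sets: Mapping[str, CleanReadSet], ref: MiRNAReference
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Mature-miRNA count matrix (rows: sequences, cols: libraries).

    Returns the table (with a ``names`` column) and the per-library clean
    totals carried alongside for normalization.
    """
    table = None
    totals = {}
    for lib, clean in clean_sets.items():
        col = count_mature(clean, ref)
        if table is None:
            table = col.rename(columns={"count": lib})
        else:
            table[lib] = col["count"]
        totals[lib] = clean.total
    assert table is not None, "no libraries given"
    return table, totals


def count_precursor_matches(
    clean: CleanReadSet, ref: MiRNAReference
) -> pd.DataFrame:
    """Per-precursor (unique, total) read support by exact substring match.

    A read matches a precursor when the read or its reverse complement is an
    exact substring of the precursor; a read matching several precursors is
    counted for each of them (a documented ambiguity of the per-precursor
    tally).  A read occurring at several offsets of one precursor is still
    counted once for that precursor.
    """
    rows = []
    for name, pre in sorted(ref.precursors.items()):
        uniq = total = 0
        for seq, n in clean.counts.items():
            if seq in pre or revcomp(seq) in pre:
                uniq += 1
                total += n
        rows.append((name, uniq, total))
    df = pd.DataFrame(rows, columns=["precursor", "unique", "total"]).set_index(
        "precursor"
    )
    return df


def precursors_hit(precursor_counts: pd.DataFrame) -> int:
    """Number of precursors with at least one matching read."""
    return int((precursor_counts["total"] > 0).sum())


def matching_precursor_reads(
    clean: CleanReadSet, ref: MiRNAReference
) -> tuple[int, int]:
    """(unique, total) clean reads matching >=1 precursor (each read once)."""
    uniq = total = 0
    pres = list(ref.precursors.values())
    for seq, n in clean.counts.items():
        rc = revcomp(seq)
        if any(seq in p or rc in p for p in pres):
            uniq += 1
            total += n
    return uniq, total


def load_ncrna_fasta(handle) -> dict[str, tuple[str, str]]:
    """Classified ncRNA records: name -> (class, DNA sequence).

    The class is read from a ``class=...`` key in the FASTA description, else
    from a class token (rRNA/tRNA/snoRNA) in the record name; anything
    unrecognized is "other".
    """
    records = {}
    for rec in SeqIO.parse(handle, "fasta"):
        cls = "other"
        for token in rec.description.split():
            if token.startswith("class="):
                cls = token.split("=", 1)[1]
                break
        else:
            lowered = rec.id.lower()
            for known in NCRNA_CLASSES[:3]:
                if known.lower() in lowered:
                    cls = known
                    break
        records[rec.id] = (cls if cls in NCRNA_CLASSES else "other", to_dna(str(rec.seq)))
    return records


def filter_ncrna(
    clean: CleanReadSet, ncrna: Mapping[str, tuple[str, str]]
) -> tuple[CleanReadSet, pd.DataFrame]:
    """Remove reads that are exact substrings of any ncRNA record.

    Both orientations are tested.  Removed reads are tallied by class with
    fixed priority rRNA > tRNA > snoRNA > other when a read hits several
    classes.  Returns (retained set, removed-per-class frame with unique and
    total columns; conservation: removed + retained = input).
    """
    by_class: dict[str, list[str]] = {c: [] for c in NCRNA_CLASSES}
    for _name, (cls, seq) in ncrna.items():
        by_class[cls].append(seq)
    removed = {c: {"unique": 0, "total": 0} for c in NCRNA_CLASSES}
    retained: dict[str, int] = {}
    for seq, n in clean.counts.items():
        rc = revcomp(seq)
        hit_class = None
        for cls in NCRNA_CLASSES:
            if any(seq in ref or rc in ref for ref in by_class[cls]):
                hit_class = cls
                break
        if hit_class is None:
            retained[seq] = n
        else:
            removed[hit_class]["unique"] += 1
            removed[hit_class]["total"] += n
    removed_df = pd.DataFrame(removed).T
    removed_df.index.name = "class"
    return CleanReadSet(clean.library_id, retained), removed_df
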