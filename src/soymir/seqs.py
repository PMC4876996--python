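"""Small nucleotide-sequence helpers shared across the pipeline.

All internal sequences use the DNA alphabet {A,C,G,T}; RNA input (miRBase
mature/precursor FASTA) is normalized with U->T at load time and converted
back to U only for display.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA or RNA input; DNA output for DNA input)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_dna(seq: str) -> str:
    """Uppercase and replace U with T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and replace T with U (display form for mature miRNAs)."""
    return seq.upper().replace("T", "U")


def is_dna(seq: str) -> bool:
    return bool(seq) and set(seq) <= DNA_ALPHABET


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)
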