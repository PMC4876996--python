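"""Nested secondary-structure prediction by base-pair maximization.

The hairpin criteria used for plant miRNA candidacy consume only pairing
topology: which mature bases are paired, how asymmetric the bulges in the
miRNA/miRNA* duplex are, and where the terminal loop sits.  Base-pair
maximization (Nussinov-style dynamic programming with a minimum loop of 3
unpaired bases and G:U wobble pairs allowed) provides exactly that topology
deterministically, without an energy-parameter dependency.  The traceback is
deterministic: among pairings achieving the optimum the partner with the
smallest outer index is chosen first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MIN_LOOP = 3  # unpaired bases required inside any loop: j - i > 3 for a pair (i, j)

_CANONICAL = frozenset(
    {"AT", "TA", "AU", "UA", "GC", "CG", "GT", "TG", "GU", "UG"}
)


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or G:U wobble pair (DNA or RNA letters)."""
    return a + b in _CANONICAL


@dataclass
class FoldResult:
    """A nested (pseudoknot-free) structure for one sequence.

    ``pairs`` uses 1-based positions with i < j; ``structure`` is the
    dot-bracket string of the same length as ``sequence``.
    """

    sequence: str
    structure: str
    pairs: list[tuple[int, int]]
    n_pairs: int
    partner: dict[int, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.partner:
            for i, j in self.pairs:
                self.partner[i] = j
                self.partner[j] = i

    def hairpin_loops(self) -> list[tuple[int, int]]:
        """Closing pairs (i, j) with no other pair nested inside them."""
        loops = []
        for i, j in self.pairs:
            if all(not (i < a < j) for a, b in self.pairs if (a, b) != (i, j)):
                loops.append((i, j))
        return loops


def fold_hairpin(sequence: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Fold ``sequence`` into the maximum-base-pair nested structure.

    Parameters
    ----------
    sequence:
        15-600 nt, DNA or RNA alphabet (no ambiguity codes).
    min_loop:
        Minimum number of unpaired bases enclosed by any pair.

    Returns
    -------
    FoldResult with the optimal pair count and a deterministic traceback.
    """
    seq = sequence.upper()
    if not 1 <= len(seq) <= 600:
        raise ValueError(f"sequence length {len(seq)} outside supported range")
    if not set(seq) <= set("ACGTU"):
        bad = sorted(set(seq) - set("ACGTU"))
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    n = len(seq)

    # partners_of[j] = sorted array of k < j that can pair with base j
    chars = np.frombuffer(seq.encode(), dtype="S1")
    partners_of: list[np.ndarray] = []
    for j in range(n):
        ks = [k for k in range(j - min_loop) if can_pair(seq[k], seq[j])]
        partners_of.append(np.asarray(ks, dtype=np.intp))

    # N[i, j] = max pairs in seq[i..j]; recurrence splits on the partner of j.
    N = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i, j - 1]  # j unpaired
            cand = partners_of[j]
            ks = cand[cand >= i]
            if ks.size:
                left = N[i, ks - 1]
                left = np.where(ks > i, left, 0)
                vals = left + N[np.minimum(ks + 1, j), j - 1] * (ks + 1 <= j - 1) + 1
                m = int(vals.max())
                if m > best:
                    best = m
            N[i, j] = best
    del chars

    # Deterministic traceback: at (i, j), if some pairing (k, j) achieves the
    # optimum, take the smallest such k (smallest outer index); otherwise j is
    # unpaired.
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while j - i > min_loop and N[i, j] > 0:
            target = N[i, j]
            cand = partners_of[j]
            ks = cand[cand >= i]
            chosen = -1
            for k in map(int, ks):
                left = N[i, k - 1] if k > i else 0
                right = N[k + 1, j - 1] if k + 1 <= j - 1 else 0
                if left + right + 1 == target:
                    chosen = k
                    break
            if chosen < 0:
                j -= 1  # j unpaired at the optimum
                continue
            pairs.append((chosen + 1, j + 1))
            if chosen + 1 <= j - 1:
                stack.append((chosen + 1, j - 1))
            j = chosen - 1
            if j <= i:
                break

    pairs.sort()
    structure = ["."] * n
    for a, b in pairs:
        structure[a - 1] = "("
        structure[b - 1] = ")"
    return FoldResult(
        sequence=sequence,
        structure="".join(structure),
        pairs=pairs,
        n_pairs=len(pairs),
    )
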