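"""Docking-strand library validation.

Speed-optimized docking strands are tandem concatemers of a short motif;
the library combines natural right-handed (R) sequences with left-handed
(L-DNA) mirror analogs.  This module checks the design constraints: tandem
repeat construction, hairpin freedom (no long self-complementary stem) and
cross-hybridization between strands.  Complementarity is exact Watson-Crick
string matching; mirror (L) and natural (R) DNA never hybridize with each
other, so cross-chirality scores are zero by definition.
"""

from __future__ import annotations

from dataclasses import dataclass

ALPHABET = set("ACGT")
COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: placeholder tandem-repeat motifs; the published R1-R6/L1-L6 sequences live
#: in supplementary material and can be supplied by the user instead
PLACEHOLDER_MOTIFS = {
    "R1": "TCCTCCC",
    "R2": "ACCACCA",
    "R3": "TGGTGGT",
    "R4": "CACCACC",
    "R5": "AGGAGGA",
    "R6": "TTCCTCC",
    "L1": "TCCTCCC",
    "L2": "ACCACCA",
    "L3": "TGGTGGT",
    "L4": "CACCACC",
    "L5": "AGGAGGA",
    "L6": "TTCCTCC",
}


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - ALPHABET
    if bad or not seq:
        raise ValueError(f"invalid sequence characters: {sorted(bad) if bad else 'empty'}")
    return seq


def reverse_complement(seq: str) -> str:
    return _check_sequence(seq).translate(COMPLEMENT)[::-1]


@dataclass
class DockingStrand:
    """A docking sequence: tandem repeats of a motif with a chirality label."""

    sequence: str  # 5'->3'
    chirality: str  # 'L' | 'R'
    repeat_unit: str = ""
    n_repeats: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        self.sequence = _check_sequence(self.sequence)
        if self.chirality not in ("L", "R"):
            raise ValueError("chirality must be 'L' or 'R'")
        if self.repeat_unit:
            self.repeat_unit = _check_sequence(self.repeat_unit)

    def __len__(self) -> int:
        return len(self.sequence)


def build_concatemer(
    motif: str,
    n_repeats: int,
    spacer: str = "",
    chirality: str = "R",
    name: str = "",
) -> DockingStrand:
    """Concatenate ``n_repeats`` copies of ``motif`` joined by ``spacer``."""
    motif = _check_sequence(motif)
    if spacer:
        spacer = _check_sequence(spacer)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    seq = spacer.join([motif] * n_repeats)
    return DockingStrand(seq, chirality, repeat_unit=motif, n_repeats=n_repeats, name=name)


def decompose(strand: DockingStrand) -> tuple[str, int]:
    """Recover (motif, n_repeats) of a spacer-free concatemer.

    Returns the smallest period of the sequence; a non-repetitive strand
    decomposes to (sequence, 1).
    """
    seq = strand.sequence
    n = len(seq)
    for period in range(1, n + 1):
        if n % period == 0 and seq == seq[:period] * (n // period):
            return seq[:period], n // period
    return seq, 1  # pragma: no cover


def max_selfcomp_stem(strand: DockingStrand | str, min_loop: int = 3) -> int:
    """Longest possible hairpin stem of a strand.

    The length of the longest pair of reverse-complementary substrings
    separated by at least ``min_loop`` unpaired nucleotides.  A stem of
    length k with outer pair (i, j) requires s[i + t] complementary to
    s[j - t] for t < k and a loop j - i - 2k + 1 >= min_loop.
    """
    seq = strand.sequence if isinstance(strand, DockingStrand) else _check_sequence(strand)
    n = len(seq)
    comp = seq.translate(COMPLEMENT)
    # ext[i][j]: pairing run length going inward from outer pair (i, j)
    best = 0
    ext = [[0] * (n + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(n - 1, i, -1):
            if comp[i] == seq[j]:
                inner = ext[i + 1][j - 1] if (i + 1 <= j - 1) else 0
                ext[i][j] = inner + 1
            k_max = min(ext[i][j], (j - i + 1 - min_loop) // 2)
            if k_max > best:
                best = k_max
    return best


def is_hairpin_free(strand: DockingStrand | str, max_stem: int = 2, min_loop: int = 3) -> bool:
    """Hairpin-freedom predicate: longest stem below the design threshold."""
    return max_selfcomp_stem(strand, min_loop) <= max_stem


def cross_hyb_score(a: DockingStrand, b: DockingStrand) -> int:
    """Longest contiguous reverse-complementary run between two strands.

    Zero by definition when the chiralities differ: left-handed DNA does not
    hybridize with natural right-handed DNA regardless of sequence.
    """
    if a.chirality != b.chirality:
        return 0
    s = a.sequence
    t = reverse_complement(b.sequence)
    # longest common substring of s and revcomp(b)
    prev = [0] * (len(t) + 1)
    best = 0
    for i in range(1, len(s) + 1):
        cur = [0] * (len(t) + 1)
        for j in range(1, len(t) + 1):
            if s[i - 1] == t[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def cross_hyb_matrix(strands: list[DockingStrand]) -> list[list[int]]:
    """Pairwise cross-hybridization scores; block-diagonal by chirality."""
    return [[cross_hyb_score(a, b) for b in strands] for a in strands]


def default_library(n_repeats: int = 5) -> list[DockingStrand]:
    """Placeholder 12-strand R/L library of tandem concatemers."""
    return [
        build_concatemer(motif, n_repeats, chirality=name[0], name=name)
        for name, motif in PLACEHOLDER_MOTIFS.items()
    ]
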