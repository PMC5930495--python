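"""Standard genetic code, third-position degeneracy classes, and translation.

Synonymous-shuffle null models only ever alter the third codon position.
With the first two positions held fixed, the standard genetic code
(NCBI translation table 1) partitions the admissible third-position
substitutions of every codon into one of four degeneracy classes —
R (A/G), Y (C/T), H (A/C/T) and N (any nucleotide) — or leaves the codon
FIXED when it is the sole codon of its family (Met ATG, Trp TGG, and the
TGA stop).  Six-codon amino acids (Leu, Ser, Arg) resolve naturally into
a two-codon and a four-codon family because their sub-families differ in
the first two positions.

Stop codons: TAA and TAG are mutually synonymous through a third-position
change and are treated as an R-class family; TGA has no such partner and
is FIXED.  Passing ``freeze_stops=True`` forces every stop codon to FIXED
for users who prefer never to touch stops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")
STOP_SYMBOL = "*"

_STANDARD_TABLE = unambiguous_dna_by_id[1]

#: Codon -> one-letter amino acid, stops rendered as ``*``.
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = STOP_SYMBOL

_CLASS_LABELS = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("ACT"): "H",
    frozenset("ACGT"): "N",
}


class SequenceValidationError(ValueError):
    """Raised when an input fails the in-frame A/C/G/T coding-sequence contract."""


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame protein-coding nucleotide sequence.

    Parameters
    ----------
    nucleotides:
        Upper-case sequence over ``{A, C, G, T}`` whose length is a
        positive multiple of 3.  The reading frame starts at position 0;
        all motif positions downstream are 0-based offsets on this (top)
        strand.
    identifier:
        Free-text label, typically the FASTA header.
    """

    nucleotides: str
    identifier: str = ""

    def __post_init__(self) -> None:
        n = len(self.nucleotides)
        if n == 0 or n % 3 != 0:
            raise SequenceValidationError(
                f"{self.identifier or 'sequence'!s}: length {n} is not a "
                "positive multiple of 3 (expected an in-frame CDS)"
            )
        bad = set(self.nucleotides) - NUCLEOTIDES
        if bad:
            raise SequenceValidationError(
                f"{self.identifier or 'sequence'!s}: invalid characters "
                f"{sorted(bad)}; only A/C/G/T are accepted"
            )

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codons(self) -> list[str]:
        s = self.nucleotides
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def internal_stop_positions(self) -> list[int]:
        """Codon indices (excluding the last codon) that encode a stop."""
        return [
            i
            for i, c in enumerate(self.codons()[:-1])
            if CODON_TO_AA[c] == STOP_SYMBOL
        ]


@dataclass(frozen=True)
class DegeneracyClass:
    """Third-position degeneracy class of a codon.

    ``label`` is one of ``R``, ``Y``, ``H``, ``N`` or ``FIXED``;
    ``allowed_third_positions`` is the set of third-position bases that
    keep the encoded amino acid (or keep a stop a stop).
    """

    label: str
    allowed_third_positions: frozenset[str]


def _check_codon(codon: str) -> str:
    if len(codon) != 3 or set(codon) - NUCLEOTIDES:
        raise SequenceValidationError(f"invalid codon {codon!r}")
    return codon


@lru_cache(maxsize=None)
def classify_codon(codon: str, freeze_stops: bool = False) -> DegeneracyClass:
    """Degeneracy class of ``codon``'s third position under the standard code."""
    codon = _check_codon(codon)
    aa = CODON_TO_AA[codon]
    if freeze_stops and aa == STOP_SYMBOL:
        return DegeneracyClass("FIXED", frozenset(codon[2]))
    allowed = frozenset(
        b for b in "ACGT" if CODON_TO_AA[codon[:2] + b] == aa
    )
    if len(allowed) == 1:
        return DegeneracyClass("FIXED", allowed)
    return DegeneracyClass(_CLASS_LABELS[allowed], allowed)


@lru_cache(maxsize=None)
def synonymous_options(codon: str, freeze_stops: bool = False) -> tuple[str, ...]:
    """All codons reachable from ``codon`` by a synonymous third-position change.

    Always contains ``codon`` itself; sorted alphabetically.
    """
    cls = classify_codon(codon, freeze_stops)
    return tuple(sorted(codon[:2] + b for b in cls.allowed_third_positions))


def translate(seq: CodingSequence | str) -> str:
    """Translate an in-frame CDS; stop codons render as ``*``."""
    s = seq.nucleotides if isinstance(seq, CodingSequence) else seq
    if len(s) % 3 != 0:
        raise SequenceValidationError("length not a multiple of 3")
    return "".join(CODON_TO_AA[s[i : i + 3]] for i in range(0, len(s), 3))
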