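"""Deaminase mutation-motif scanning and replacement-transition counting.

AID/APOBEC cytidine deaminases act on single-stranded DNA, mutating C→U
(read as C→T after replication) within short preferred contexts such as
WRC (AID), TC (APOBEC3A/B) or CCC (APOBEC3G).  This module finds all
(possibly overlapping) occurrences of an IUPAC motif on either strand of
a coding sequence, simulates the canonical deamination at each
occurrence — C→T on the top strand, G→A on the top strand for a
bottom-strand hit — and counts how many of those single-nucleotide
changes are nonsynonymous ("replacement transitions").
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

from .codons import CODON_TO_AA, CodingSequence, SequenceValidationError

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

STRAND_MODES = ("top", "bottom", "both")


class MotifConfigError(ValueError):
    """Raised for an ill-formed motif specification."""


def reverse_complement(s: str) -> str:
    """Reverse complement with IUPAC degeneracy (R<->Y, S<->S, H<->D, ...)."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(s))
    except KeyError as exc:
        raise MotifConfigError(f"invalid IUPAC character {exc.args[0]!r}") from exc


@lru_cache(maxsize=None)
def _compiled(pattern: str) -> re.Pattern[str]:
    # lookahead so overlapping occurrences are all found
    body = "".join(f"[{IUPAC_SETS[c]}]" for c in pattern)
    return re.compile(f"(?=({body}))")


def _default_target_index(pattern: str) -> int:
    """Rightmost literal C: deaminase motifs put the mutated C at the 3' end,
    and for CpG the relevant C is the first (and only) literal C."""
    idx = pattern.rfind("C")
    if idx < 0:
        raise MotifConfigError(
            f"motif pattern {pattern!r} contains no literal C to deaminate"
        )
    return idx


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC mutation motif plus the position of the deaminated cytidine.

    ``target_index`` defaults to the rightmost literal C of the pattern.
    ``strand_mode`` is ``top``, ``bottom`` or ``both``; a pattern equal to
    its own reverse complement (e.g. CG) is scanned on the top strand only
    under ``both``, since each site would otherwise be counted twice.
    """

    pattern: str
    target_index: int | None = None
    strand_mode: str = "both"
    name: str = ""

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if len(pat) < 2:
            raise MotifConfigError(f"motif {pat!r} shorter than 2 nucleotides")
        for c in pat:
            if c not in IUPAC_SETS:
                raise MotifConfigError(f"invalid IUPAC character {c!r} in {pat!r}")
        if self.target_index is None:
            object.__setattr__(self, "target_index", _default_target_index(pat))
        ti = self.target_index
        if not (0 <= ti < len(pat)) or pat[ti] != "C":
            raise MotifConfigError(
                f"motif {pat!r}: target_index {ti} does not point at a literal C"
            )
        if self.strand_mode not in STRAND_MODES:
            raise MotifConfigError(
                f"unknown strand mode {self.strand_mode!r}; expected {STRAND_MODES}"
            )
        if not self.name:
            object.__setattr__(self, "name", pat)

    @property
    def is_self_complementary(self) -> bool:
        return self.pattern == reverse_complement(self.pattern)

    @property
    def effective_strands(self) -> tuple[str, ...]:
        if self.strand_mode == "both":
            if self.is_self_complementary:
                return ("top",)
            return ("top", "bottom")
        return (self.strand_mode,)


class Occurrence(NamedTuple):
    """One motif hit: the strand it lies on and the 0-based top-strand
    position of the nucleotide the deamination would mutate."""

    strand: str
    position: int


@dataclass(frozen=True)
class MotifMetrics:
    """Per-motif triple: occurrence count, replacement transitions, and
    their ratio (``None`` when the count is zero)."""

    motif_count: int
    replacement_transitions: int

    @property
    def rep_tr_frac(self) -> float | None:
        if self.motif_count == 0:
            return None
        return self.replacement_transitions / self.motif_count


def _as_string(seq: CodingSequence | str) -> str:
    return seq.nucleotides if isinstance(seq, CodingSequence) else seq


def find_occurrences(
    seq: CodingSequence | str, motif: MotifSpec
) -> list[Occurrence]:
    """All (overlapping) motif hits, scanned left-to-right, top strand first.

    A top-strand hit at match start ``m`` mutates top-strand position
    ``m + target_index`` (C→T); a bottom-strand hit — a match of the
    pattern's reverse complement on the top strand — mutates position
    ``m + len(pattern) - 1 - target_index`` (G→A on the top strand).
    Hits overhanging the sequence ends are not counted (linear topology).
    """
    s = _as_string(seq)
    occ: list[Occurrence] = []
    strands = motif.effective_strands
    if "top" in strands:
        rx = _compiled(motif.pattern)
        occ.extend(
            Occurrence("top", m.start() + motif.target_index)
            for m in rx.finditer(s)
        )
    if "bottom" in strands:
        rc = reverse_complement(motif.pattern)
        offset = len(motif.pattern) - 1 - motif.target_index
        rx = _compiled(rc)
        occ.extend(
            Occurrence("bottom", m.start() + offset) for m in rx.finditer(s)
        )
    return occ


def count_motifs(seq: CodingSequence | str, motif: MotifSpec) -> int:
    """Number of motif occurrences under the motif's strand mode."""
    return len(find_occurrences(seq, motif))


def count_replacement_transitions(
    seq: CodingSequence | str, motif: MotifSpec
) -> int:
    """Occurrences whose simulated deamination changes the encoded amino acid.

    The implied change is C→T at a top-strand hit and G→A (projected onto
    the top strand) at a bottom-strand hit; a change that creates or
    destroys a stop codon counts as nonsynonymous.
    """
    s = _as_string(seq)
    if len(s) % 3 != 0:
        raise SequenceValidationError(
            "replacement transitions need an in-frame sequence"
        )
    n = 0
    for strand, pos in find_occurrences(s, motif):
        new = "T" if strand == "top" else "A"
        start = 3 * (pos // 3)
        codon = s[start : start + 3]
        off = pos - start
        mutated = codon[:off] + new + codon[off + 1 :]
        if CODON_TO_AA[codon] != CODON_TO_AA[mutated]:
            n += 1
    return n


def motif_metrics(seq: CodingSequence | str, motif: MotifSpec) -> MotifMetrics:
    """Assemble the (count, replacement transitions, fraction) triple."""
    return MotifMetrics(
        motif_count=count_motifs(seq, motif),
        replacement_transitions=count_replacement_transitions(seq, motif),
    )


def default_motif_set() -> list[MotifSpec]:
    """The 23 default motifs: 4 NC, 16 NNC, WRC (AID hotspot), SYC (AID
    coldspot) and CG (CpG), all scanned on both strands."""
    motifs: list[MotifSpec] = []
    for b in "ACGT":
        motifs.append(MotifSpec(b + "C", target_index=1))
    for b1 in "ACGT":
        for b2 in "ACGT":
            motifs.append(MotifSpec(b1 + b2 + "C", target_index=2))
    motifs.append(MotifSpec("WRC", target_index=2))
    motifs.append(MotifSpec("SYC", target_index=2))
    motifs.append(MotifSpec("CG", target_index=0))
    return motifs
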