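"""Synonymous-shuffle null models for coding sequences.

Three schemes generate "other sequences evolution could equally have
produced": each preserves the amino-acid sequence exactly (only third
codon positions move) while correcting for a different compositional
covariate of the subject sequence.

``gc3``
    Redraws every non-FIXED third position independently, splitting
    probability mass ``g`` (the subject's third-position GC fraction)
    uniformly over the degeneracy class's G/C options and mass ``1 - g``
    uniformly over its A/T options.  Corrects for GC3 in expectation but
    does not conserve it exactly in any one replicate.

``n3``
    Pools third-position nucleotides by degeneracy class (R, Y, H, N) and
    permutes each pool without replacement.  Conserves the base
    composition of the sequence — and hence GC content — exactly.

``dn23``
    Redraws third positions with probability proportional to the
    subject-wide frequency of the (position-2, candidate-position-3)
    dinucleotide, normalised over the codon's synonymous options.
    Largely preserves dinucleotide frequency and codon bias.

All schemes are driven by a single :class:`numpy.random.Generator`; a run
is reproducible from ``ShuffleConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .codons import (
    CodingSequence,
    classify_codon,
    synonymous_options,
)

logger = logging.getLogger(__name__)

SHUFFLE_METHODS = ("gc3", "n3", "dn23")

_GC = frozenset("GC")
_AT = frozenset("AT")


class ShuffleConfigError(ValueError):
    """Raised for an unknown shuffle method or invalid replicate count."""


@dataclass(frozen=True)
class ShuffleConfig:
    """Null-model configuration.

    ``method`` selects the shuffle scheme; ``replicates`` (r) is the null
    distribution size (1000 by default); identical ``(method, seed,
    input)`` yields an identical replicate stream.
    """

    method: str = "gc3"
    replicates: int = 1000
    seed: int | None = None
    gc3_include_fixed: bool = True
    freeze_stops: bool = False

    def __post_init__(self) -> None:
        if self.method not in SHUFFLE_METHODS:
            raise ShuffleConfigError(
                f"unknown shuffle method {self.method!r}; "
                f"expected one of {SHUFFLE_METHODS}"
            )
        if self.replicates < 1:
            raise ShuffleConfigError("replicates must be >= 1")


# ---------------------------------------------------------------------------
# composition statistics of the subject sequence


def gc3_content(
    seq: CodingSequence | str,
    include_fixed: bool = True,
    freeze_stops: bool = False,
) -> float:
    """Fraction of G/C at third codon positions of the subject.

    With ``include_fixed=False``, codons whose third position cannot move
    (FIXED class) are excluded from both numerator and denominator.
    """
    s = seq.nucleotides if isinstance(seq, CodingSequence) else seq
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    if not include_fixed:
        codons = [
            c for c in codons if classify_codon(c, freeze_stops).label != "FIXED"
        ]
        if not codons:
            logger.warning(
                "gc3_content: no non-FIXED codons; falling back to g=0.5"
            )
            return 0.5
    return sum(c[2] in _GC for c in codons) / len(codons)


def dinucleotide_frequencies(seq: CodingSequence | str) -> dict[str, float]:
    """Frequencies of the (position 2, position 3) dinucleotide over all codons."""
    s = seq.nucleotides if isinstance(seq, CodingSequence) else seq
    n = len(s) // 3
    freqs: dict[str, float] = {
        a + b: 0.0 for a in "ACGT" for b in "ACGT"
    }
    for i in range(n):
        freqs[s[3 * i + 1 : 3 * i + 3]] += 1.0
    return {d: c / n for d, c in freqs.items()}


# ---------------------------------------------------------------------------
# per-codon option probabilities


def gc3_option_probabilities(
    codon: str, g: float, freeze_stops: bool = False
) -> dict[str, float]:
    """Per-option probabilities the gc3 scheme assigns to one codon.

    Mass ``g`` is split uniformly over the G/C-ending options of the
    codon's degeneracy class and mass ``1 - g`` uniformly over the
    A/T-ending options; a FIXED codon keeps probability 1 on itself.
    If a class has options on one side only (possible only when ``g`` is
    0 or 1 leaves no mass on the available side), the draw renormalises
    over the available options.
    """
    opts = synonymous_options(codon, freeze_stops)
    if len(opts) == 1:
        return {opts[0]: 1.0}
    gc_opts = [o for o in opts if o[2] in _GC]
    at_opts = [o for o in opts if o[2] in _AT]
    probs: dict[str, float] = {}
    for o in gc_opts:
        probs[o] = (g / len(gc_opts)) if gc_opts else 0.0
    for o in at_opts:
        probs[o] = ((1.0 - g) / len(at_opts)) if at_opts else 0.0
    total = sum(probs.values())
    if total <= 0.0:  # degenerate: g leaves no mass on the only available side
        return {o: 1.0 / len(opts) for o in opts}
    return {o: p / total for o, p in probs.items()}


def dn23_option_weights(
    codon: str,
    dinuc_freqs: dict[str, float],
    freeze_stops: bool = False,
) -> dict[str, float]:
    """Normalised selection weights the dn23 scheme assigns to one codon.

    Each synonymous option is weighted by the subject-wide frequency of
    the dinucleotide its (position 2, position 3) pair would form; if all
    options have zero frequency, the draw is uniform.
    """
    opts = synonymous_options(codon, freeze_stops)
    weights = {o: dinuc_freqs.get(o[1:3], 0.0) for o in opts}
    total = sum(weights.values())
    if total <= 0.0:
        return {o: 1.0 / len(opts) for o in opts}
    return {o: w / total for o, w in weights.items()}


# ---------------------------------------------------------------------------
# vectorised batch engine

_BASE_CODE = {b: ord(b) for b in "ACGT"}


def _categorical_batch(
    seq_bytes: np.ndarray,
    per_codon: list[dict[str, float]],
    r: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``r`` sequences with independent per-codon third-position draws.

    ``per_codon`` maps each codon slot to its option-probability dict.
    Returns an (r, len) uint8 matrix.
    """
    n = len(per_codon)
    kmax = max(len(p) for p in per_codon)
    opt_mat = np.zeros((n, kmax), dtype=np.uint8)
    cum_mat = np.ones((n, kmax), dtype=np.float64)
    for i, probs in enumerate(per_codon):
        opts = list(probs)
        cum = np.cumsum([probs[o] for o in opts])
        cum[-1] = 1.0  # guard against floating-point undershoot
        k = len(opts)
        opt_mat[i, :k] = [_BASE_CODE[o[2]] for o in opts]
        opt_mat[i, k:] = opt_mat[i, k - 1]
        cum_mat[i, :k] = cum
    u = rng.random((r, n))
    idx = (u[:, :, None] >= cum_mat[None, :, :]).sum(axis=-1)
    thirds = opt_mat[np.arange(n)[None, :], idx]
    out = np.tile(seq_bytes, (r, 1))
    out[:, 2::3] = thirds
    return out


def _n3_batch(
    seq_bytes: np.ndarray,
    codons: list[str],
    r: int,
    rng: np.random.Generator,
    freeze_stops: bool,
) -> np.ndarray:
    out = np.tile(seq_bytes, (r, 1))
    groups: dict[str, list[int]] = {}
    for i, c in enumerate(codons):
        label = classify_codon(c, freeze_stops).label
        if label != "FIXED":
            groups.setdefault(label, []).append(i)
    for idxs in groups.values():
        pos = np.asarray([3 * i + 2 for i in idxs])
        vals = seq_bytes[pos]
        mat = np.tile(vals, (r, 1))
        mat = rng.permuted(mat, axis=1)
        out[:, pos] = mat
    return out


def _shuffle_batch_bytes(
    nucleotides: str,
    method: str,
    r: int,
    rng: np.random.Generator,
    *,
    gc3_include_fixed: bool = True,
    freeze_stops: bool = False,
) -> np.ndarray:
    seq_bytes = np.frombuffer(nucleotides.encode("ascii"), dtype=np.uint8).copy()
    codons = [nucleotides[i : i + 3] for i in range(0, len(nucleotides), 3)]
    if method == "gc3":
        g = gc3_content(nucleotides, gc3_include_fixed, freeze_stops)
        per_codon = [
            gc3_option_probabilities(c, g, freeze_stops) for c in codons
        ]
        return _categorical_batch(seq_bytes, per_codon, r, rng)
    if method == "dn23":
        freqs = dinucleotide_frequencies(nucleotides)
        per_codon = [
            dn23_option_weights(c, freqs, freeze_stops) for c in codons
        ]
        return _categorical_batch(seq_bytes, per_codon, r, rng)
    if method == "n3":
        return _n3_batch(seq_bytes, codons, r, rng, freeze_stops)
    raise ShuffleConfigError(f"unknown shuffle method {method!r}")


def shuffle_batch(
    seq: CodingSequence | str,
    method: str,
    r: int,
    rng: np.random.Generator,
    *,
    gc3_include_fixed: bool = True,
    freeze_stops: bool = False,
) -> list[str]:
    """``r`` shuffled copies of ``seq`` as raw strings (fast path)."""
    s = seq.nucleotides if isinstance(seq, CodingSequence) else seq
    mat = _shuffle_batch_bytes(
        s, method, r, rng,
        gc3_include_fixed=gc3_include_fixed, freeze_stops=freeze_stops,
    )
    return [row.tobytes().decode("ascii") for row in mat]


# ---------------------------------------------------------------------------
# public single-shuffle operations


def _single(seq: CodingSequence, method: str, rng: np.random.Generator,
            **kw) -> CodingSequence:
    (s,) = shuffle_batch(seq, method, 1, rng, **kw)
    return CodingSequence(s, seq.identifier)


def gc3_shuffle(seq: CodingSequence, rng: np.random.Generator,
                **kw) -> CodingSequence:
    """One GC3-corrected synonymous shuffle of ``seq``."""
    return _single(seq, "gc3", rng, **kw)


def n3_shuffle(seq: CodingSequence, rng: np.random.Generator,
               **kw) -> CodingSequence:
    """One base-composition-preserving within-class permutation of ``seq``."""
    return _single(seq, "n3", rng, **kw)


def dn23_shuffle(seq: CodingSequence, rng: np.random.Generator,
                 **kw) -> CodingSequence:
    """One dinucleotide-frequency-weighted synonymous shuffle of ``seq``."""
    return _single(seq, "dn23", rng, **kw)


def generate_null(
    seq: CodingSequence, cfg: ShuffleConfig
) -> Iterator[CodingSequence]:
    """Yield exactly ``cfg.replicates`` shuffles of ``seq``.

    Deterministic given ``cfg.seed``: one generator is seeded per call and
    replicates consume it sequentially.
    """
    rng = np.random.default_rng(cfg.seed)
    for i, s in enumerate(
        shuffle_batch(
            seq, cfg.method, cfg.replicates, rng,
            gc3_include_fixed=cfg.gc3_include_fixed,
            freeze_stops=cfg.freeze_stops,
        )
    ):
        yield CodingSequence(s, f"{seq.identifier}|{cfg.method}_{i}")
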