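"""Synthetic coding sequences, planted motif depletion, and exact oracles.

Everything here exists so the analysis can be exercised without any real
sequence data: :func:`random_cds` draws in-frame sequences with an exact
target third-position GC content, :func:`deplete_motif` builds positive
controls for under-representation by synonymously stripping a motif, and
:func:`enumerate_synonymous` / :func:`exact_shuffle_distribution` give
exhaustive ground truth for the shufflers on tiny inputs.

Generated peptides exclude Met and Trp (the single-codon amino acids) so
that every third position is adjustable and the target GC3 can be hit
exactly; stop codons are never generated.  Real coding sequences start
with Met and have biased amino-acid usage — see the methods note for
what that does and does not imply.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .codons import (
    CODON_TO_AA,
    CodingSequence,
    classify_codon,
    synonymous_options,
)
from .motifs import MotifSpec, _compiled, count_motifs, reverse_complement
from .shuffle import (
    dinucleotide_frequencies,
    dn23_option_weights,
    gc3_content,
    gc3_option_probabilities,
)

_GC = frozenset("GC")

#: amino acids with at least two codons (Met/Trp excluded)
_VARIABLE_AAS = "ACDEFGHIKLNPQRSTVY"

# amino acid -> list of codon families; a family is the tuple of synonymous
# codons sharing their first two positions (six-codon amino acids split into
# a two-codon and a four-codon family)
AA_TO_FAMILIES: dict[str, list[tuple[str, ...]]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa == "*":
        continue
    fams = AA_TO_FAMILIES.setdefault(_aa, [])
    fam = synonymous_options(_codon)
    if fam not in fams:
        fams.append(fam)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic CDS.

    ``n_codons`` codons, exact third-position GC fraction ``gc3``
    (realised as ``round(n_codons * gc3)`` G/C thirds), optionally
    followed by a synonymous depletion of ``deplete`` at strength
    ``deplete_strength``.
    """

    n_codons: int
    gc3: float = 0.5
    deplete: MotifSpec | None = None
    deplete_strength: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_codons < 2:
            raise ValueError("need at least 2 codons")
        if not 0.0 <= self.gc3 <= 1.0:
            raise ValueError("gc3 target must lie in [0, 1]")
        if not 0.0 <= self.deplete_strength <= 1.0:
            raise ValueError("depletion strength must lie in [0, 1]")


def cds_for_peptide(
    peptide: str,
    gc3: float,
    rng: np.random.Generator,
) -> CodingSequence:
    """Random codon realisation of ``peptide`` with exact GC3 where possible.

    For each residue a codon family is drawn uniformly; then exactly
    ``round(n * gc3)`` third positions are set to G/C (adjusted for any
    FIXED codons the peptide forces), drawing uniformly within the G/C or
    A/T options of each family.
    """
    n = len(peptide)
    families = []
    for aa in peptide:
        if aa not in AA_TO_FAMILIES:
            raise ValueError(f"unknown amino acid {aa!r}")
        fams = AA_TO_FAMILIES[aa]
        families.append(fams[rng.integers(len(fams))])
    k_target = int(round(n * gc3))
    fixed_gc = sum(
        1 for f in families if len(f) == 1 and f[0][2] in _GC
    )
    adjustable = [i for i, f in enumerate(families) if len(f) > 1]
    k_adj = min(max(k_target - fixed_gc, 0), len(adjustable))
    gc_slots = set(
        np.asarray(adjustable)[
            rng.choice(len(adjustable), size=k_adj, replace=False)
        ].tolist()
    ) if adjustable else set()
    codons = []
    for i, fam in enumerate(families):
        if len(fam) == 1:
            codons.append(fam[0])
            continue
        side = [c for c in fam if (c[2] in _GC) == (i in gc_slots)]
        codons.append(side[rng.integers(len(side))])
    return CodingSequence("".join(codons), "synthetic")


def random_peptide(n: int, rng: np.random.Generator) -> str:
    return "".join(
        _VARIABLE_AAS[i] for i in rng.integers(len(_VARIABLE_AAS), size=n)
    )


def random_cds(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> CodingSequence:
    """Draw a random in-frame CDS per ``spec`` (no stop codons, no Met/Trp)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    seq = cds_for_peptide(random_peptide(spec.n_codons, rng), spec.gc3, rng)
    if spec.deplete is not None:
        seq = deplete_motif(seq, spec.deplete, spec.deplete_strength)
    return seq


# ---------------------------------------------------------------------------
# planted depletion


def _window_count(window: str, motif: MotifSpec) -> int:
    n = 0
    if "top" in motif.effective_strands:
        n += sum(1 for _ in _compiled(motif.pattern).finditer(window))
    if "bottom" in motif.effective_strands:
        rc = reverse_complement(motif.pattern)
        n += sum(1 for _ in _compiled(rc).finditer(window))
    return n


def deplete_motif(
    seq: CodingSequence,
    motif: MotifSpec,
    strength: float = 1.0,
    freeze_stops: bool = False,
) -> CodingSequence:
    """Synonymously strip up to ``strength`` of the motif's occurrences.

    Greedy left-to-right passes: each codon is swapped for the synonymous
    option that most reduces the local occurrence count, until the
    requested fraction of the initial occurrences has been removed or no
    swap helps.  Only third positions move, so the depleted sequence
    stays inside the shuffle null's support and translation is preserved.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    s = list(seq.nucleotides)
    L = len(motif.pattern)
    initial = count_motifs(seq, motif)
    target = int(math.ceil(strength * initial - 1e-9))
    if target == 0 or initial == 0:
        return seq
    n = len(s) // 3
    removed = 0
    progress = True
    while removed < target and progress:
        progress = False
        for i in range(n):
            cur = "".join(s[3 * i : 3 * i + 3])
            opts = synonymous_options(cur, freeze_stops)
            if len(opts) == 1:
                continue
            lo = max(0, 3 * i - (L - 1))
            hi = min(len(s), 3 * i + 3 + (L - 1))
            head = "".join(s[lo : 3 * i])
            tail = "".join(s[3 * i + 3 : hi])
            cur_cnt = _window_count(head + cur + tail, motif)
            best_delta, best = 0, None
            for alt in opts:
                if alt == cur:
                    continue
                d = _window_count(head + alt + tail, motif) - cur_cnt
                if d < best_delta:
                    best_delta, best = d, alt
            if best is not None:
                s[3 * i : 3 * i + 3] = best
                removed += -best_delta
                progress = True
                if removed >= target:
                    break
    return CodingSequence("".join(s), seq.identifier)


# ---------------------------------------------------------------------------
# exhaustive oracles


def enumerate_synonymous(
    seq: CodingSequence, limit: int = 100_000, freeze_stops: bool = False
) -> list[CodingSequence]:
    """All sequences sharing ``seq``'s translation with positions 1-2 fixed.

    Guarded: raises if the product of per-codon option counts exceeds
    ``limit`` — use a smaller input for exhaustive checks.
    """
    per_codon = [synonymous_options(c, freeze_stops) for c in seq.codons()]
    total = math.prod(len(o) for o in per_codon)
    if total > limit:
        raise ValueError(
            f"{total} synonymous sequences exceed the enumeration guard "
            f"({limit}); use a shorter input"
        )
    return [
        CodingSequence("".join(combo), seq.identifier)
        for combo in itertools.product(*per_codon)
    ]


def exact_shuffle_distribution(
    seq: CodingSequence,
    method: str,
    *,
    gc3_include_fixed: bool = True,
    freeze_stops: bool = False,
    limit: int = 100_000,
) -> dict[str, float]:
    """Exact output distribution of one shuffle, for tiny inputs.

    gc3/dn23: product of the per-codon option probabilities.  n3: uniform
    over the orderings of each degeneracy class's third-position multiset
    (distinct arrangements weighted by their multiplicity).
    """
    codons = seq.codons()
    if method in ("gc3", "dn23"):
        if method == "gc3":
            g = gc3_content(seq, gc3_include_fixed, freeze_stops)
            per_codon = [
                gc3_option_probabilities(c, g, freeze_stops) for c in codons
            ]
        else:
            freqs = dinucleotide_frequencies(seq)
            per_codon = [
                dn23_option_weights(c, freqs, freeze_stops) for c in codons
            ]
        if math.prod(len(p) for p in per_codon) > limit:
            raise ValueError("input too large for exact enumeration")
        dist: dict[str, float] = {}
        for combo in itertools.product(*(p.items() for p in per_codon)):
            s = "".join(c for c, _ in combo)
            pr = math.prod(p for _, p in combo)
            dist[s] = dist.get(s, 0.0) + pr
        return dist
    if method == "n3":
        groups: dict[str, list[int]] = {}
        for i, c in enumerate(codons):
            label = classify_codon(c, freeze_stops).label
            if label != "FIXED":
                groups.setdefault(label, []).append(i)
        per_group: list[tuple[list[int], dict[tuple[str, ...], float]]] = []
        size = 1
        for idxs in groups.values():
            vals = tuple(codons[i][2] for i in idxs)
            arrangements = Counter(itertools.permutations(vals))
            total = sum(arrangements.values())
            per_group.append(
                (idxs, {a: c / total for a, c in arrangements.items()})
            )
            size *= len(arrangements)
            if size > limit:
                raise ValueError("input too large for exact enumeration")
        base = list(seq.nucleotides)
        dist = {}
        for combo in itertools.product(
            *(d.items() for _, d in per_group)
        ):
            s = base.copy()
            pr = 1.0
            for (idxs, _), (arrangement, p) in zip(per_group, combo):
                for i, b in zip(idxs, arrangement):
                    s[3 * i + 2] = b
                pr *= p
            key = "".join(s)
            dist[key] = dist.get(key, 0.0) + pr
        return dist
    raise ValueError(f"unknown shuffle method {method!r}")
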