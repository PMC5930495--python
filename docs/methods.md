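# Methods

## Model

A protein-coding sequence that evolved under cytidine-deaminase
mutational pressure may carry a deficit of deaminase mutation motifs, or
of motifs whose deamination would be nonsynonymous, relative to what its
protein sequence and composition would otherwise allow.  The null
hypothesis is that, conditional on the encoded protein and a chosen
compositional covariate, all synonymous realisations of the gene are
exchangeable.  The null distribution is built by Monte-Carlo: `r`
synonymous shuffles of the subject (default r = 1000), each touching
only third codon positions.

With the first two codon positions fixed, the standard genetic code
confines synonymous third-position changes to one of four degeneracy
classes — R (A/G), Y (C/T), H (A/C/T), N (any) — or to none (FIXED:
Met, Trp, and the TGA stop).  Six-codon amino acids split into a
two-codon and a four-codon family because the sub-families differ at
positions 1–2.  TAA/TAG interchange as an R-class family; a
`freeze_stops` switch (default off) pins all stops for conservative use.
Sequences with internal stops are accepted with a warning (viral ORF
annotations sometimes contain them); a strict flag rejects them.

## Shuffle schemes

**gc3** computes g, the G/C fraction at third positions over *all*
codons of the subject (FIXED included; `gc3_include_fixed=False`
excludes them), then redraws each non-FIXED third position
independently: probability mass g is split uniformly over the class's
G/C options and 1−g over its A/T options.  For the Ile family (H class)
with g = 0.6 this gives P(ATC) = 0.6, P(ATT) = P(ATA) = 0.2; for a Y
class, P(C) = g; for N, P(G) = P(C) = g/2.  This is the unique symmetric
extension of the worked Ile case.  If g ∈ {0, 1} empties the only
available side of a class the draw renormalises over the options that
remain.  The scheme corrects for GC3 in expectation; it conserves it
exactly in no single replicate, and its mean is exactly unbiased only
when the input has no FIXED codons (FIXED thirds enter g but are never
redrawn) — the calibration test therefore uses Met/Trp-free synthetic
inputs.

**n3** pools third-position nucleotides by degeneracy class and permutes
each pool without replacement.  Any base found in an R slot is A or G
and is synonymous in every other R slot (likewise Y, H, N), so both the
protein and the exact base multiset — hence GC content — are conserved.
Cross-class exchange (an H slot receiving a G from an N slot) could
break synonymy and is deliberately not performed; classes are strictly
disjoint here.

**dn23** tabulates the dinucleotide frequencies formed by codon
positions 2–3 across the subject (positions 3–1 bridging codons are not
used), then redraws each third position with probability proportional to
the frequency of the (position-2, candidate-base) dinucleotide,
normalised over the codon's synonymous options; if every option has zero
frequency the draw is uniform (a corner case, since a codon's own
dinucleotide is always represented unless the table was restricted).
The scheme *largely* maintains dinucleotide frequency and codon bias but
is not exactly unbiased: pooling the frequency table across degeneracy
classes makes the per-class normalisations differ from the pooled
frequencies on heterogeneous inputs.  Its calibration is therefore
asserted at the per-replicate SD scale (mean output frequency within 3
replicate SDs of the input), not at the Monte-Carlo SE of the mean —
measured bias on 100-codon inputs is ~0.01 in frequency, well inside a
replicate SD (~0.025).

All randomness flows from a single `numpy` generator seeded once per
run; identical (method, seed, input) reproduces the replicate stream
byte for byte.  Replicates are generated by a vectorised batch engine
(inverse-CDF categorical draws / axis-wise permutations), which keeps a
full default analysis (23 motifs, r = 1000, 200 codons, all bivariate
pairs) at ~2 s.

## Motif engine

A motif is an IUPAC pattern with a designated deaminated C
(`target_index`, defaulting to the rightmost literal C: deaminase motifs
place the mutated C 3′, and for CG the only C is position 0) and a
strand mode.  Scanning uses overlapping matches (deamination
opportunities are per-site; no dedup rule is imposed); bottom-strand
occurrences are matches of the reverse-complement pattern on the top
strand, with the mutated position projected as
`start + len − 1 − target_index` and the implied change G→A.  Motifs
overhanging the ends are not counted (linear topology).  A pattern equal
to its own reverse complement (CG) is scanned on the top strand only
under `both`, since each palindromic site would otherwise be double
counted.  A replacement transition is an occurrence whose implied
single-base change alters the encoded amino acid; changes creating or
destroying stops count as replacements.  Bottom- and top-strand hits in
the same codon are counted independently (counts are per-occurrence
throughout).

## Statistics

`belowX` is the strict empirical lower-tail estimate
`#{null < observed}/r`.  Strict counting follows the metric's standard
definition; it is anti-conservative for discrete counts at small r, so a
mid-p variant ((#less + #equal/2)/r) is available behind a flag, off by
default.  Replicates with zero motif occurrences have an undefined
replacement-transition fraction; these entries are dropped from the
fraction null (and logged), not imputed — a 0/0 carries no information
and imputing 0 would bias the null downward.  Null means and SDs
(`expectedX`, `expectedSdX`, …) use the sample SD (ddof = 1).

Bivariate metrics correlate the *replicate-level* metric vectors
(counts, replacement transitions, fractions) per motif pair — the only
reading that yields a usable joint distribution for conditioning — with
pairwise deletion of missing fraction entries; zero-variance vectors
report missing.  The conditional p-value approximates the joint null of
(X, Y) as bivariate normal: X | Y = y is normal with mean
`mx + ρ·(sx/sy)·(y − my)` and SD `sx·√(1−ρ²)`, and the reported value is
the lower-tail probability of the observed X.  Degenerate parameters
(|ρ| ≥ 1, zero SD) report missing with a warning; no continuity
correction is applied.  Raw p-values are reported for all 23 default
motifs without multiplicity adjustment; `BH_below*` keys add
Benjamini–Hochberg-adjusted columns as a clearly-separated convenience.
Conditional p-values are emitted for both orderings of each pair
(`pXcondY` ≠ `pYcondX`); correlations once per unordered pair.

Significance threshold q (default 0.05, must lie in (0, 0.5)):
`under` if p < q, `over` if p > 1−q, else `neutral`.

## Synthetic data

`random_cds` draws peptides uniformly over the 18 multi-codon amino
acids (no Met/Trp, no stops) and realises codons with an *exact* number
`round(n·gc3)` of G/C third positions, choosing uniformly within the
G/C or A/T side of each family.  This emulates the one covariate the
null models condition on (GC3) while deliberately ignoring features of
real genes: amino-acid usage bias, codon usage bias, CpG suppression,
dinucleotide structure, and the leading Met.  Passing tests on such
inputs therefore validates the *machinery* (conservation laws,
calibration, detection of planted depletion) — not any claim about how
strongly real viral genes deviate.  `deplete_motif` builds positive
controls by greedy synonymous swaps that minimise the local occurrence
count (window of ± pattern length around the changed codon), removing up
to the requested fraction of initial occurrences; only third positions
move, so depleted subjects remain inside the null's support and the
comparison stays fair.  `enumerate_synonymous` and
`exact_shuffle_distribution` provide exhaustive ground truth for inputs
whose synonymous space is ≤ 10⁵ sequences (guarded), used by the
goodness-of-fit tests at 10⁵ draws.

## Problem sizes and numerical choices

The calibration study uses 200 subjects of 200 codons at r = 500 with
the n3 scheme: under n3 the subject-as-null-draw construction is exactly
exchangeable with its own null (the third-position class multisets are
identical), making the type-I-error check sharp, and 200 codons give the
TC-count null enough spread (SD ≈ 4–5) that the discreteness of the
strict p-value stays within the binomial 99% band around 0.05.  The
positive control uses 50 trials of fully TAC-depleted 200-codon subjects
at r = 1000 against the gc3 null.  Goodness-of-fit tests compare 10⁵
sampler draws on a 5-codon toy against exact enumeration (chi-square).

Floating-point guards: per-codon cumulative probabilities are clamped to
end at exactly 1.0 before inverse-CDF sampling; `empirical_below`
returns missing (not 0) when the null is empty after dropping missing
entries; report serialisation uses 3 significant digits in `kv` mode
(display style) and full double precision in `tsv` mode (exact
round-trip).

## Limitations

- The bivariate-normal conditioning is an approximation; count metrics
  are discrete and can be skewed for rare motifs.
- dn23 maintains dinucleotide frequency only approximately (see above);
  codon-pair bias is not corrected by any scheme.
- Representation calls on real genes depend on the chosen covariate:
  gc3/n3 answer "given this GC content", dn23 "given this dinucleotide
  structure"; discordance between schemes is informative, not an error.
- No multiple-testing control is applied to the headline p-values; the
  BH columns are advisory.
- Analyses of published viral genes require the user to supply the exact
  CDS used; coding-region boundaries and isoform choice (e.g. spliced
  Rep-68) change the counts.
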