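# deamotif

Statistical detection of under- or over-representation of AID/APOBEC
cytidine-deaminase **mutation motifs** in protein-coding sequences.

AID and the APOBEC3 family deaminate C→U on single-stranded DNA inside
short preferred contexts — WRC for AID (W = A/T, R = A/G), TC for
APOBEC3A/B, CCC for APOBEC3G, with SYC the AID "coldspot".  A gene that
has evolved under this mutational pressure (a ssDNA virus, an EBV gene
expressed in germinal-center B cells) may carry *fewer* such motifs, or
fewer motifs whose deamination would change the protein, than chance
allows.  `deamotif` quantifies that.

## The method

Given an in-frame CDS (the *subject*), the null model is the set of
synonymous sequences evolution could equally have produced: `r`
shuffled sequences (default 1000) that encode exactly the same protein,
generated under one of three schemes that each correct for a different
compositional covariate:

| scheme | third positions are… | corrects for |
|--------|---------------------|--------------|
| `gc3`  | redrawn per codon: mass *g* (the subject's third-position GC fraction) split uniformly over the degeneracy class's G/C options, 1−*g* over its A/T options | GC3 content |
| `n3`   | pooled by degeneracy class (R, Y, H, N) and permuted without replacement | exact base composition |
| `dn23` | redrawn with weights proportional to the subject's (position-2, position-3) dinucleotide frequencies | dinucleotide frequency / codon bias |

For every motif X and every sequence, three statistics are measured:
(a) `observedX`, the number of motif occurrences on both strands
(overlaps counted, bottom-strand hits found via the reverse-complement
pattern); (b) `repTr_observedX`, the number of occurrences whose
simulated deamination (C→T, or G→A projected from the bottom strand) is
nonsynonymous; and (c) their ratio `repTrFrac_observedX`.  The
under-representation p-value `belowX` is the fraction of null replicates
strictly below the subject; `belowX < q` (default q = 0.05) reads as
under-representation and `belowX > 1−q` as over-representation.
Pairwise Pearson correlations of the replicate-level metrics
(`corXxY`, …) feed a bivariate-normal approximation that yields
conditional p-values (`pXcondY`, …): the representation of motif X given
the observed level of a potentially confounding motif Y (e.g. an APOBEC
motif conditional on CpG content).

The default motif vocabulary is the 23 patterns 4×NC, 16×NNC, WRC, SYC
and CG; a plain-text config file substitutes any IUPAC motifs/strands.

## Worked example

```sh
deamotif-simulate --codons 150 --gc3 0.55 --seed 3 --out demo.fasta
deamotif demo.fasta --shuffle gc3 -r 1000 --seed 7 --no-bivariate --out demo.kv
```

Selected lines of `demo.kv` (key↹value, 3 significant digits):

```
observedTAC     16
repTrFrac_observedTAC   0.625
expectedTAC     14.8
expectedSdTAC   3.29
belowTAC        0.597
repTrFrac_belowTAC      0.655
```

16 TAC motifs were observed against a null mean of 14.8 (SD 3.3);
59.7% of shuffled sequences carry fewer TAC motifs than the subject, so
this random sequence is — as it should be — neutral for TAC.  The same
applies to the replacement-transition fraction (0.625, p = 0.655).
A depleted positive control flips this: see
`examples/depletion_control.py`, which prints `belowTAC 0.000 -> under`
after synonymously stripping every TAC.

From Python:

```python
from deamotif import MotifSpec, ShuffleConfig, build_report, read_fasta

seq, = read_fasta("demo.fasta")
report = build_report(seq, ShuffleConfig("gc3", 1000, seed=7),
                      [MotifSpec("WRC"), MotifSpec("TC", target_index=1)])
print(report["belowWRC"], report.classification("WRC"))
```

The scripts in `examples/` each demonstrate one capability end to end
(basic report, shuffle conservation laws, planted-depletion control,
analysis of user-supplied viral CDS files).

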