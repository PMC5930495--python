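"""Motif-representation analysis of user-supplied viral coding sequences.

The AAV2 Rep-68 and HPV E6 coding sequences are classic subjects for the
TAC (AID hotspot) analysis: AAV2 is a ssDNA virus exposed to deaminases
and shows TAC under-representation, while HPV E6, expressed in epithelial
cells that AID never sees, is neutral.  No accession is bundled here —
fetch the in-frame CDS FASTA files yourself and pass them on the command
line:

    python examples/viral_reproduction.py rep68.fasta e6.fasta
"""

import sys

from deamotif import MotifSpec, ShuffleConfig, build_report, read_fasta

if len(sys.argv) < 2:
    sys.exit("usage: viral_reproduction.py CDS.fasta [CDS.fasta ...]")

tac = MotifSpec("TAC")
cfg = ShuffleConfig(method="gc3", replicates=1000, seed=1)
for path in sys.argv[1:]:
    for seq in read_fasta(path):
        report = build_report(seq, cfg, [tac], bivariate=False)
        print(f"== {seq.identifier} ==")
        for key in ("observedTAC", "repTr_observedTAC",
                    "repTrFrac_observedTAC", "expectedTAC", "expectedSdTAC",
                    "belowTAC", "repTr_belowTAC", "repTrFrac_belowTAC"):
            v = report[key]
            print(f"{key:24s} {v if isinstance(v, int) else f'{v:.3f}'}")
        print(f"TAC representation: {report.classification('TAC')}")
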