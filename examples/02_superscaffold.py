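"""Pileup consensus and nucleotide-over-protein precedence.

Three reads are placed on a 60 bp reference; the consensus is the strict
per-position majority, a tie is masked 'N', and uncovered positions stay
'-'. A protein consistency layer then fills part of the uncovered tail.
"""

import numpy as np

from capsid import pileup_assemble, build_superscaffold
from capsid.aln_io import Placement
from capsid.scaffold import AaLayer

ref_len = 60
rng = np.random.default_rng(0)
template = "".join(rng.choice(list("ACGT"), size=ref_len))

placements = [
    Placement("r1", "g", 0, template[0:30]),
    Placement("r2", "g", 10, template[10:40]),
    # r3 disagrees at position 12 -> still outvoted 2:1
    Placement("r3", "g", 10, "T" + template[11:40]),
]
pile = pileup_assemble("g", ref_len, placements)
print("nt consensus:", pile.consensus)

# a protein layer supporting positions 40..52 with base calls for 40..46
supported = np.zeros(ref_len, dtype=bool)
supported[40:52] = True
base = [""] * ref_len
for p in range(40, 46):
    base[p] = template[p]
layer = AaLayer("p1", "g", ref_len, supported, base)

scaffold = build_superscaffold("g", pile, [layer])
print("scaffold:    ", scaffold.seq)
print("sources:     ", "".join({"nt": "n", "aa": "a", "none": "."}[s] for s in scaffold.source))
print(
    "\n'n' positions come from the read pileup, 'a' from the protein layer"
    "\n(masked 'N' where the layer asserts coding support but no base call),"
    "\nand '.' positions have no evidence at all."
)
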