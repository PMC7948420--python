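"""Net-charge model of the Set2p N-terminal regulatory window.

The first 15 residues of the H3K36 methyltransferase Set2p hold a lysine
at position 3, three phosphorylatable serines (6, 8, 10) and the EDEKE
acidic patch (11-15). Counting +1 for the N-terminus and each K, -1 for
each D/E, -2 per phosphoserine, 0 for a S->A phosphonull and -1 for a
S->D phosphomimetic gives the local charge each mutant can carry.
"""

from ptmforge.context import SET2_NTERM15, SET2_PHOSPHOSITES, net_charge

cases = [
    ("wild type (S6/S8/S10 phosphorylated)", {}),
    ("single phosphonull S8A", {8: "A"}),
    ("triple phosphonull S6A/S8A/S10A", {6: "A", 8: "A", 10: "A"}),
    ("single phosphomimetic S8D", {8: "D"}),
    ("triple phosphomimetic S6D/S8D/S10D", {6: "D", 8: "D", 10: "D"}),
]
print(f"window: {SET2_NTERM15} (positions 1-15)\n")
for label, muts in cases:
    q = net_charge(SET2_NTERM15, SET2_PHOSPHOSITES, muts)
    print(f"{label:42s} net charge {q:+d}")
# A phosphomimetic aspartate restores only one of the two charges a
# phosphoserine carries, which is why S->D windows sit between the
# wild-type and S->A extremes.
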