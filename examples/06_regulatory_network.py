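"""Assemble a draft kinase -> histone-enzyme network from typed evidence.

Builds evidence tables with three planted true edges and noise records
that each fail an admission rule, applies the thresholds (motif score
> 2; perturbation p < 0.05 with sign-matched fold change; physical
interactions as protein-level evidence; genetic interactions only as
corroboration), and prints the resulting edge list.
"""

from ptmforge.network import admit_motif, admit_physical, admit_quant, assemble
from ptmforge.synth import gen_evidence_tables

planted = [
    {"regulator": "CKA1", "substrate": "SET2", "site": 6,
     "evidence_types": {"motif_prediction", "quant_perturbation"}, "genetic": True},
    {"regulator": "CKA1", "substrate": "RPH1",
     "evidence_types": {"physical_interaction"}},
    {"regulator": "GLC7", "substrate": "SET2", "site": 10,
     "regulator_class": "phosphatase", "evidence_types": {"quant_perturbation"}},
]
tables, _ = gen_evidence_tables(planted, n_noise_records=12, seed=8)

net = assemble(
    admit_motif(tables["motif"]),
    admit_quant(tables["quant"]),
    admit_physical(tables["physical"]),
    tables["genetic"],
)
print(net.edge_table().to_string(index=False))
# CKA1 touches two enzymes, so it is flagged a multi-substrate regulator;
# genetic-only noise pairs are absent because genetic interactions never
# create an edge on their own.
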