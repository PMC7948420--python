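import numpy as np
import pytest

from ptmforge import synth


@pytest.fixture
def protein():
    """A reproducible 400-residue protein rich in K/R/S/T."""
    return synth.gen_protein(400, {"K": 0.08, "R": 0.06, "S": 0.12, "T": 0.08}, seed=7)


@pytest.fixture
def planted_psms(protein):
    """PSM table with 10 planted phosphosites and threshold-straddling decoys."""
    sites = synth.choose_phospho_sites(protein, 10, seed=7)
    table, truth = synth.gen_psm_table(
        "ENZ1", protein, [(p, "phospho") for p in sites], n_psms=25, seed=7
    )
    return table, truth, {"ENZ1": protein}
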