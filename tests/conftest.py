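import numpy as np
import pytest

import cfduplex as cf
from cfduplex import digitize as dg


@pytest.fixture(scope="session")
def tiny_panel():
    """Two genes, 120 bp total: fast enough for property loops."""
    panel = cf.synthetic_panel(n_genes=2, total_bp=120, seed=3)
    panel.ensure_genome()
    return panel


@pytest.fixture(scope="session")
def lod_panel():
    """Single-gene fragment-sized panel used by dilution studies."""
    panel = cf.synthetic_panel(n_genes=1, total_bp=166, seed=11)
    panel.ensure_genome()
    return panel


@pytest.fixture(scope="session")
def noisy_params():
    """Deliberately dirty settings that exercise every error channel."""
    return cf.SimParams(
        molecules_per_position=8,
        per_base_error_rate=0.02,
        low_quality_fraction=0.1,
        pcr_duplicate_mean=2.5,
        pcr_lineage_error_rate=1e-3,
    )


def pileup_samples(panel, params, truths_list, rng):
    """Simulate + digitize each truth set; return pileups."""
    piles = []
    for truths in truths_list:
        _, reads = cf.simulate_sample(panel, truths, [], params, rng)
        cons = dg.digitize_reads(reads, panel=panel)
        piles.append(dg.pileup(cons, panel, reads))
    return piles
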