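import numpy as np
import pytest

import phagescape as ps


@pytest.fixture(scope="session")
def design():
    return ps.LibraryDesign()


@pytest.fixture(scope="session")
def small_run(design):
    """An error-free 10,000-read simulated run from a 500-peptide pool with a
    50/50 strand mixture, shared by the round-trip tests."""
    cfg = ps.SimulationConfig(
        n_tissues=1,
        n_reads_per_tissue=10_000,
        n_background_peptides=500,
        substitution_error_rate=0.0,
        sense_fraction=0.5,
        seed=7,
    )
    truth = ps.generate_peptide_pool(cfg)
    reads = [
        ps.ReadRecord(rid, seq, tuple(quals))
        for rid, seq, quals in ps.iter_reads(truth, design, cfg, "tissue_1")
    ]
    return cfg, truth, reads


@pytest.fixture()
def rng():
    return np.random.default_rng(20)
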