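import numpy as np
import pytest

from peroxmine.motifs import default_motif_table
from peroxmine.simulate import SimConfig, generate_proteome, generate_psms
from peroxmine.types import default_design


@pytest.fixture(scope="session")
def motif_table():
    return default_motif_table()


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def small_sim(design):
    """A small simulated experiment shared by read-only tests."""
    cfg = SimConfig(n_proteins=60, frac_perox=0.3, noise_sd=0.2, seed=11)
    rng = np.random.default_rng(cfg.seed)
    proteome, truth, orthomap, reference = generate_proteome(cfg, rng=rng)
    psms = generate_psms(proteome, truth, cfg, design, rng)
    return dict(
        config=cfg,
        proteome=proteome,
        truth=truth,
        orthomap=orthomap,
        reference=reference,
        psms=psms,
    )
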