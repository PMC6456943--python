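import numpy as np
import pytest

from kmerlock.panel_design import Panel, PanelEntity, SNPResidue, preprocess_panel
from kmerlock.rlwe_backend import PlainBackend, RlweBackend, toy_params
from kmerlock.synthetic_data import SimConfig, simulate_panel


def make_residue(rng, rid="r0", chrom="chr1", pos=1000, flank=200):
    from kmerlock.synthetic_data import random_dna

    ref = random_dna(rng, 1)
    alt = [b for b in "ACGT" if b != ref][rng.integers(3)]
    return SNPResidue(
        id=rid, chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
        flank5=random_dna(rng, flank), flank3=random_dna(rng, flank),
    )


def make_panel(n=3, flank=200, seed=0):
    """Independent residues, far apart, already preprocessed."""
    rng = np.random.default_rng(seed)
    residues = [
        make_residue(rng, rid=f"r{i}", pos=(i + 1) * 100_000, flank=flank)
        for i in range(n)
    ]
    return preprocess_panel(residues)


@pytest.fixture(scope="session")
def plain_backend():
    return PlainBackend(p=65537)


@pytest.fixture(scope="session")
def tiny_rlwe():
    """Small ring supporting a handful of multiplications; shared across tests."""
    params = toy_params(n=256, b_max=6)
    backend = RlweBackend(params, seed=1234)
    backend.ensure_rotation_keys(range(1, 64))
    return backend


@pytest.fixture(scope="session")
def small_sim():
    """5-residue panel with 200 bp flanks plus reads, fully deterministic."""
    from kmerlock.synthetic_data import simulate_reads

    cfg = SimConfig(n_residues=5, flank_len=200, depth=8, seed=77)
    residues, truth = simulate_panel(cfg)
    panel = preprocess_panel(residues)
    pairs = simulate_reads(panel, truth, cfg)
    return cfg, panel, truth, pairs
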