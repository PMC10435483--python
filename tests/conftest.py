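import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from catnet import synthetic as syn


SMALL = dict(
    n_chroms=1, chrom_length=400_000, n_genes=30, n_intragenic_enh=6,
    n_extragenic_enh=6, n_decoy_intragenic=2, n_decoy_extragenic=2,
    n_ncrna=2, read_depth=40_000,
)


@pytest.fixture(scope="session")
def small_sim():
    """Clean 30-gene genome without read artifacts (round-trip scenarios)."""
    cfg = syn.SimConfig(seed=11, mispriming_rate=0.0, intermediate_rate=0.0,
                        **SMALL)
    genome, ann = syn.simulate_genome(cfg)
    return cfg, genome, ann


@pytest.fixture(scope="session")
def artifact_sim():
    """10k-read genome with planted mispriming/intermediate artifacts."""
    cfg = syn.SimConfig(seed=12, mispriming_rate=0.05, intermediate_rate=0.02,
                        **{**SMALL, "read_depth": 10_000})
    genome, ann = syn.simulate_genome(cfg)
    track, counts = syn.simulate_occupancy(ann)
    reads = syn.simulate_reads(counts, genome, ann)
    return cfg, genome, ann, track, reads


@pytest.fixture(scope="session")
def default_sim():
    """Default 200-gene study-condition genome."""
    cfg = syn.SimConfig(seed=1)
    genome, ann = syn.simulate_genome(cfg)
    return cfg, genome, ann


@pytest.fixture(scope="session")
def default_tracks(default_sim):
    cfg, genome, ann = default_sim
    rng = np.random.default_rng(cfg.seed + 10)
    control = {f"c{i}": syn.simulate_occupancy(ann, rng=rng)[0] for i in range(3)}
    treated = {}
    contacts = None
    for i in range(3):
        tr, _, cts = syn.simulate_perturbation(ann, rng=rng)
        treated[f"t{i}"] = tr
        contacts = cts
    return control, treated, contacts
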