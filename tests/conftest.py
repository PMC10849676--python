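import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bmptargets.simulate as sim

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cfg() -> sim.SynthConfig:
    """The full default synthetic study (20 summits over 2 Mb, 3 lanes)."""
    return sim.default_config(seed=0)


@pytest.fixture(scope="session")
def small_cfg() -> sim.SynthConfig:
    """A reduced synthetic study for fast per-module tests."""
    cfg = sim.SynthConfig(
        seed=0,
        genome_length=200_000,
        n_chromosomes=1,
        n_lanes=2,
        n_chip_fragments=20_000,
        n_input_fragments=20_000,
        n_genes=12,
        planted_peaks=[("chr1", p, 4000.0) for p in (30_000, 80_000, 150_000)],
        planted_ortho_groups=[(f"NVE_g{i}", f"Dme_g{i}", f"Xla_g{i}") for i in range(1, 5)],
        planted_species_targets={
            "Nve": ["NVE_g1", "NVE_g2", "NVE_g3"],
            "Dme": ["Dme_g1", "Dme_g2"],
            "Xla": ["Xla_g1"],
        },
        planted_fold_enrichments={"chordin": {"transgenic": 1.82, "wildtype": 0.15}},
    )
    return cfg


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    """Generated fragments + truth for the reduced study (computed once)."""
    return sim.gen_chip_experiment(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
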