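import pytest

from metasgb.benchmark import build_reference
from metasgb.simulate import SimulationConfig

#: small catalog used by cross-module tests: 8 SGBs (half MAG-only), 40 genomes
TINY_CONFIG = SimulationConfig(
    n_fgbs=2,
    ggbs_per_fgb=2,
    sgbs_per_ggb=2,
    genomes_per_sgb=5,
    usgb_fraction=0.5,
    n_universal_genes=150,
    n_ggb_genes=20,
    n_sgb_genes=40,
    n_accessory_genes=5,
    n_reads=50_000,
)


@pytest.fixture(scope="session")
def tiny_ref():
    """A fully built small reference (catalog + bins + marker database)."""
    return build_reference(seed=7, config=TINY_CONFIG)
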