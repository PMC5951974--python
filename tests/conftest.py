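import numpy as np
import pytest

from gutstab import synthgenome as sg


def micro_config() -> sg.GenomeConfig:
    """Tiny genome for fast unit tests: 24-kb chromosome, 3 plasmids,
    2 short rRNA copies."""
    return sg.GenomeConfig(
        chrom_length=24_000,
        plasmids=[
            sg.PlasmidSpec("p1", 5_000, 0.0, 2),
            sg.PlasmidSpec("p2", 4_000, 0.4, 1),
            sg.PlasmidSpec("p4", 4_500, 0.3, 1),
        ],
        n_rrna=2,
        rrna_length=400,
    )


@pytest.fixture(scope="session")
def micro_ref() -> sg.ReferenceGenome:
    return sg.build_reference(micro_config(), seed=7)


@pytest.fixture(scope="session")
def desk_ref() -> sg.ReferenceGenome:
    """Desk-scale default reference (200-kb chromosome, 7 plasmids)."""
    return sg.build_reference(seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
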