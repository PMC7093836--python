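import numpy as np
import pytest

from satlib.pipeline import run_simulated_survey
from satlib.seqcore import SatFamily
from satlib.simulate import (
    AmplificationEvent,
    LibraryModelConfig,
    default_config,
    random_monomer,
)


@pytest.fixture(scope="session")
def full_survey():
    """The ten-species default design, simulated, sequenced and re-measured.

    Shared across tests: this is the expensive end-to-end run (a few
    minutes), so it is computed once per session with a fixed seed.
    """
    return run_simulated_survey(default_config(seed=7))


@pytest.fixture(scope="session")
def recovery_survey():
    """A low-divergence, high-coverage-per-family run for abundance recovery.

    One deeply sampled species pair on a short tree with mutation kept
    under a few percent; family fractions are large enough that shotgun
    sampling noise at 5x coverage sits well inside a 10% relative band.
    """
    rng = np.random.default_rng(11)
    config = LibraryModelConfig(
        newick="(A:1.0,(B:0.5,C:0.5)bc:0.5)r;",
        families=(
            (SatFamily("FAM1", random_monomer(170, rng)), 200),
            (SatFamily("FAM2", random_monomer(350, rng)), 60),
            (SatFamily("FAM3", random_monomer(170, rng)), 120),
        ),
        mu=0.01,  # <= 2% divergence over the deepest path
        amp_events=(AmplificationEvent("A", 0.2, "FAM1", window=1, factor=1.5),),
        background_genome_length=200_000,
        seed=11,
    )
    return run_simulated_survey(config, coverage=5.0, read_length=100)
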