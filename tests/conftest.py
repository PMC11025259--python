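import numpy as np
import pytest

from wexscape.core import ChromosomeModel, GenomeModel, Group, SampleMeta, Subtype
from wexscape.simulate import SimConfig, simulate_cohort
from wexscape.spectra import load_reference_signatures


@pytest.fixture(scope="session")
def genome():
    from wexscape.core import load_genome_model

    return load_genome_model()


@pytest.fixture(scope="session")
def toy_genome():
    """One 100 Mb chromosome with a centromere at 50–53 Mb."""
    return GenomeModel([
        ChromosomeModel("chr1", 100_000_000, 50_000_000, 53_000_000),
        ChromosomeModel("chr2", 80_000_000, 40_000_000, 43_000_000),
    ])


@pytest.fixture(scope="session")
def reference():
    return load_reference_signatures()


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort (2 samples per group x subtype)."""
    cfg = SimConfig(seed=11)
    cfg.n_per_cell = {k: 2 for k in cfg.n_per_cell}
    return simulate_cohort(cfg)


def make_meta(sample_id="S1", group=Group.IBC, subtype=Subtype.TN,
              purity=0.7, panel_size_mb=50.0, age=50.0, ploidy=2.0):
    return SampleMeta(sample_id=sample_id, group=group, subtype=subtype,
                      age=age, purity=purity, ploidy=ploidy,
                      panel_size_mb=panel_size_mb)
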