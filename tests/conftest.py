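import numpy as np
import pandas as pd
import pytest

from chimkin.fixture import load_relapse_pairs
from chimkin.simulate import (SimulationConfig, simulate_genotypes,
                              simulate_panel)


@pytest.fixture(scope="session")
def pairs():
    """The bundled clinical pair table."""
    return load_relapse_pairs()


@pytest.fixture(scope="session")
def sim_panel():
    return simulate_panel(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def sim_pair(sim_panel):
    """Unrelated recipient/donor genotypes on the session panel."""
    cfg = SimulationConfig(seed=101)
    return simulate_genotypes(cfg, sim_panel, rng=np.random.default_rng(202))


def make_noiseless_counts(genotypes, recipient_frac, depth=2000):
    """Exact expected read counts for a two-contributor mixture.

    The alt fraction at each locus is the dosage-weighted mixture exactly;
    depth is chosen so the expected counts are integers for the fractions
    used in tests.
    """
    subjects = list(genotypes)
    loci = list(genotypes[subjects[0]])
    fr = {subjects[0]: recipient_frac, subjects[1]: 1.0 - recipient_frac}
    rows = []
    for loc in loci:
        p = sum(fr[s] * genotypes[s][loc] / 2.0 for s in subjects)
        alt = p * depth
        assert abs(alt - round(alt)) < 1e-9, "pick depth giving integer counts"
        rows.append((loc, depth - round(alt), round(alt)))
    return pd.DataFrame(
        rows, columns=["locus_id", "ref_count", "alt_count"]
    ).set_index("locus_id")
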