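import numpy as np
import pytest

import strainpan as sp


@pytest.fixture(scope="session")
def small_panel():
    """5-strain panel with core, accessory and unique genes (rate 0.02)."""
    config = sp.PanelConfig(
        n_genomes=5,
        n_core=30,
        accessory_spec=[(2, 5), (4, 4)],
        n_unique_per_genome=3,
        substitution_rate=0.02,
        seed=42,
    )
    panel, truth = sp.simulate_panel(config)
    return config, panel, truth


@pytest.fixture(scope="session")
def small_panel_families(small_panel):
    """Ortholog inference run once on the 5-strain panel."""
    _config, panel, _truth = small_panel
    families, matrix = sp.panel_ortholog_families(panel)
    return families, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, n):
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, n)])


def random_protein(rng, n):
    aa = np.asarray(list("ARNDCQEGHILKMFPSTWYV"))
    return "".join(aa[rng.integers(0, 20, n)])
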