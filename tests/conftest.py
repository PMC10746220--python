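import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# property tests must behave identically on every run/machine
settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from eukmag import synth_fixtures as sf
from eukmag import trophic as tr


@pytest.fixture(scope="session")
def small_panel():
    """Small labelled KO panel shared by trophic tests (fast to generate)."""
    return sf.make_trophic_panel(
        sf.PanelSpec(n_refs_per_mode=40, n_kos=300, n_informative=60, seed=7)
    )


@pytest.fixture(scope="session")
def small_panel_matrix(small_panel):
    m = tr.profiles_to_matrix(small_panel.profiles)
    labels = [p.label for p in small_panel.profiles]
    return m, labels


@pytest.fixture(scope="session")
def planted_abundance():
    """Two planted 8-member communities, 60 samples, 4 background MAGs."""
    return sf.make_abundance_matrix(sf.AbundanceSimSpec(seed=3))


@pytest.fixture()
def toy_tree_newick():
    return "((A:1,B:2):1,C:4);"
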