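import numpy as np
import pandas as pd
import pytest

from coexnet import ModuleSpec, SyntheticDesign, generate_study_truth


@pytest.fixture(scope="session")
def three_module_design():
    return SyntheticDesign(
        modules=[
            ModuleSpec("M1", 100, factor_loading=0.9),
            ModuleSpec("M2", 80, factor_loading=0.9),
            ModuleSpec("M3", 60, factor_loading=0.9),
        ],
        n_background_genes=100,
        samples_per_group={"A": 40},
        noise_sd=0.5,
        seed=42,
    )


@pytest.fixture(scope="session")
def three_module_study(three_module_design):
    return generate_study_truth(three_module_design)


@pytest.fixture(scope="session")
def small_trait_study():
    """Two modules with trait effects, four groups, HIV-style phenotypes."""
    design = SyntheticDesign(
        modules=[
            ModuleSpec("M1", 40, factor_loading=0.9, trait_effect=0.6),
            ModuleSpec("M2", 30, factor_loading=0.9, trait_effect=-0.4),
        ],
        n_background_genes=60,
        samples_per_group={"A": 8, "B": 8, "C": 8, "D": 8},
        noise_sd=0.5,
        seed=7,
    )
    return generate_study_truth(design)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_expression(rng):
    data = rng.standard_normal((20, 12))
    return pd.DataFrame(
        data,
        index=[f"G{i:03d}" for i in range(20)],
        columns=[f"S{j:02d}" for j in range(12)],
    )
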