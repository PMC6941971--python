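import numpy as np
import pandas as pd
import pytest

from ttrans.compendium import z_transform
from ttrans.matching import fit_calibration
from ttrans.synthetic import simulate_cohorts, simulate_compendium


@pytest.fixture(scope="session")
def small_cohorts():
    """Three small cohorts with shared planted signatures."""
    cohorts, truth = simulate_cohorts(
        n_cohorts=3, n_patients=120, p_disease=16, p_genes=300, k=2,
        noise_sd=1.0, seed=11,
    )
    return cohorts, truth


@pytest.fixture(scope="session")
def planted_bundle(small_cohorts):
    """Small compendium with one causal suppressor target, z-scored, calibrated."""
    _, truth = small_cohorts
    comp, links, ctruth = simulate_compendium(
        n_drugs=120, n_cell_lines=3, n_targets=8, drugs_per_target=8,
        effect_size=5.0, noise_sd=1.0, B_true=truth.B_true, seed=12,
        p_genes=300,
    )
    comp = z_transform(comp)
    calib = fit_calibration(comp, links)
    return comp, links, ctruth, calib


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_link_frame(rows):
    return pd.DataFrame(rows, columns=["chemical", "protein", "combined_score"])
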