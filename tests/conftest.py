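import dendropy
import numpy as np
import pandas as pd
import pytest

from ocwmass import SimulationConfig, simulate_dataset


def make_dataset(**kwargs):
    """Simulated dataset with quiet defaults (no morphotypes/captivity/noise
    unless asked for), so tests state exactly which structure they need."""
    defaults = dict(
        n_species=60,
        residual_sd_log=0.0,
        individual_sd_log=0.0,
        lambda_signal=0.0,
        morphotype_fractions={},
        morphotype_shifts={},
        captive_fraction=0.0,
        seed=0,
    )
    defaults.update(kwargs)
    return simulate_dataset(SimulationConfig(**defaults))


@pytest.fixture
def noise_free_species():
    """Species exactly on the generating log-power curve."""
    return make_dataset(seed=11).species


@pytest.fixture
def noisy_species():
    """Species with iid lognormal scatter around the curve."""
    return make_dataset(residual_sd_log=0.3, seed=7).species


@pytest.fixture
def tree_abc():
    """Hand-readable tree ((A:1,B:1):1,C:2); A,B share one unit of path."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


def star_tree(labels, depth=1.0):
    data = "(" + ",".join(f"{l}:{depth:g}" for l in labels) + ");"
    return dendropy.Tree.get(data=data, schema="newick")
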