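import warnings

import numpy as np
import pandas as pd
import pytest

import methvar as mv
from methvar import synth


@pytest.fixture(scope="session")
def biased_dataset():
    """One chamber-biased replicate plate (gain 0.8 in chamber 1, red CV x1.5
    in chamber 8), shared across read-only tests."""
    cfg = synth.biased_scenario(n_probes=3000, seed=11)
    sheet, truth, lowlevel = synth.simulate_dataset(cfg)
    return cfg, sheet, truth, lowlevel


@pytest.fixture(scope="session")
def null_dataset():
    """A bias-free replicate plate."""
    cfg = synth.SimulationConfig(n_probes=3000, seed=7)
    sheet, truth, lowlevel = synth.simulate_dataset(cfg)
    return cfg, sheet, truth, lowlevel


@pytest.fixture(scope="session")
def biased_betas(biased_dataset):
    cfg, sheet, truth, lowlevel = biased_dataset
    return mv.clean_matrix(mv.betas_from_lowlevel(lowlevel))


def make_lowlevel(mean_green, mean_red, manifest=None, sd=None, n_beads=10):
    """Small hand-built LowLevelArraySet from per-channel arrays."""
    mean_green = np.asarray(mean_green, float)
    n_p, n_s = mean_green.shape
    if manifest is None:
        manifest = synth.make_manifest(n_p, type_i_fraction=0.0)
    probes = manifest.probe_ids
    samples = [f"s{j}" for j in range(n_s)]

    def frame(arr):
        return pd.DataFrame(np.asarray(arr, float), index=probes, columns=samples)

    sd_arr = np.zeros((n_p, n_s)) if sd is None else np.asarray(sd, float)
    nb = np.full((n_p, n_s), n_beads, dtype=int)
    return mv.LowLevelArraySet(
        manifest=manifest,
        mean_fi={"green": frame(mean_green), "red": frame(mean_red)},
        sd_fi={"green": frame(sd_arr), "red": frame(sd_arr)},
        n_beads={
            "green": pd.DataFrame(nb, index=probes, columns=samples),
            "red": pd.DataFrame(nb, index=probes, columns=samples),
        },
    )


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield
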