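import numpy as np
import pytest

import hoseeg as h


@pytest.fixture(scope="session")
def coupled_segments():
    """64 non-overlapping 64-sample segments of a coupled QPC record
    (f1=20 Hz, f2=30 Hz), phase-refreshed per segment."""
    spec = h.QPCSpec(f1=20.0, f2=30.0, coupled=True, noise_sd=0.05,
                     n_samples=4096, seed=7, phase_block=64)
    rec = h.gen_qpc_signal(spec)
    return rec.samples.reshape(64, 64)


@pytest.fixture(scope="session")
def uncoupled_segments():
    spec = h.QPCSpec(f1=20.0, f2=30.0, coupled=False, noise_sd=0.05,
                     n_samples=4096, seed=7, phase_block=64)
    rec = h.gen_qpc_signal(spec)
    return rec.samples.reshape(64, 64)


@pytest.fixture(scope="session")
def qpc_cell():
    """Grid cell of the (20, 30) Hz pair, ordered into the principal domain
    (f1 ≥ f2), on the nfft=64 grid."""
    grid = h.BiFrequencyGrid(nfft=64, fs=h.BONN_FS)
    i, j = grid.nearest_cell(20.0, 30.0)
    return max(i, j), min(i, j)


@pytest.fixture(scope="session")
def planted_feature_data():
    """A 47-feature two-class dataset where exactly features 11 and 29 are
    informative (3σ mean shift); everything else is pure noise."""
    rng = np.random.default_rng(42)
    n_per = 80
    X = rng.normal(0, 1, (2 * n_per, 47))
    y = np.array([0] * n_per + [1] * n_per)
    informative = (11, 29)
    for f in informative:
        X[y == 1, f] += 3.0
    return X, y, informative


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """A small synthetic three-class Bonn-like dataset on disk."""
    out = tmp_path_factory.mktemp("bonn_like")
    recipes = {
        k: h.ClassRecipe(r.class_label, r.qpc_band_pair, r.coupling_strength,
                         records_per_class=4, noise_sd=r.noise_sd)
        for k, r in h.DEFAULT_SET_RECIPES.items()
    }
    h.gen_bonn_like_dataset(out, recipes, seed=11)
    return out
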