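import numpy as np
import pytest

from physiodecode import SimConfig, simulate_dataset, simulate_latent_physio


@pytest.fixture(scope="session")
def latents_long():
    """Coupled band-limited latents, 600 frames at 1.44 s (~14.4 min)."""
    return simulate_latent_physio(600, dt=1.44, rho=0.275, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """Small simulated dataset shared by training-adjacent tests."""
    cfg = SimConfig(
        n_scans=24, n_rois=20, n_frames=250, varexp_target=0.25,
        scans_per_subject=4, seed=5,
    )
    scans, manifest = simulate_dataset(cfg)
    X = [s.roi_data.T for s in scans]
    y = [np.column_stack([s.rv_true, s.hr_true]) for s in scans]
    return cfg, scans, manifest, X, y
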