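import numpy as np
import pandas as pd
import pytest

from ne_awake import synth
from ne_awake.types import PhotometrySession


@pytest.fixture(scope="session")
def short_cfg():
    """A 5-minute session at the acquisition rate with default responses."""
    return synth.SimulationConfig(seed=7, duration_s=300.0)


@pytest.fixture(scope="session")
def clean_session():
    """Noiseless bleaching-only session plus its trial schedule."""
    cfg = synth.SimulationConfig(
        seed=3, duration_s=300.0, noise_sd=0.0, surge_amp=0.0, rise_amp=0.0
    )
    trials = synth.generate_trial_schedule(cfg)
    session, truth = synth.generate_photometry_session(cfg, trials)
    return cfg, trials, session, truth


@pytest.fixture()
def linear_session():
    """signal = 2*iso + 1 exactly, for closed-form fit recovery."""
    iso = 70.0 + np.sin(np.linspace(0, 6 * np.pi, 5000)) + np.linspace(0, -3, 5000)
    sig = 2.0 * iso + 1.0
    return PhotometrySession(signal=sig, isosbestic=iso, fs=100.0)


@pytest.fixture(scope="session")
def null_cell_table():
    """8-vs-7 animal cell-count table with identical group gradients."""
    table, _ = synth.generate_cell_counts(
        {"PRN": 8, "BF": 7}, missing_slice_prob=0.3, seed=21
    )
    return table


@pytest.fixture(scope="session")
def scored_trials():
    """Per-trial element scores across 7 mice with outcome labels."""
    rng = np.random.default_rng(5)
    rows = []
    for m in range(7):
        for i in range(20):
            outcome = "awakening" if i % 2 == 0 else "maintained"
            base = 1.0 if outcome == "awakening" else 0.3
            rows.append(
                {
                    "mouse": f"m{m}",
                    "trial_id": i,
                    "outcome": outcome,
                    "score": base + 0.2 * rng.normal(),
                    "drop": -base + 0.2 * rng.normal(),
                }
            )
    return pd.DataFrame(rows)
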