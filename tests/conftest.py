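"""Shared fixtures: small synthetic datasets and one reduced end-to-end
pipeline run reused across the integration tests."""

from __future__ import annotations

import numpy as np
import pytest

from synergyemg import emg_synth as es
from synergyemg.pipeline_cli import PipelineConfig, run_all


@pytest.fixture(scope="session")
def small_dataset():
    """A short noisy recording: 8 directions x 2 postures x 3 reps."""
    cfg = es.SimConfig.reduced(n_reps=3, seed=11)
    return es.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Sensor-noise-free recording for exact parameter-recovery checks."""
    cfg = es.SimConfig.reduced(n_reps=2, seed=5, snr_db=None,
                               baseline_snr_db=None)
    return es.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full reduced-scale pipeline run (10 reps/cell, 1024 Hz),
    shared by the end-to-end and acceptance tests."""
    out = tmp_path_factory.mktemp("pipeline") / "run.h5"
    cfg = PipelineConfig.from_dict({"seed": 1, "out": str(out)})
    manifest, state = run_all(cfg)
    return cfg, manifest, state


def tiny_pipeline_config(out_path, seed=3) -> PipelineConfig:
    """Desk-minimum pipeline configuration used by the smoke/resume and
    determinism tests (4 reps/cell, short trials, few training epochs)."""
    return PipelineConfig.from_dict({
        "seed": seed,
        "out": str(out_path),
        "simulate": {"n_reps": 5, "trial_duration_s": 1.6, "gap_s": 0.4},
        "ica": {"sample_stride": 12},
        "synergy": {"smax_emg": 8, "smax_ica": 6, "n_seeds": 2,
                    "max_iter": 150},
        "classify": {"epochs": 4},
    })


def planted_envelope_matrix(k: int, m: int, n: int, noise: float,
                            seed: int) -> np.ndarray:
    """Non-negative matrix with k planted synergies plus relative
    Gaussian noise of magnitude ``noise`` (rectified to keep E >= 0).

    Activations are smooth bumps on disjoint-ish time slots (the planted
    rank is unambiguous); synergy vectors have distinct dominant
    channels.
    """
    rng = np.random.default_rng(seed)
    # trial-structured recruitment: each synergy is active (smooth bump)
    # in its own sparse subset of trials, so the planted rank is
    # identifiable rather than compressible
    trial_len = 10
    n_trials = m // trial_len
    bump = np.hanning(trial_len)
    T = np.zeros((n_trials * trial_len, k))
    for tr in range(n_trials):
        active = rng.random(k) < 0.35
        if not active.any():
            active[rng.integers(k)] = True
        amps = np.where(active, rng.uniform(0.5, 1.5, k), 0.0)
        T[tr * trial_len:(tr + 1) * trial_len] = np.outer(bump, amps)
    if T.shape[0] < m:
        T = np.vstack([T, np.zeros((m - T.shape[0], k))])
    # near-disjoint dominant channels: every synergy carries a
    # comparable, non-redundant share of the variance
    M = 0.05 * rng.uniform(0, 1, (k, n))
    bounds = np.linspace(0, n, k + 1).astype(int)
    for j in range(k):
        M[j, bounds[j]:bounds[j + 1]] += rng.uniform(0.8, 1.2,
                                                     bounds[j + 1] - bounds[j])
    E = T @ M
    E += noise * E.std() * rng.standard_normal(E.shape)
    return np.clip(E, 0.0, None)
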