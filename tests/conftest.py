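"""Shared fixtures: compact phantom trials and frame-series builders."""

import logging

import numpy as np
import pytest

from hfoveit import phantom, preprocess
from hfoveit.core import GRID_COLS, GRID_ROWS, FrameSeries

logging.getLogger("hfoveit").setLevel(logging.ERROR)

# compact trial dimensions used throughout the suite: a 10-s analysis
# window (one 5-s amplitude block after edge trimming) inside 16-s steps
SHORT = dict(
    step_duration_s=16.0,
    analysis_len_s=10.0,
    baseline_duration_s=6.0,
    settle_tau_s=1.0,
)


def short_config(**overrides) -> phantom.PhantomConfig:
    kwargs = {**SHORT, **overrides}
    return phantom.PhantomConfig(**kwargs)


def run_pipeline(trial: phantom.PhantomTrial):
    """Baseline -> per-step maps for a phantom trial."""
    cfg = trial.config
    baseline = preprocess.compute_baseline(
        trial.series, (0.0, cfg.baseline_duration_s)
    )
    return preprocess.extract_step_maps(
        trial.series, trial.annotations, baseline, cfg.analysis_len_s
    )


@pytest.fixture(scope="session")
def compact_trial() -> phantom.PhantomTrial:
    """One deterministic low-noise trial reused across read-only tests."""
    return phantom.simulate_trial(short_config(seed=42))


@pytest.fixture(scope="session")
def compact_steps(compact_trial):
    return run_pipeline(compact_trial)


def make_series(
    pixel_fn,
    duration: float = 10.0,
    frame_rate: float = 40.0,
    f0: float = 9.0,
) -> FrameSeries:
    """Synthesize a frame series from ``pixel_fn(t) -> scalar or (1024,)``.

    The returned value at each time point is broadcast over the grid.
    """
    n = int(round(duration * frame_rate))
    times = np.arange(n) / frame_rate
    vals = np.asarray([np.broadcast_to(pixel_fn(t), (GRID_ROWS, GRID_COLS)) for t in times])
    return FrameSeries(
        times=times, frames=vals.astype(float), frame_rate=frame_rate, oscillation_hz=f0
    )
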