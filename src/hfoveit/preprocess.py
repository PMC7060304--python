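"""Signal conditioning: from raw pixel impedance series to per-step maps.

Every pixel time series mixes three components at very different time
scales: a slowly varying aeration level driven by the mean airway pressure,
the HFOV oscillation at the carrier frequency (9 Hz by default) and broadband
noise. The two maps the titration method needs are separated by linear
filtering:

* aeration / baseline use a low-pass at ``f0/4`` (2.25 Hz at the default
  carrier), removing the oscillation before taking window means or minima;
* ventilation uses a band-pass of ``f0 +/- 2`` Hz, then peak-to-peak
  amplitude per 5-s block, averaged over the blocks of the window.

All filters are 4th-order Butterworth applied forward-backward
(zero phase). The first and last second of each analysis window are
excluded from the statistics to discard filter edge transients; for
windows shorter than 7 s the trim shrinks so at least 5 s remain.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .core import (
    AerationMap,
    AnalysisError,
    BaselineMap,
    FrameSeries,
    StepMaps,
    VentilationMap,
)

BLOCK_LEN_S = 5.0
EDGE_TRIM_S = 1.0
BANDPASS_HALF_WIDTH_HZ = 2.0
FILTER_ORDER = 4


def _window_indices(series: FrameSeries, t_a: float, t_b: float) -> np.ndarray:
    if t_b <= t_a:
        raise AnalysisError(f"empty analysis window [{t_a}, {t_b}] s")
    tol = 0.5 / series.frame_rate
    # annotations mark half-open windows, so t_b may sit one frame past the
    # final sample
    if t_a < series.times[0] - tol or t_b > series.times[-1] + 2 * tol:
        raise AnalysisError(
            f"window [{t_a}, {t_b}] s outside recording "
            f"[{series.times[0]}, {series.times[-1]}] s"
        )
    idx = np.nonzero((series.times >= t_a - tol) & (series.times <= t_b + tol))[0]
    if len(idx) < 2:
        raise AnalysisError(f"window [{t_a}, {t_b}] s contains < 2 frames")
    return idx


def _edge_trim(n: int, window_len: float, frame_rate: float) -> slice:
    # full 1-s trim per side once >= 7 s, shrinking so >= 5 s always remain
    trim_s = min(EDGE_TRIM_S, max(0.0, (window_len - BLOCK_LEN_S) / 2.0))
    k = int(round(trim_s * frame_rate))
    k = min(k, max(0, (n - 2) // 2))
    return slice(k, n - k if k else n)

def _lowpass(x: np.ndarray, frame_rate: float, f0: float) -> np.ndarray:
    sos = signal.butter(FILTER_ORDER, f0 / 4.0, btype="low", fs=frame_rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def _bandpass(x: np.ndarray, frame_rate: float, f0: float) -> np.ndarray:
    lo = f0 - BANDPASS_HALF_WIDTH_HZ
    hi = min(f0 + BANDPASS_HALF_WIDTH_HZ, 0.499 * frame_rate)
    sos = signal.butter(FILTER_ORDER, (lo, hi), btype="band", fs=frame_rate, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def compute_baseline(
    series: FrameSeries, baseline_window: Tuple[float, float]
) -> BaselineMap:
    """Per-pixel baseline: minimum of the low-pass-filtered signal in the window.

    The reference state is the lowest aeration seen during the pre-trial
    (post-lavage) period, so all later aeration maps measure air content
    gained relative to the injured, de-recruited lung. Low-pass filtering
    before the minimum keeps oscillation troughs and noise spikes from
    being mistaken for the baseline.
    """
    t_a, t_b = baseline_window
    if t_b - t_a < BLOCK_LEN_S:
        raise AnalysisError(
            f"baseline window must be >= {BLOCK_LEN_S} s, got {t_b - t_a} s"
        )
    idx = _window_indices(series, t_a, t_b)
    seg = series.pixel_signals[idx]
    low = _lowpass(seg, series.frame_rate, series.oscillation_hz)
    keep = _edge_trim(len(idx), t_b - t_a, series.frame_rate)
    values = low[keep].min(axis=0)
    return BaselineMap(values.reshape(32, 32))


def oscillation_amplitude(
    series: FrameSeries, window: Tuple[float, float]
) -> VentilationMap:
    """Mean peak-to-peak oscillation amplitude per pixel over a window.

    The signal is band-passed around the carrier, the trimmed window is cut
    into consecutive 5-s blocks (trailing partial block discarded), the
    peak-to-peak excursion is taken per block and the blocks are averaged.
    A pure sine of amplitude A therefore reports 2A.
    """
    t_a, t_b = window
    idx = _window_indices(series, t_a, t_b)
    seg = series.pixel_signals[idx]
    band = _bandpass(seg, series.frame_rate, series.oscillation_hz)
    keep = _edge_trim(len(idx), t_b - t_a, series.frame_rate)
    band = band[keep]
    n_block = int(round(BLOCK_LEN_S * series.frame_rate))
    n_full = len(band) // n_block
    if n_full < 1:
        raise AnalysisError(
            f"window [{t_a}, {t_b}] s too short for one {BLOCK_LEN_S}-s "
            "amplitude block after edge trimming"
        )
    blocks = band[: n_full * n_block].reshape(n_full, n_block, -1)
    ptp = blocks.max(axis=1) - blocks.min(axis=1)
    values = ptp.mean(axis=0)
    return VentilationMap(np.maximum(values, 0.0).reshape(32, 32))


def aeration(
    series: FrameSeries,
    baseline: BaselineMap,
    window: Tuple[float, float],
) -> AerationMap:
    """Baseline-referenced mean aeration per pixel over a window."""
    t_a, t_b = window
    idx = _window_indices(series, t_a, t_b)
    seg = series.pixel_signals[idx]
    low = _lowpass(seg, series.frame_rate, series.oscillation_hz)
    keep = _edge_trim(len(idx), t_b - t_a, series.frame_rate)
    values = low[keep].mean(axis=0).reshape(32, 32) - baseline.values
    return AerationMap(values)


def extract_step_maps(
    series: FrameSeries,
    annotations: pd.DataFrame,
    baseline: BaselineMap,
    analysis_len: float = 60.0,
) -> List[StepMaps]:
    """Aeration + ventilation map pair for every annotated pressure step.

    Maps are computed over the final ``analysis_len`` seconds of each
    step's window (by default the last minute, letting the lung settle at
    the new pressure first). Output is ordered by decreasing mPaw, i.e. by
    ``step_index`` of the decremental trial.
    """
    steps: List[StepMaps] = []
    tol = 0.5 / series.frame_rate
    for _, row in annotations.sort_values("step_index").iterrows():
        t0, t1 = float(row["t_start_s"]), float(row["t_end_s"])
        if t1 - t0 < analysis_len - tol:
            raise AnalysisError(
                f"step {int(row['step_index'])} "
                f"(mPaw {row['mpaw_cmh2o']} cmH2O) lasts {t1 - t0:.1f} s, "
                f"shorter than the {analysis_len:.0f}-s analysis window"
            )
        window = (max(t0, t1 - analysis_len), t1)
        mpaw = float(row["mpaw_cmh2o"])
        aer = aeration(series, baseline, window)
        vent = oscillation_amplitude(series, window)
        aer.mpaw = mpaw
        vent.mpaw = mpaw
        steps.append(
            StepMaps(
                step_index=int(row["step_index"]),
                mpaw=mpaw,
                aeration=aer,
                ventilation=vent,
            )
        )
    return steps
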