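"""Core containers for EIT-guided mean-airway-pressure titration.

The pipeline works on a stream of reconstructed electrical impedance
tomography (EIT) images: a time-stamped sequence of 32x32 grids of relative
impedance acquired during high-frequency oscillatory ventilation (HFOV).
Rows run ventral (row 0) to dorsal (row 31); columns run from the subject's
left. From the stream, each pressure step of a decremental mean-airway-
pressure (mPaw) trial yields

* an :class:`AerationMap` -- baseline-referenced mean impedance, a proxy for
  regional end-expiratory air content, and
* a :class:`VentilationMap` -- amplitude of the oscillatory (carrier-
  frequency) impedance component, a proxy for regional tidal ventilation.

Region classification and the three titration strategies operate on these
per-step maps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

GRID_ROWS = 32
GRID_COLS = 32
N_PIXELS = GRID_ROWS * GRID_COLS

#: canonical pixel-order statement carried in sidecar metadata
PIXEL_ORDER = "row-major, row 1 = most ventral, column 1 = subject-left"


class ValidationError(ValueError):
    """An input file or in-memory structure violates a format invariant."""


class AnalysisError(ValueError):
    """A computation's precondition is not met (window, step count, ...)."""


def _as_grid(values, name: str) -> np.ndarray:
    # canonical maps are 32x32, but any 2-D grid with >= 2 rows is accepted
    # so the regional operators also work on reduced grids
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 1:
        raise ValidationError(
            f"{name}: expected a 2-D grid with >= 2 rows, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name}: values must be finite")
    return arr


@dataclass
class FrameSeries:
    """Time-stamped sequence of 32x32 relative-impedance grids.

    Parameters
    ----------
    times : (n,) array
        Frame time stamps in seconds, strictly increasing.
    frames : (n, 32, 32) array
        Relative impedance, arbitrary units. Row 0 is the most ventral row.
    frame_rate : float
        Nominal acquisition rate in Hz.
    oscillation_hz : float
        HFOV carrier (oscillator) frequency in Hz; must be resolvable,
        i.e. ``frame_rate > 2 * oscillation_hz``.
    """

    times: np.ndarray
    frames: np.ndarray
    frame_rate: float = 40.0
    oscillation_hz: float = 9.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValidationError("FrameSeries: need at least one frame")
        if self.frames.shape != (len(self.times), GRID_ROWS, GRID_COLS):
            raise ValidationError(
                "FrameSeries: frames shape "
                f"{self.frames.shape} does not match "
                f"({len(self.times)}, {GRID_ROWS}, {GRID_COLS})"
            )
        if not np.all(np.isfinite(self.times)) or not np.all(
            np.isfinite(self.frames)
        ):
            raise ValidationError("FrameSeries: values must be finite")
        dt = np.diff(self.times)
        if len(dt) and np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 1
            raise ValidationError(
                f"FrameSeries: time stamps not strictly increasing at frame {bad}"
            )
        if self.frame_rate <= 2.0 * self.oscillation_hz:
            raise ValidationError(
                "FrameSeries: frame_rate must exceed twice the oscillation "
                f"frequency ({self.frame_rate} Hz vs {self.oscillation_hz} Hz)"
            )
        if len(dt):
            nominal = 1.0 / self.frame_rate
            if np.max(np.abs(dt - nominal)) > 0.01 * nominal + 1e-12:
                raise ValidationError(
                    "FrameSeries: frame intervals deviate from the nominal "
                    "rate by more than 1%"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def pixel_signals(self) -> np.ndarray:
        """(n, 1024) row-major view of the frame stack."""
        return self.frames.reshape(len(self.times), N_PIXELS)


@dataclass
class BaselineMap:
    """Per-pixel baseline impedance (lowest filtered value in a window)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _as_grid(self.values, "BaselineMap")


@dataclass
class AerationMap:
    """Baseline-referenced mean impedance over a step's analysis window."""

    values: np.ndarray
    mpaw: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = _as_grid(self.values, "AerationMap")


@dataclass
class VentilationMap:
    """Mean oscillation (peak-to-peak) amplitude over the analysis window."""

    values: np.ndarray
    mpaw: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = _as_grid(self.values, "VentilationMap")
        if np.any(self.values < 0):
            raise ValidationError("VentilationMap: amplitudes must be >= 0")


@dataclass
class StepMaps:
    """Both maps for one pressure step of the decremental trial."""

    step_index: int
    mpaw: float
    aeration: AerationMap
    ventilation: VentilationMap


@dataclass
class LungMask:
    """Boolean 32x32 lung-region mask at one mPaw level."""

    mask: np.ndarray
    mpaw: Optional[float] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("LungMask: expected a 2-D boolean grid")

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class RegionResult:
    """Overdistension / recruitability classification at one step.

    ``overdistended`` is ``None`` for the lowest mPaw step: the limited-
    volume-change criterion compares each step with the adjacent lower
    pressure, so the bottom of the ladder has no partner.
    ``od_recruit_ratio`` is ``None`` when the recruitable count is zero
    (reported as missing, never as infinity).
    """

    mpaw: float
    overdistended: Optional[np.ndarray]
    n_overdistended: Optional[int]
    recruitable: np.ndarray
    n_recruitable: int
    od_recruit_ratio: Optional[float]


@dataclass
class StepAnalysis:
    """Per-step diagnostics produced by :func:`hfoveit.regional.analyze_series`."""

    step_index: int
    mpaw: float
    cov_pct: float
    lung: LungMask
    regions: Optional[RegionResult]


@dataclass
class MethodSelection:
    """Optimal mPaw chosen by one titration strategy."""

    method: str
    mpaw: Optional[float]
    note: Optional[str] = None


@dataclass
class TitrationResult:
    """Optimal mPaw by each strategy plus per-step diagnostic curves."""

    by_oxygenation: MethodSelection
    by_cov: MethodSelection
    by_regions: MethodSelection
    curves: "pd.DataFrame"  # noqa: F821 - imported lazily by callers
    disagreements: dict = field(default_factory=dict)

    def selections(self) -> dict:
        return {
            s.method: s
            for s in (self.by_oxygenation, self.by_cov, self.by_regions)
        }


def dorsal_fraction_rows(n_rows: int = GRID_ROWS) -> np.ndarray:
    """Row coordinate y in [0, 1]: 0 = most ventral row, 1 = most dorsal."""
    if n_rows < 2:
        raise ValueError("need at least two rows")
    return np.arange(n_rows, dtype=float) / (n_rows - 1)


def asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
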