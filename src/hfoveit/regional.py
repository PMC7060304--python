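"""Regional indices: center of ventilation, lung mask, overdistended and
recruitable regions, and the overdistension/recruitment ratio.

The classification is purely pixel-wise and threshold-based:

* a pixel belongs to the *lung region* at a step when its aeration gain over
  the lowest-pressure reference step exceeds 20% of the largest gain of any
  pixel at that step;
* a lung pixel is *overdistended* when raising the pressure to the adjacent
  higher step changes its aeration by less than 20% of the largest
  pixel change of that pair -- already full, more pressure adds no air;
* a pixel is *recruitable* when it is lung at the highest pressure but not
  at the current one -- collapsed now, but re-openable.

The 20% threshold is the method's single tuning constant and is exposed as
a parameter everywhere; inequalities are strict exactly as defined (">"
for the lung mask, "<" for limited change), so ties at the threshold fall
outside both sets.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    AerationMap,
    AnalysisError,
    LungMask,
    RegionResult,
    StepAnalysis,
    StepMaps,
    VentilationMap,
    dorsal_fraction_rows,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.20


def cov(vmap: VentilationMap | AerationMap) -> float:
    """Center of ventilation (CoV) in percent, 0 = ventral, 100 = dorsal.

    Ventilation-weighted mean of the ventral-to-dorsal row coordinate
    ``y = (row - 1)/(n_rows - 1)``, scaled to percent. Values above 50%
    mean ventilation concentrated in gravity-dependent (dorsal) regions.
    """
    values = vmap.values
    total = float(values.sum())
    if total <= 0:
        raise AnalysisError(
            "CoV undefined: total ventilation is zero (all-zero map)"
        )
    y = dorsal_fraction_rows(values.shape[0])
    return float((y @ values.sum(axis=1)) / total * 100.0)


def _check_same_grid(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if a.shape != b.shape:
        raise AnalysisError(f"{what}: grids differ in shape {a.shape} vs {b.shape}")


def lung_mask(
    aer_n: AerationMap,
    aer_ref: AerationMap,
    thr: float = DEFAULT_THRESHOLD,
) -> LungMask:
    """Lung region at a step, relative to the lowest-mPaw reference step.

    Pixel j is lung iff ``aer_n[j] - aer_ref[j] > thr * max(aer_n - aer_ref)``.
    If no pixel gains aeration over the reference (max difference <= 0)
    the mask is empty.
    """
    _check_same_grid(aer_n.values, aer_ref.values, "lung_mask")
    diff = aer_n.values - aer_ref.values
    max_diff = float(diff.max())
    if max_diff <= 0:
        mask = np.zeros_like(diff, dtype=bool)
    else:
        mask = diff > thr * max_diff
    return LungMask(mask, mpaw=aer_n.mpaw)


def overdistension_mask(
    aer_lower: AerationMap,
    aer_higher: AerationMap,
    lung_lower: LungMask,
    thr: float = DEFAULT_THRESHOLD,
) -> Tuple[np.ndarray, int]:
    """Overdistended pixels for the adjacent pair (lower, higher) pressure.

    A pixel is overdistended when its aeration change from the lower to the
    higher pressure stays below ``thr`` times the maximal pixel change of
    the pair (*limited volume change*) while the pixel already belongs to
    the lung region at the lower pressure. When no pixel gains aeration at
    the higher pressure the criterion is vacuous and the mask is empty.
    """
    _check_same_grid(aer_lower.values, aer_higher.values, "overdistension_mask")
    _check_same_grid(aer_lower.values, lung_lower.mask, "overdistension_mask")
    diff = aer_higher.values - aer_lower.values
    max_diff = float(diff.max())
    if max_diff <= 0:
        logger.warning(
            "overdistension_mask: no pixel gains aeration at the higher "
            "pressure (max diff %.3g <= 0); returning empty mask", max_diff
        )
        mask = np.zeros_like(diff, dtype=bool)
    else:
        mask = (diff < thr * max_diff) & lung_lower.mask
    return mask, int(mask.sum())


def recruitable_mask(
    lung_highest: LungMask, lung_n: LungMask
) -> Tuple[np.ndarray, int]:
    """Pixels that are lung at the highest mPaw but not at the current step."""
    _check_same_grid(lung_highest.mask, lung_n.mask, "recruitable_mask")
    mask = lung_highest.mask & ~lung_n.mask
    return mask, int(mask.sum())


def od_recruit_ratio(
    n_overdistended: Optional[int], n_recruitable: int
) -> Optional[float]:
    """Overdistended over recruitable pixel count; missing when undefined."""
    if n_overdistended is None or n_recruitable == 0:
        return None
    return float(n_overdistended) / float(n_recruitable)


def analyze_series(
    steps: Sequence[StepMaps],
    thr: float = DEFAULT_THRESHOLD,
    cov_source: str = "ventilation",
    strict_cov: bool = True,
) -> List[StepAnalysis]:
    """Per-step CoV and region classification for a decremental trial.

    Lung masks are computed for every step against the lowest step as the
    reference; recruitable pixels against the highest step's lung mask;
    overdistension for each adjacent pressure pair, attributed to the
    higher step of the pair -- the lowest step therefore carries no
    overdistension count (there is no lower pressure to compare with) and
    its region entry reports a missing overdistended value.

    With fewer than two steps region analysis is unavailable and only CoV
    is returned (``regions`` is ``None``).

    Parameters
    ----------
    cov_source : {"ventilation", "aeration"}
        Which map CoV weights are read from. The oscillation amplitude is
        the standard choice; aeration is offered for sensitivity analysis.
    strict_cov : bool
        With ``True`` (default) an all-zero map raises; with ``False`` the
        step's CoV is reported as NaN (useful for noiseless synthetic maps
        whose lowest step may be fully silent).
    """
    steps = list(steps)
    if not steps:
        raise AnalysisError("analyze_series: no steps")
    mpaws = [s.mpaw for s in steps]
    if any(b >= a for a, b in zip(mpaws, mpaws[1:])):
        raise AnalysisError(
            "analyze_series: steps must be ordered by strictly decreasing mPaw"
        )
    if cov_source not in ("ventilation", "aeration"):
        raise ValueError(f"unknown cov_source {cov_source!r}")

    def _cov(s: StepMaps) -> float:
        vmap = s.ventilation if cov_source == "ventilation" else s.aeration
        if not strict_cov and vmap.values.sum() <= 0:
            return float("nan")
        return cov(vmap)

    covs = [_cov(s) for s in steps]
    if len(steps) < 2:
        return [
            StepAnalysis(
                step_index=steps[0].step_index,
                mpaw=steps[0].mpaw,
                cov_pct=covs[0],
                lung=lung_mask(steps[0].aeration, steps[0].aeration, thr),
                regions=None,
            )
        ]

    ref = steps[-1].aeration  # lowest mPaw = reference level
    lungs = [lung_mask(s.aeration, ref, thr) for s in steps]
    highest = lungs[0]

    out: List[StepAnalysis] = []
    for k, s in enumerate(steps):
        rec_mask, n_rec = recruitable_mask(highest, lungs[k])
        if k + 1 < len(steps):
            # pair (lower = k+1, higher = k); attributed to the higher step
            od_mask, n_od = overdistension_mask(
                steps[k + 1].aeration, s.aeration, lungs[k + 1], thr
            )
        else:
            od_mask, n_od = None, None
        out.append(
            StepAnalysis(
                step_index=s.step_index,
                mpaw=s.mpaw,
                cov_pct=covs[k],
                lung=lungs[k],
                regions=RegionResult(
                    mpaw=s.mpaw,
                    overdistended=od_mask,
                    n_overdistended=n_od,
                    recruitable=rec_mask,
                    n_recruitable=n_rec,
                    od_recruit_ratio=od_recruit_ratio(n_od, n_rec),
                ),
            )
        )
    return out


def curves_frame(analysis: Sequence[StepAnalysis]) -> pd.DataFrame:
    """Tabular per-step diagnostic curves (one row per pressure step)."""
    rows = []
    for a in analysis:
        r = a.regions
        rows.append(
            {
                "step_index": a.step_index,
                "mpaw_cmh2o": a.mpaw,
                "cov_pct": a.cov_pct,
                "n_lung": a.lung.count,
                "n_overdistended": None if r is None else r.n_overdistended,
                "n_recruitable": None if r is None else r.n_recruitable,
                "od_recruit_ratio": None if r is None else r.od_recruit_ratio,
            }
        )
    return pd.DataFrame(rows)
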