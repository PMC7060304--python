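"""The three optimal-mPaw selection strategies and the combined titration.

All three strategies scan the decremental ladder (highest pressure first)
and must return one of the trial's own step pressures:

* **oxygenation** -- the step *before* the first step at which PaO2 falls by
  strictly more than 10% versus the immediately preceding step;
* **EIT-CoV** -- the step whose center of ventilation is closest to 50%
  (a balanced ventral/dorsal ventilation distribution);
* **EIT-regions** -- the step where the overdistended-count and
  recruitable-count curves intersect, or, failing an intersection, the step
  with the smallest sum of the two counts.

Every tie is resolved toward the *higher* pressure: the method's purpose is
avoiding derecruitment, so when two steps are equally good the more
recruitment-conservative one wins (each such resolution is logged).
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    AnalysisError,
    MethodSelection,
    StepMaps,
    TitrationResult,
)
from . import regional

logger = logging.getLogger(__name__)

NO_DROP_NOTE = "no-drop"


def select_by_oxygenation(
    mpaw: Sequence[float],
    pao2: Sequence[float],
    drop_frac: float = 0.10,
) -> MethodSelection:
    """Optimal mPaw by the oxygenation rule.

    Scanning in decremental order, the first step whose PaO2 lies more than
    ``drop_frac`` below the previous step's value marks the loss of
    recruitment; the previous step's pressure is returned. A drop of
    exactly ``drop_frac`` does not trigger (strict inequality). If no such
    drop occurs the lowest pressure is returned, flagged ``"no-drop"``.
    """
    mpaw = [float(p) for p in mpaw]
    if len(mpaw) < 2:
        raise AnalysisError("select_by_oxygenation: need >= 2 steps")
    if any(b >= a for a, b in zip(mpaw, mpaw[1:])):
        raise AnalysisError("select_by_oxygenation: mPaw must be decremental")
    vals = []
    for k, v in enumerate(pao2):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise AnalysisError(
                f"select_by_oxygenation: missing PaO2 at step with mPaw "
                f"{mpaw[k]} cmH2O"
            )
        vals.append(float(v))
    if len(vals) != len(mpaw):
        raise AnalysisError("select_by_oxygenation: PaO2/mPaw length mismatch")
    for k in range(1, len(vals)):
        if vals[k] < (1.0 - drop_frac) * vals[k - 1]:
            return MethodSelection(method="oxygenation", mpaw=mpaw[k - 1])
    return MethodSelection(
        method="oxygenation", mpaw=mpaw[-1], note=NO_DROP_NOTE
    )


def select_by_cov(
    mpaw: Sequence[float],
    cov_pct: Sequence[float],
    target: float = 50.0,
) -> MethodSelection:
    """Optimal mPaw by CoV: the step with CoV closest to the target (50%)."""
    pairs = [
        (float(p), float(c))
        for p, c in zip(mpaw, cov_pct)
        if c is not None and not (isinstance(c, float) and np.isnan(c))
    ]
    if not pairs:
        raise AnalysisError("select_by_cov: no step has a defined CoV")
    best_p, best_d = None, None
    for p, c in pairs:  # decremental order: first == higher mPaw wins ties
        d = abs(c - target)
        if best_d is None or d < best_d - 1e-12:
            best_p, best_d = p, d
        elif abs(d - best_d) <= 1e-12:
            logger.info(
                "select_by_cov: tie at |CoV-%.0f|=%.3g, keeping higher "
                "mPaw %.1f over %.1f", target, d, best_p, p
            )
    return MethodSelection(method="cov", mpaw=best_p)


def select_by_regions(
    mpaw: Sequence[float],
    n_overdistended: Sequence[Optional[int]],
    n_recruitable: Sequence[Optional[int]],
) -> MethodSelection:
    """Optimal mPaw by the overdistension/recruitability curves.

    Only steps where both counts are defined participate (the lowest step
    carries no overdistension count). With ``d = OD - recruit`` per step in
    decremental order: a step with ``d == 0`` is the intersection and is
    returned directly; when ``d`` changes sign between adjacent steps the
    flanking step with smaller ``|d|`` is returned (tie -> higher mPaw);
    with no sign change, the step minimizing ``OD + recruit`` is returned
    (tie -> higher mPaw).
    """
    def _defined(v) -> bool:
        return v is not None and not (isinstance(v, float) and np.isnan(v))

    rows = [
        (float(p), int(od), int(rc))
        for p, od, rc in zip(mpaw, n_overdistended, n_recruitable)
        if _defined(od) and _defined(rc)
    ]
    if len(rows) < 1:
        raise AnalysisError(
            "select_by_regions: no step has both region counts defined"
        )
    d = [od - rc for _, od, rc in rows]
    for k in range(len(rows)):
        if d[k] == 0:
            return MethodSelection(method="regions", mpaw=rows[k][0])
        if k + 1 < len(rows) and (d[k] > 0) != (d[k + 1] > 0) and d[k + 1] != 0:
            if abs(d[k + 1]) < abs(d[k]):
                return MethodSelection(method="regions", mpaw=rows[k + 1][0])
            if abs(d[k + 1]) == abs(d[k]):
                logger.info(
                    "select_by_regions: |OD-recruit| tie across the "
                    "intersection, keeping higher mPaw %.1f", rows[k][0]
                )
            return MethodSelection(method="regions", mpaw=rows[k][0])
    sums = [od + rc for _, od, rc in rows]
    best = min(range(len(rows)), key=lambda k: (sums[k], k))
    if sums.count(sums[best]) > 1:
        logger.info(
            "select_by_regions: OD+recruit tie, keeping higher mPaw %.1f",
            rows[best][0],
        )
    return MethodSelection(method="regions", mpaw=rows[best][0])


def titrate(
    steps: Sequence[StepMaps],
    blood_gas: pd.DataFrame,
    thr: float = regional.DEFAULT_THRESHOLD,
    drop_frac: float = 0.10,
    cov_target: float = 50.0,
    cov_source: str = "ventilation",
) -> TitrationResult:
    """Run all three strategies on a preprocessed trial.

    Parameters
    ----------
    steps
        Per-step map pairs ordered by decreasing mPaw (preprocess output).
    blood_gas
        Validated blood-gas table with one row per ``step_index``.
    """
    steps = list(steps)
    if len(steps) < 2:
        raise AnalysisError(
            "titrate: need >= 2 pressure steps for a decremental trial"
        )
    analysis = regional.analyze_series(steps, thr=thr, cov_source=cov_source)
    curves = regional.curves_frame(analysis)

    bg = blood_gas.set_index("step_index")
    pao2, fio2 = [], []
    for s in steps:
        if s.step_index not in bg.index:
            raise AnalysisError(
                f"titrate: no blood-gas row for step_index {s.step_index}"
            )
        pao2.append(float(bg.loc[s.step_index, "pao2_mmhg"]))
        fio2.append(float(bg.loc[s.step_index, "fio2"]))
    curves["pao2_mmhg"] = pao2
    curves["fio2"] = fio2
    curves["pf_ratio_mmhg"] = np.asarray(pao2) / np.asarray(fio2)

    mpaws = [s.mpaw for s in steps]
    sel_ox = select_by_oxygenation(mpaws, pao2, drop_frac=drop_frac)
    sel_cov = select_by_cov(mpaws, list(curves["cov_pct"]), target=cov_target)
    sel_reg = select_by_regions(
        mpaws,
        list(curves["n_overdistended"]),
        list(curves["n_recruitable"]),
    )

    def _diff(a: MethodSelection, b: MethodSelection) -> Optional[float]:
        if a.mpaw is None or b.mpaw is None:
            return None
        return float(a.mpaw - b.mpaw)

    disagreements = {
        "oxygenation_vs_cov": _diff(sel_ox, sel_cov),
        "oxygenation_vs_regions": _diff(sel_ox, sel_reg),
        "cov_vs_regions": _diff(sel_cov, sel_reg),
    }
    return TitrationResult(
        by_oxygenation=sel_ox,
        by_cov=sel_cov,
        by_regions=sel_reg,
        curves=curves,
        disagreements=disagreements,
    )
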