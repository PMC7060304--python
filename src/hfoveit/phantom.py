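"""Synthetic decremental-HFOV trial generator with planted ground truth.

No public EIT recording of a decremental HFOV trial exists, so every
pipeline stage is validated against a lung phantom with known regional
behavior. The generative model is deliberately minimal -- validation
scaffolding, not physiology:

* the imaged slice holds two elliptical lung fields on a 32x32 grid, rows
  running ventral (row 0) to dorsal (row 31);
* each lung pixel has a *closing pressure* (below it the pixel collapses,
  aeration 0 -- drawn with a gravity gradient, dorsal pixels closing at
  higher pressures), an *opening pressure* above the closing pressure, and
  a *saturation pressure* above which extra pressure adds almost no air;
* between those bounds the aeration response is piecewise linear with a
  per-pixel gain, i.e. ``a(P) = g * (min(P, P_sat) - P_close)`` for open
  pixels -- a sigmoid flattened to its three regimes so that planted
  collapse/saturation schedules translate exactly into region counts;
* the oscillatory component rides on the aeration level at the HFOV
  carrier frequency with amplitude proportional to the local compliance
  (the slope of the aeration response): collapsed pixels do not oscillate
  and saturated pixels barely do;
* PaO2 falls with the collapsed-pixel fraction (shunt) and mildly with the
  saturated fraction, with additive noise; FiO2 is 1.0 throughout.

The trial emits the exact on-disk formats of :mod:`hfoveit.io_formats`;
the same seed reproduces the files byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import regional
from .core import (
    GRID_COLS,
    GRID_ROWS,
    AerationMap,
    FrameSeries,
    StepMaps,
    ValidationError,
    VentilationMap,
    dorsal_fraction_rows,
)
from .io_formats import (
    write_blood_gas,
    write_frame_series,
    write_step_annotations,
)

DEFAULT_LADDER = tuple(float(p) for p in range(36, 8, -3))  # 36 -> 9 cmH2O


@dataclass
class PhantomConfig:
    """Parameters of one simulated decremental trial (all pressures cmH2O)."""

    ladder: Tuple[float, ...] = DEFAULT_LADDER
    step_duration_s: float = 75.0
    analysis_len_s: float = 60.0
    baseline_duration_s: float = 10.0
    frame_rate_hz: float = 40.0
    oscillation_hz: float = 9.0
    # lung geometry: two ellipses (row_center, col_center, row_semi, col_semi)
    lung_ellipses: Tuple[Tuple[float, float, float, float], ...] = (
        (15.5, 9.5, 9.5, 5.5),
        (15.5, 22.5, 9.5, 5.5),
    )
    # per-pixel pressure thresholds: mean = ventral value + grad * y, y in [0,1]
    closing_mu_ventral: float = -2.0
    closing_grad: float = 24.0
    closing_sd: float = 3.0
    opening_offset: float = 6.0
    sat_mu_ventral: float = 14.0
    sat_grad: float = 36.0
    sat_sd: float = 3.0
    sat_margin: float = 3.0
    # fraction of lung pixels that never saturate in the trial's range,
    # keeping the pair-wise maximal aeration gain well defined
    sat_exempt_frac: float = 0.0
    # aeration response
    gain: float = 1.0
    gain_sd: float = 0.10
    # linear ventral/dorsal compliance tilt: gain *= 1 + gain_tilt*(y - 0.5)
    gain_tilt: float = 0.0
    sat_slope_frac: float = 0.01
    tissue_baseline: float = 0.2
    background: float = 0.05
    settle_tau_s: float = 3.0
    # oscillation: amplitude = osc_scale * local slope (units per cmH2O)
    osc_scale: float = 4.0
    noise_sd: float = 0.01
    # blood gas model
    pao2_max: float = 450.0
    pao2_collapse_coef: float = 420.0
    pao2_sat_coef: float = 30.0
    pao2_noise_sd: float = 5.0
    pao2_min: float = 35.0
    fio2: float = 1.0
    # HFOV settings carried as metadata (waveform is a pure carrier sine)
    inspiratory_time_frac: float = 0.33
    delta_pressure_cmh2o: float = 70.0
    seed: int = 0
    p_star: Optional[float] = None  # planted open-lung pressure, if any

    def __post_init__(self) -> None:
        ladder = tuple(float(p) for p in self.ladder)
        if len(ladder) < 1 or any(b >= a for a, b in zip(ladder, ladder[1:])):
            raise ValidationError("PhantomConfig: ladder must be strictly decreasing")
        self.ladder = ladder
        if self.opening_offset <= 0:
            raise ValidationError(
                "PhantomConfig: opening pressure must exceed closing pressure "
                "(opening_offset > 0)"
            )
        if self.step_duration_s < self.analysis_len_s:
            raise ValidationError(
                "PhantomConfig: step_duration_s must cover analysis_len_s"
            )
        if self.baseline_duration_s < 5.0:
            raise ValidationError("PhantomConfig: baseline segment must be >= 5 s")


@dataclass
class GroundTruth:
    """Planted per-step truth of a phantom trial (noise-free model state)."""

    mpaw: np.ndarray
    collapsed: List[np.ndarray]  # closing pressure above current mPaw
    saturated: List[np.ndarray]  # saturation pressure at/below current mPaw
    lung_masks: List[np.ndarray]  # threshold rule on noiseless aeration maps
    od_counts: List[Optional[int]]
    recruit_counts: List[int]
    cov_pct: np.ndarray
    pao2_mmhg: np.ndarray  # before noise
    aeration_maps: List[np.ndarray]
    ventilation_maps: List[np.ndarray]
    baseline_map: np.ndarray
    template: np.ndarray
    p_star: Optional[float] = None


@dataclass
class PhantomTrial:
    """One simulated subject: raw stream, tables and ground truth."""

    series: FrameSeries
    annotations: pd.DataFrame
    blood_gas: pd.DataFrame
    truth: GroundTruth
    config: PhantomConfig


def lung_template(config: PhantomConfig) -> np.ndarray:
    """Boolean 32x32 template of the two elliptical lung fields."""
    rows, cols = np.mgrid[0:GRID_ROWS, 0:GRID_COLS]
    mask = np.zeros((GRID_ROWS, GRID_COLS), dtype=bool)
    for rc, cc, rs, cs in config.lung_ellipses:
        mask |= ((rows - rc) / rs) ** 2 + ((cols - cc) / cs) ** 2 <= 1.0
    return mask


def _draw_pixel_fields(config: PhantomConfig, rng: np.random.Generator):
    """Per-pixel closing/opening/saturation pressures and gains."""
    template = lung_template(config)
    y = dorsal_fraction_rows()[:, None] * np.ones((1, GRID_COLS))
    closing = rng.normal(
        config.closing_mu_ventral + config.closing_grad * y, config.closing_sd
    )
    closing = np.clip(closing, 0.5, 40.0)
    opening = closing + config.opening_offset
    sat = rng.normal(
        config.sat_mu_ventral + config.sat_grad * y, config.sat_sd
    )
    sat = np.maximum(sat, closing + config.sat_margin)
    if config.sat_exempt_frac > 0:
        exempt = rng.random(sat.shape) < config.sat_exempt_frac
        sat = np.where(exempt, 1e9, sat)
    gains = np.clip(rng.normal(config.gain, config.gain_sd, y.shape), 0.2, None)
    gains = gains * np.clip(1.0 + config.gain_tilt * (y - 0.5), 0.1, None)
    return template, closing, opening, sat, gains


def _response(
    P: float,
    template: np.ndarray,
    closing: np.ndarray,
    sat: np.ndarray,
    gains: np.ndarray,
    config: PhantomConfig,
) -> Tuple[np.ndarray, np.ndarray]:
    """Noiseless (aeration, oscillation peak-to-peak) maps at pressure P."""
    open_px = template & (closing <= P)
    aer = np.where(open_px, gains * (np.minimum(P, sat) - closing), 0.0)
    slope = np.where(
        open_px, np.where(sat <= P, config.sat_slope_frac * gains, gains), 0.0
    )
    ptp = 2.0 * config.osc_scale * slope
    return aer, ptp


def _ground_truth(
    config: PhantomConfig,
    template: np.ndarray,
    closing: np.ndarray,
    sat: np.ndarray,
    gains: np.ndarray,
) -> GroundTruth:
    ladder = np.asarray(config.ladder)
    aer_maps, vent_maps, collapsed, saturated = [], [], [], []
    for P in ladder:
        aer, ptp = _response(P, template, closing, sat, gains, config)
        aer_maps.append(aer)
        vent_maps.append(ptp)
        collapsed.append(template & (closing > P))
        saturated.append(template & (closing <= P) & (sat <= P))

    # region classification of the noiseless model maps (what a perfect
    # measurement chain would recover)
    steps = [
        StepMaps(
            step_index=k,
            mpaw=float(P),
            aeration=AerationMap(aer_maps[k], mpaw=float(P)),
            ventilation=VentilationMap(vent_maps[k], mpaw=float(P)),
        )
        for k, P in enumerate(ladder)
    ]
    if len(steps) >= 2:
        analysis = regional.analyze_series(steps, strict_cov=False)
        lung_masks = [a.lung.mask for a in analysis]
        od_counts = [a.regions.n_overdistended for a in analysis]
        recruit_counts = [a.regions.n_recruitable for a in analysis]
        cov_pct = np.array([a.cov_pct for a in analysis])
    else:
        lung_masks = [np.zeros_like(template)]
        od_counts, recruit_counts = [None], [0]
        cov_pct = np.array([regional.cov(steps[0].ventilation)])

    n_template = max(int(template.sum()), 1)
    cf = np.array([c.sum() / n_template for c in collapsed])
    sf = np.array([s.sum() / n_template for s in saturated])
    pao2 = np.clip(
        config.pao2_max
        - config.pao2_collapse_coef * cf
        - config.pao2_sat_coef * sf,
        config.pao2_min,
        None,
    )
    baseline = np.where(template, config.tissue_baseline, config.background)
    return GroundTruth(
        mpaw=ladder,
        collapsed=collapsed,
        saturated=saturated,
        lung_masks=lung_masks,
        od_counts=od_counts,
        recruit_counts=recruit_counts,
        cov_pct=cov_pct,
        pao2_mmhg=pao2,
        aeration_maps=aer_maps,
        ventilation_maps=vent_maps,
        baseline_map=baseline,
        template=template,
        p_star=config.p_star,
    )


def simulate_trial(config: PhantomConfig) -> PhantomTrial:
    """Simulate one decremental trial; fully determined by ``config.seed``.

    The recording opens with a pre-trial segment at the injured,
    de-recruited state (the baseline reference) and then walks the pressure
    ladder, each step settling exponentially toward its aeration level with
    the carrier-frequency oscillation riding on top.
    """
    rng = np.random.default_rng(config.seed)
    template, closing, opening, sat_p, gains = _draw_pixel_fields(config, rng)
    truth = _ground_truth(config, template, closing, sat_p, gains)

    fs = config.frame_rate_hz
    n_base = int(round(config.baseline_duration_s * fs))
    n_step = int(round(config.step_duration_s * fs))
    n_total = n_base + n_step * len(config.ladder)
    times = np.arange(n_total) / fs

    base_level = truth.baseline_map.ravel()
    levels = [base_level + a.ravel() for a in truth.aeration_maps]
    amps = [0.5 * v.ravel() for v in truth.ventilation_maps]  # sine amplitude

    signals = np.empty((n_total, base_level.size))
    signals[:n_base] = base_level
    prev = base_level
    carrier = np.sin(2.0 * np.pi * config.oscillation_hz * times)
    rows = []
    for k in range(len(config.ladder)):
        i0 = n_base + k * n_step
        i1 = i0 + n_step
        tau = max(config.settle_tau_s, 1e-6)
        decay = np.exp(-(times[i0:i1] - times[i0]) / tau)
        signals[i0:i1] = (
            levels[k][None, :]
            + (prev - levels[k])[None, :] * decay[:, None]
            + amps[k][None, :] * carrier[i0:i1, None]
        )
        prev = levels[k]
        rows.append(
            {
                "step_index": k,
                "mpaw_cmh2o": config.ladder[k],
                "t_start_s": i0 / fs,
                "t_end_s": i1 / fs,
            }
        )
    if config.noise_sd > 0:
        signals += rng.normal(0.0, config.noise_sd, signals.shape)

    series = FrameSeries(
        times=times,
        frames=signals.reshape(n_total, GRID_ROWS, GRID_COLS),
        frame_rate=fs,
        oscillation_hz=config.oscillation_hz,
    )
    annotations = pd.DataFrame(rows)
    pao2 = truth.pao2_mmhg + rng.normal(
        0.0, config.pao2_noise_sd, len(config.ladder)
    )
    pao2 = np.clip(pao2, config.pao2_min, None)
    paco2 = 45.0 + 60.0 * np.array(
        [c.sum() / max(int(template.sum()), 1) for c in truth.collapsed]
    )
    blood_gas = pd.DataFrame(
        {
            "step_index": np.arange(len(config.ladder)),
            "pao2_mmhg": pao2,
            "paco2_mmhg": paco2,
            "fio2": config.fio2,
        }
    )
    return PhantomTrial(
        series=series,
        annotations=annotations,
        blood_gas=blood_gas,
        truth=truth,
        config=config,
    )


def write_trial(trial: PhantomTrial, out_dir) -> dict:
    """Write a trial's file set (frames, annotations, blood gas, truth)."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "frames": os.path.join(out_dir, "frames.csv"),
        "annotations": os.path.join(out_dir, "steps.csv"),
        "blood_gas": os.path.join(out_dir, "blood_gas.csv"),
        "ground_truth": os.path.join(out_dir, "ground_truth.json"),
    }
    write_frame_series(trial.series, paths["frames"])
    write_step_annotations(trial.annotations, paths["annotations"])
    write_blood_gas(trial.blood_gas, paths["blood_gas"])
    t = trial.truth
    truth_summary = {
        "mpaw_cmh2o": [float(p) for p in t.mpaw],
        "n_collapsed": [int(c.sum()) for c in t.collapsed],
        "n_saturated": [int(s.sum()) for s in t.saturated],
        "n_lung": [int(m.sum()) for m in t.lung_masks],
        "od_counts": [None if c is None else int(c) for c in t.od_counts],
        "recruit_counts": [int(c) for c in t.recruit_counts],
        "cov_pct": [float(c) for c in t.cov_pct],
        "pao2_mmhg": [float(p) for p in t.pao2_mmhg],
        "p_star": None if t.p_star is None else float(t.p_star),
        "seed": int(trial.config.seed),
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# planted-optimum and cohort construction
# ---------------------------------------------------------------------------

def planted_config(
    p_star: float,
    seed: int = 0,
    noise_sd: float = 0.02,
    **overrides,
) -> PhantomConfig:
    """Config whose overdistension/recruitability curves cross at ``p_star``.

    With the piecewise-linear response and a 3-cmH2O ladder, the
    overdistended count attributed to step P tracks pixels whose saturation
    pressure lies below P - 2.4 (the pair's lower pressure plus the 20%
    gain margin) and the recruitable count tracks pixels whose closing
    pressure lies above P - 0.2 (P - 9) (the lung-mask margin over the
    9-cmH2O reference). Equating the two normal tail fractions puts the
    crossing at ``(mu_sat + mu_close + 0.6) / 1.8``; the helper inverts
    that relation with the saturation mean pinned at ``p_star + 3``.
    """
    mu_sat = p_star + 3.0
    mu_close = 1.8 * p_star - 0.6 - mu_sat
    kwargs = dict(
        closing_mu_ventral=mu_close,
        closing_grad=0.0,
        closing_sd=3.0,
        sat_mu_ventral=mu_sat,
        sat_grad=0.0,
        sat_sd=3.0,
        gain_sd=0.0,
        sat_exempt_frac=0.05,
        noise_sd=noise_sd,
        seed=seed,
        p_star=p_star,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


def coincident_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Config on which all three titration strategies agree at 21 cmH2O.

    The lung fields sit slightly ventral of the grid center and the
    collapse/saturation fronts are balanced so that the ventilation
    distribution is centered (CoV = 50%) at the same step where the
    overdistended and recruitable curves intersect, while the shunt-driven
    PaO2 model first drops by more than 10% one step below it.
    """
    kwargs = dict(
        sat_mu_ventral=11.0,
        closing_mu_ventral=0.0,
        closing_grad=22.0,
        pao2_collapse_coef=1800.0,
        pao2_noise_sd=2.0,
        lung_ellipses=((14.5, 9.5, 9.5, 5.5), (14.5, 22.5, 9.5, 5.5)),
        seed=seed,
        p_star=21.0,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@dataclass
class CohortSpec:
    """Distribution of subject configs for a simulated cohort."""

    base: PhantomConfig = field(default_factory=PhantomConfig)
    closing_shift_sd: float = 1.5
    sat_shift_sd: float = 1.5
    gain_rel_sd: float = 0.10

    @property
    def is_degenerate(self) -> bool:
        """True when every subject is drawn identical to the base config."""
        return (
            self.closing_shift_sd == 0
            and self.sat_shift_sd == 0
            and self.gain_rel_sd == 0
        )

    def draw(self, rng: np.random.Generator, seed: int) -> PhantomConfig:
        if self.closing_shift_sd < 0 or self.sat_shift_sd < 0:
            raise ValidationError("CohortSpec: shift SDs must be >= 0")
        if self.is_degenerate:
            return replace(self.base)
        return replace(
            self.base,
            closing_mu_ventral=self.base.closing_mu_ventral
            + rng.normal(0.0, self.closing_shift_sd),
            sat_mu_ventral=self.base.sat_mu_ventral
            + rng.normal(0.0, self.sat_shift_sd),
            gain=self.base.gain * float(np.exp(rng.normal(0.0, self.gain_rel_sd))),
            seed=seed,
        )


def simulate_cohort(
    n_subjects: int,
    spec: Optional[CohortSpec] = None,
    seed: int = 0,
    out_dir=None,
) -> List[PhantomTrial]:
    """Simulate ``n_subjects`` reproducible trials from one cohort spec.

    With ``out_dir`` set, each subject's file set lands in
    ``<out_dir>/subject_<k>/`` in the standard formats.
    """
    if n_subjects < 1:
        raise ValidationError("simulate_cohort: need n_subjects >= 1")
    spec = spec or CohortSpec()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    trials = []
    for k, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(sub_seed)
        config = spec.draw(rng, seed=sub_seed)
        trial = simulate_trial(config)
        if out_dir is not None:
            import os

            write_trial(trial, os.path.join(out_dir, f"subject_{k + 1:02d}"))
        trials.append(trial)
    return trials
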