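# Methods

## Signal model and preprocessing

Each pixel of the reconstructed EIT stream is treated as the sum of a
slowly varying aeration level (driven by mean airway pressure), the HFOV
oscillation at the carrier frequency `f0` (9 Hz by default, sampled at
40 Hz), and broadband noise. The two are separated by zero-phase (forward–
backward) 4th-order Butterworth filters:

- **aeration / baseline**: low-pass at `f0/4` (2.25 Hz by default). The
  baseline is the per-pixel *minimum* of the filtered signal over a
  pre-trial window at the injured, de-recruited state; filtering first
  prevents oscillation troughs or noise spikes from being taken as the
  baseline. The baseline is per pixel, not a global scalar, so that the
  aeration map is a spatial image.
- **ventilation**: band-pass at `f0 ± 2` Hz, then peak-to-peak excursion
  per consecutive 5-s block, averaged over the blocks of the analysis
  window (trailing partial block discarded). A pure sine of amplitude A
  reports 2A. Peak-to-peak per 5-s block was chosen as the amplitude
  operator; RMS or tidal-image differencing are defensible alternatives
  and would differ only by a fixed scale for narrowband signals, which the
  scale-invariant CoV and the relative 20 % thresholds do not see.

The first and last second of every analysis window are excluded from the
statistics to discard filter edge transients; for windows shorter than 7 s
the trim shrinks linearly so that at least 5 s always remain. Each
pressure step is analyzed over the final 60 s of its window by default
(configurable; the compact phantom runs below use 10 s).

Maps extracted over a window tolerate the annotation's end time sitting
one frame past the last sample (annotations mark half-open intervals).

## Region classification

All classification is pixel-wise and threshold-based with a single tuning
constant, the fraction `thr = 0.20`:

- **lung mask** at step *n*: pixels whose aeration gain over the lowest-
  pressure reference step exceeds `thr` times the maximal pixel gain at
  that step (strict `>`). If no pixel gains aeration the mask is empty.
  The gain (difference) reading was chosen over reading the left-hand side
  as the absolute pixel value; the absolute reading would make the
  reference step's threshold zero and admit every positive-noise
  background pixel. A consequence of the difference reading is that the
  reference step's own lung mask is empty, so its recruitable count equals
  the entire highest-step lung mask — a convention, reported as such, and
  irrelevant to titration because the intersection of the region curves
  lies well above the reference step.
- **overdistended** for the adjacent pair (lower *n*, higher *n + 1*):
  pixels whose aeration change from *n* to *n + 1* stays below `thr` times
  the pair's maximal pixel change (strict `<`) *and* that belong to the
  lung mask at the lower step. The count is attributed to the **higher**
  step of the pair — the only attribution consistent with the lowest step
  having no value (nothing below it to compare with). If no pixel gains
  aeration at the higher pressure the criterion is vacuous; the mask is
  defined empty and a warning is logged.
- **recruitable** at step *n*: lung at the highest step AND NOT lung at
  *n*.
- **overdistension/recruitment ratio**: the count ratio, reported missing
  (not infinite) when the recruitable count is zero.

Ties at exactly the threshold fall outside both sets (inequalities strict
as defined). CoV is computed on the ventilation map — the index describes
the *ventilation* distribution; an `aeration` option exists for
sensitivity analysis.

## Titration strategies

All selections return a pressure from the trial's own ladder. Every tie is
resolved toward the higher pressure (recruitment-conservative) and logged.

- **oxygenation**: scanning decrementally, the first step whose PaO₂ falls
  strictly more than 10 % below the preceding step marks derecruitment;
  the preceding step is returned. A drop of exactly 10 % does not trigger.
  With several qualifying drops the first (highest-pressure) one counts.
  Without any, the lowest pressure is returned with a `no-drop` flag
  rather than an error, so cohort pipelines complete.
- **EIT-CoV**: argmin of |CoV − 50 %|.
- **EIT-regions**: with `d = OD − recruit` per step in decremental order,
  a step with `d = 0` is the intersection; a sign change between adjacent
  steps resolves to the flanking step with smaller |d|; with no sign
  change, the step minimizing `OD + recruit` is returned. Resolving the
  intersection to an existing ladder step (rather than interpolating)
  keeps the output on the 3-cmH₂O grid that the protocol can actually set.

## Cohort statistics

Medians and quartiles use the exclusive rank-`p(n+1)` convention
(`numpy.quantile(..., method="weibull")`), interpolated linearly and
clamped to the extreme order statistics; it is the convention that
reproduces the bundled trial's printed upper quartile (21.8) from its
per-subject column, where the common `linear` default yields 21.0. The
convention is test-locked against a longhand rank-interpolation oracle.
Bland–Altman agreement uses bias = mean difference and limits of agreement
= bias ± 1.96 × sample SD (n−1). Group hypothesis testing
(Kruskal–Wallis / Wilcoxon / Holm) is out of scope.

## The phantom

The generator is validation scaffolding, not a physiological claim. Two
elliptical lung fields sit on the 32×32 grid (rows ventral → dorsal). Each
lung pixel draws, from a seeded generator:

- a **closing pressure** (normal; ventral mean −2 cmH₂O, +24 cmH₂O from
  ventral to dorsal, SD 3) below which the pixel is collapsed (aeration 0,
  no oscillation) — dorsal lung collapses first as pressure falls;
- an **opening pressure** = closing + 6 cmH₂O (the trial is decremental
  after full recruitment, so only the closing threshold acts);
- a **saturation pressure** (normal; ventral mean 14, +36 from ventral to
  dorsal, SD 3, ≥ closing + 3) above which additional pressure adds no
  air — ventral lung overdistends first at high pressure. A configurable
  fraction of pixels never saturates (5 % in the planted family), keeping
  the pair-wise maximal gain well defined even near the top of the ladder;
- a **gain** (normal, mean 1, SD 0.1 relative) giving the piecewise-linear
  aeration response `a(P) = g·(min(P, P_sat) − P_close)` for open pixels.

Oscillation amplitude is proportional to the local compliance (the slope
of the aeration response, scale 4 impedance units per cmH₂O of effective
swing): collapsed pixels are silent and saturated pixels nearly so (1 % of
the open slope), which is exactly why the method classifies overdistension
from pressure-induced aeration changes rather than from the oscillation.
The stream settles exponentially (τ = 3 s; 1 s in compact runs) toward
each step's level with the 9-Hz sine riding on top plus white noise
(SD 0.01, roughly 1.7 % of a healthy pixel's oscillation peak-to-peak).
The HFOV settings Δpressure 70 cmH₂O and inspiratory time 33 % are carried
as metadata; the emitted waveform is a pure carrier sine. PaO₂ is
`PaO₂max − c·(collapsed fraction) − d·(saturated fraction) + noise`
(defaults 450, 420, 30, SD 5 mmHg, FiO₂ 1.0).

Ground truth stores, per step, the collapsed and saturated pixel sets, the
noiseless aeration/ventilation maps and the region classification of those
noiseless maps — what a perfect measurement chain would recover; the
pipeline tests compare their output against it. Determinism: one seeded
`numpy` generator, no global state; equal seeds give byte-identical files
(`%.17g` CSV floats, round-trip parsing on read).

**Planted-optimum family.** With the 3-cmH₂O ladder and the piecewise-
linear response, the overdistended count attributed to step P tracks
pixels with saturation below P − 2.4 (the pair's lower pressure plus the
20 % gain margin) and the recruitable count tracks pixels with closing
above P − 0.2 (P − 9) (the lung-mask margin over the 9-cmH₂O reference).
Equating the two normal tail fractions puts the curve crossing at
`(μ_sat + μ_close + 0.6)/1.8`; `planted_config(p_star)` inverts this with
`μ_sat = p_star + 3`. Empirically the realized crossing is within about
0.6 cmH₂O of the target, so recovery studies plant optima within
±0.5 cmH₂O of ladder values, where "nearest ladder step" is unambiguous.
`coincident_config()` additionally balances the fronts and the PaO₂ scale
so that all three strategies agree at 21 cmH₂O.

**Cohort distribution.** Subjects draw a shared-seeded shift of the
closing and saturation means (SD 1.5 cmH₂O each) and a log-normal gain
factor (10 %); a fully degenerate spec (all spreads zero) yields literally
identical subjects.

**What the phantom does not emulate:** cardiac oscillations, electrode
artifacts and drift, hysteresis of the pressure–volume relation, the
nonlinear shape of real recruitment curves, reconstruction blurring and
the off-plane contribution of the EIT sensitivity region. Passing tests
therefore demonstrate correctness of the analysis chain on a lung whose
regional behavior is known, not fidelity of any physiological prediction.

## Problem sizes in tests and the acceptance script

Simulation studies run compact trials — 16-s steps with a 10-s analysis
window (one full 5-s amplitude block after edge trimming), 6-s baseline,
τ = 1 s — which preserve every structural property of the default 75-s
steps while keeping a 100-trial recovery study to about a minute. The
zero-noise recovery, planted-optimum (100 trials) and trend (10-subject
cohort) studies in `scripts/acceptance.py` all use these sizes; the
defaults remain 75-s steps with the 60-s analysis window.

## Known limitations

- The 20 % threshold is a convention inherited from the method; its
  sensitivity is exposed (`thr` everywhere) but not validated here.
- The oscillation-amplitude estimator (block peak-to-peak) is upward-
  biased under noise; in silent regions (collapsed or fully saturated
  lung, background) the measured ventilation map has a noise floor that
  pulls the measured CoV slightly toward 50 %.
- The reference-step convention above makes the lowest step's recruitable
  count equal to the whole highest-step lung mask.
- With fewer than two steps only CoV is computable; region analysis needs
  a pressure pair by construction.
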