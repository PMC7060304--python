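# hfoveit

EIT-guided titration of the optimal mean airway pressure (mPaw) during
high-frequency oscillatory ventilation (HFOV) in ARDS.

HFOV applies a constant mean airway pressure with small 9-Hz pressure
oscillations. Setting that pressure is a regional problem: too high and the
non-dependent (ventral) lung overdistends, too low and the dependent
(dorsal) lung collapses — and arterial blood gases see neither until late.
Electrical impedance tomography (EIT) images the regional air content of a
thoracic cross-section at the bedside as a 32×32 grid of relative
impedance, fast enough to resolve the oscillation itself. `hfoveit`
implements, from the raw pixel stream of a decremental mPaw trial
(36 → 9 cmH₂O in 3-cmH₂O steps), three titration strategies and the
statistics to compare them, plus a synthetic lung phantom so the whole
chain is testable without animal data.

## The method

From the stream, each pressure step *n* yields two functional images over
its final analysis minute:

- an **aeration map** `I_n` — the low-pass-filtered mean pixel impedance
  referenced to the lowest impedance of the injured, de-recruited lung
  (regional air content), and
- a **ventilation map** — the mean peak-to-peak amplitude of the band-passed
  9-Hz oscillation per 5-s block (regional tidal ventilation).

Three indices drive the titration:

- **Center of ventilation.** With row coordinate `y_i ∈ [0, 1]` from
  ventral to dorsal, `CoV = Σ(y_i·I_i)/Σ(I_i) × 100 %` on the ventilation
  map. The optimal mPaw is the step with CoV closest to 50 %.
- **Lung / overdistended / recruitable regions.** Lung at step *n* is the
  pixel set `{j : I_n,j − I_r,j > 20 % × max_i(I_n,i − I_r,i)}` with *r* the
  lowest-pressure step. A lung pixel is *overdistended* when its aeration
  change toward the adjacent higher step stays below 20 % of the pair's
  maximal pixel change; it is *recruitable* when it is lung at the highest
  step but not at the current one. The optimal mPaw is the step where the
  two pixel-count curves intersect (lowest sum if they never do).
- **Oxygenation.** The step before the first step at which PaO₂ drops by
  more than 10 % versus the preceding step.

Cohorts of per-subject selections are summarized as median (Q1–Q3) with the
rank-`p(n+1)` quantile convention and compared with Bland–Altman bias and
limits of agreement.

## Worked example

`examples/` holds one short script per capability. `03_titrate.py`
simulates a phantom trial, extracts the per-step maps and runs all three
strategies:

```
optimal mPaw by oxygenation :   15 cmH2O
optimal mPaw by cov         :   21 cmH2O
optimal mPaw by regions     :   21 cmH2O

disagreement oxygenation_vs_cov: -6 cmH2O
disagreement oxygenation_vs_regions: -6 cmH2O
disagreement cov_vs_regions: +0 cmH2O
```

On this subject the two EIT-based strategies agree at 21 cmH₂O while the
oxygenation criterion, which reacts only once collapse is massive enough to
shunt, lands two steps lower — the kind of individual disagreement the
cohort statistics quantify. `04_cohort_statistics.py` reproduces the
summaries of a published ten-pig trial from its per-subject selections:

```
oxygenation : 21 (18.0-21.0) cmH2O
cov         : 19.5 (15.0-21.0) cmH2O
regions     : 19.5 (18.0-21.8) cmH2O

oxygenation vs EIT-CoV bias: +1.8 cmH2O (limits of agreement -3.2 to +6.8)
largest per-subject disagreement, oxygenation vs EIT-CoV: 6 cmH2O
```

## Command line

A thin CLI wires the modules into reproducible runs:

```sh
hfoveit simulate --seed 7 --out-dir trial --step-duration 16 --analysis-len 10
hfoveit preprocess --frames trial/frames.csv --annotations trial/steps.csv \
    --out maps.csv --analysis-len 10
hfoveit titrate --maps maps.csv --blood-gas trial/blood_gas.csv --out report.json
hfoveit compare --cohort cohort.csv --out summary.json --plot bland_altman.png
```

File formats (CSV + YAML sidecar, JSON report) are documented in
`hfoveit.io_formats`.

## Layout

- `src/hfoveit/io_formats.py` — on-disk formats and validation
- `src/hfoveit/preprocess.py` — filtering, baseline, per-step maps
- `src/hfoveit/regional.py` — CoV, lung/overdistension/recruitability masks
- `src/hfoveit/titration.py` — the three selection strategies
- `src/hfoveit/stats_compare.py` — cohort summaries, Bland–Altman
- `src/hfoveit/phantom.py` — synthetic trial generator with ground truth
- `src/hfoveit/cli.py` — `hfoveit` command
- `docs/methods.md` — model, parameters, numerical choices, limitations
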