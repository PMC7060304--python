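"""Select the optimal mPaw by all three strategies on one trial.

* oxygenation: the step before the first > 10% PaO2 drop,
* EIT-CoV: the step whose center of ventilation is closest to 50%,
* EIT-regions: where the overdistended and recruitable curves intersect.
"""

from hfoveit import phantom, preprocess, titration

config = phantom.PhantomConfig(
    step_duration_s=16.0, analysis_len_s=10.0, baseline_duration_s=6.0,
    settle_tau_s=1.0, seed=7,
)
trial = phantom.simulate_trial(config)
baseline = preprocess.compute_baseline(trial.series, (0.0, config.baseline_duration_s))
steps = preprocess.extract_step_maps(
    trial.series, trial.annotations, baseline, config.analysis_len_s
)

result = titration.titrate(steps, trial.blood_gas)

for sel in result.selections().values():
    note = f" [{sel.note}]" if sel.note else ""
    print(f"optimal mPaw by {sel.method:12s}: {sel.mpaw:4.0f} cmH2O{note}")
print()
for pair, diff in result.disagreements.items():
    print(f"disagreement {pair}: {diff:+.0f} cmH2O")
print()
print("The three criteria look at different physiology (gas exchange,")
print("ventilation distribution, regional mechanics), so they need not")
print("agree; differences are multiples of the 3-cmH2O step size.")
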