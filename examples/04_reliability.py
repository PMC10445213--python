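"""Test-retest reliability of a synthetic two-session cohort.

Generates a 31-subject cohort whose latent traits have ICC(A,2) = 0.8,
scores every trial, and reports ICC with 95% CI plus Bland-Altman
agreement statistics per score for the part-A speed condition.
"""

from trailgaze import condition_tables, reliability_report, score_dataset
from trailgaze.synth import SimulationConfig, generate_dataset

config = SimulationConfig(n_subjects=31, true_icc=0.8, trials_per_condition=1, seed=42)
dataset = generate_dataset(config)
scores = score_dataset(dataset)
report = reliability_report(condition_tables(scores))

cell = report[(report["part"] == "A") & (report["instruction"] == "speed")]
cols = ["score", "icc", "icc_ci_low", "icc_ci_high", "icc_class", "bias", "slope", "slope_sig"]
print(cell[cols].round(3).to_string(index=False))
print(
    "\nTrait-driven scores (completion time, fixation duration, searching "
    "count, scanpath) are the reliable ones; trial-to-trial noise attenuates "
    "their estimates below the latent ICC of 0.8, and at n=31 the CIs are "
    "wide.  Scores without a planted trait (saccade amplitude, "
    "speed-accuracy slope) are unreliable by design.  Bias near 0 = no "
    "session drift; a starred slope would flag performance-dependent "
    "practice effects."
)
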