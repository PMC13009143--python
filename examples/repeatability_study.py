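"""Simulate a repeat study and compute its repeatability statistics.

Draws a 7-subject intra-day design (3 sessions x 2 repeats each) with
30% between-subject and 10% within-subject variability in true flow,
then summarizes per-subject mean, SD and coefficient of variation with
the Student-t 95% confidence interval of the mean CoV.
"""

from retiflow.repeatability import summarize_study, t_quantile_975
from retiflow.synthetic import (RepeatStudyConfig, default_scene,
                                simulate_repeat_study, truth_table)

base = default_scene(seed=0)
cfg = RepeatStudyConfig(n_subjects=7, n_sessions=3, n_repeats_per_session=2,
                        between_subject_cv=30.0, within_subject_cv=10.0,
                        design_label="intra_day", seed=2)
measurements = simulate_repeat_study(cfg, base)
study = truth_table(measurements)
print(f"{len(study)} measurements from {cfg.n_subjects} subjects")

table = summarize_study(study, metrics=["qm_ul_min", "qs_ul_min", "ri_q"])
print(table)
print(f"\nt coefficient for n={cfg.n_subjects}: "
      f"{t_quantile_975(cfg.n_subjects):.3f}")
# The group mean CoV of the mean volume rate lands near the injected 10%
# within-subject variability; RI, injected as constant, shows ~0% CoV.
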