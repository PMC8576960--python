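"""Train and compare the three ensembles by stratified cross-validation.

Uses a small, quickly-generated cohort; the full study conditions
(50 + 50 subjects, 30-min records) are what scripts/acceptance.py runs.
"""

from pafscreen.config import PipelineConfig
from pafscreen.evaluation import cross_validate, report_table
from pafscreen.features import feature_table
from pafscreen.synthetic import CohortSpec, synth_cohort

cfg = PipelineConfig(n_members=30, cv_folds=5, max_fitted_beats=6,
                     htga_population_size=30, htga_generations=40)

cohort = synth_cohort(CohortSpec(n_per_class=15, duration_s=300.0, seed=7))
df = feature_table([sr.record for sr in cohort], cfg)

reports = {m: cross_validate(df, m, cfg, seed=0)
           for m in ("bagging", "adaboost", "stacking")}
print(report_table(reports).round(4).to_string())

# One row per ensemble: accuracy and AUROC well above 0.5 show the combined
# P-wave + HRV features separate the simulated classes; F1 is the harmonic
# mean of NPV and specificity (the table convention), F1_positive the
# standard positive-class form.
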