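"""Run the whole pipeline and select survival-predictive features.

One call executes simulate -> standardize -> cluster -> features -> nested
leave-one-out Lasso-Cox selection -> median-split Kaplan-Meier/log-rank, and
returns every intermediate plus a machine-readable report.
"""

import warnings

import cytoresponse as cr
from cytoresponse.pipeline import RunConfig, run_pipeline

warnings.filterwarnings("ignore")

spec = cr.CohortSpec(n_patients=32, cells_per_sample=400)
res = run_pipeline(RunConfig(cohort_spec=spec, seed=11, max_training_cells=300))

print("selection frequency over leave-one-out folds (top 5):")
print(res.selection.selection_frequency.head(5).round(3).to_string())
print(f"\npenalty chosen by inner CV (1-SE rule): {res.selection.chosen_lambda:.4f}")
print(f"selected features: {res.selection.selected_features}")
print("\nunpenalized refit on the selected set (log-HR per SD):")
print(res.selection.refit.round(4).to_string())

lr = res.logrank
print(f"\nmedian split on {res.report['top_feature']}: "
      f"{res.report['median_split']['low']} low / {res.report['median_split']['high']} high")
print(f"log-rank chi2 = {lr.chi2:.2f}, p = {lr.p:.2e}")
print(f"hazard ratio (low/high) = {lr.hazard_ratio:.3f}, 95% CI "
      f"({lr.hr_ci[0]:.3f}, {lr.hr_ci[1]:.3f})")
# a hazard ratio well below 1 means the low-signaling arm dies at a fraction
# of the high arm's rate — the expected direction when sustained 24 h target
# marker signaling drives the simulated hazard
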