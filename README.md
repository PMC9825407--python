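# cytoresponse

Early-response profiling of induction chemotherapy in acute myeloid
leukemia (AML) from multiplexed single-cell (mass) cytometry: patients are
sampled before treatment and 4 h / 24 h after its start, and the question
is whether the change in intracellular signaling of the leukemic
compartment within the first day predicts long-term overall survival.

`cytoresponse` implements that analysis as a tested, reusable Python
pipeline:

1. **Batch standardization** — every multiplexed batch carries an aliquot of
   the same reference material; after the arcsinh transform
   (`asinh(x / 5)`), each channel of each batch is corrected by the
   piecewise-linear map sending its reference's 101 quantiles
   (0%, 1%, …, 100%) onto a chosen standard batch's reference quantiles.
2. **Clustering** — a 5×5 self-organizing map trained on pre-treatment +
   healthy-donor cells over 19 surface markers, consensus metaclustering of
   the nodes into k = 10 metaclusters (MCs), and nearest-cluster-center
   assignment of post-treatment cells. Sub-clustering within one MC (all 21
   surface markers) is supported.
3. **Features** — per patient: the 90th-percentile arcsinh intensity of each
   of 15 functional (phospho-)markers in each MC at each timepoint, the
   24 h / 0 h ratio per MC × marker, the 10 MC sizes, age and sex
   (612 columns in the default design).
4. **Survival** — nested leave-one-out Lasso–Cox feature selection
   (outer LOO for selection frequencies, inner LOO picking the penalty λ by
   cross-validated partial likelihood, 1-SE rule), an unpenalized Cox refit
   of the selected set (log-HR per SD, Wald p, Benjamini–Hochberg adjusted),
   then a median split of the key feature with Kaplan–Meier curves and the
   Mantel–Cox log-rank test (HR = (O₁/E₁)/(O₂/E₂) with log-rank CI).
   Multivariable Cox with transplantation as a time-dependent covariate and
   Fisher exact tests round out the clinical statistics.
5. **Validation paths** — manual-style bi-axial blast gating
   (CD45-low / CD66b-low, thresholds derived from a healthy reference) and
   ex vivo drug-sensitivity scoring (plate control normalization, DSS =
   thresholded normalized area under the inhibition–log-dose curve, and
   selective DSS against healthy donors).

Everything is exercised end-to-end on a **synthetic cohort generator**
(`cytoresponse.synth`) that emulates the study's data structure — ten
immunophenotypic populations, zero-inflated heavy-tailed intensities,
monotone per-batch distortions with shared reference aliquots, responder /
non-responder 24 h signaling dynamics, and survival drawn from a
proportional-hazards model on the latent 24 h signaling value — so every
stage can be tested against known ground truth without any data download.

## Worked example

```python
import cytoresponse as cr
from cytoresponse.pipeline import RunConfig, run_pipeline

spec = cr.CohortSpec(n_patients=32, cells_per_sample=400)
res = run_pipeline(RunConfig(cohort_spec=spec, seed=1, max_training_cells=300))

print(res.selection.selection_frequency.head(3))
lr = res.logrank
print(f"log-rank p = {lr.p:.2e}, HR(low/high) = {lr.hazard_ratio:.3f}")
print(res.report["median_split"])
```

prints (abridged):

```
MC2|p-ERK1/2|24h    0.344
MC2|p-p38|24h       0.062
MC5|p-S6|0h         0.031
log-rank p = 5.69e-05, HR(low/high) = 0.205
{'low': 16, 'high': 16}
```

MC2 is the metacluster the SOM assigned to the simulated myeloid
population, so the pipeline recovered the planted signal: the 24 h
p-ERK1/2 level of the myeloid metacluster tops the leave-one-out selection
frequencies (0.344 vs 0.062 for the next feature — the 1-SE rule keeps most
fold models very sparse), and splitting the 32 patients at that feature's
median into 16/16 arms separates survival sharply: the low-signaling arm's
hazard is about a fifth of the high arm's.

The `examples/` directory holds one short narrative script per capability
(simulation, standardization, clustering + features, survival selection,
gating validation, drug screening); each prints the numbers it computes and
a line on what they mean. A thin CLI mirrors the stages
(`cytoresponse simulate|normalize|cluster|features|survive|gate|dss|run`).

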