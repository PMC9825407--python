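"""Score ex vivo drug-sensitivity plates.

Normalizes well readouts to the plate's positive/negative control medians,
summarizes each 5-point dose series into a drug sensitivity score (DSS,
thresholded normalized area under the inhibition curve), and subtracts
healthy-donor scores to get the selective score (sDSS).
"""

import pandas as pd

import cytoresponse as cr
from cytoresponse.drugscreen import score_sample, simulate_plate, top_targets

drugs = {
    "venetoclax": (50.0, 90.0),    # (EC50 nM, max inhibition %)
    "cytarabine": (300.0, 80.0),
    "tanespimycin": (80.0, 85.0),
    "trametinib": (20.0, 75.0),
    "selumetinib": (60.0, 70.0),
    "etoposide": (900.0, 78.0),
    "everolimus": (15.0, 60.0),
    "dexamethasone": (5000.0, 40.0),
    "placebo-like": (1e7, 5.0),
}
targets = {
    "venetoclax": "BCL-2", "cytarabine": "nucleoside analog",
    "tanespimycin": "HSP90", "trametinib": "MEK", "selumetinib": "MEK",
    "etoposide": "topoisomerase", "everolimus": "mTOR",
    "dexamethasone": "glucocorticoid receptor", "placebo-like": "none",
}

patient_wells, _ = cr.normalize_plate(simulate_plate(drugs, seed=1))
patient = score_sample(patient_wells)
healthy = []
for seed in range(2, 7):  # five healthy donors
    weaker = {d: (ec, mx * 0.45) for d, (ec, mx) in drugs.items()}
    wells, _ = cr.normalize_plate(simulate_plate(weaker, seed=seed))
    healthy.append(score_sample(wells))

sdss = cr.compute_sdss(patient, healthy)
print(sdss.round(1).sort_values("sdss", ascending=False).to_string(index=False))
# sDSS > 0: the patient sample is more sensitive than healthy donors to the
# drug; near 0 or negative: no leukemia-selective effect

tally = top_targets({"P1": sdss}, targets, n=5)
print("\nmost common targets among the top-5 drugs:")
print(tally.to_string(index=False))
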