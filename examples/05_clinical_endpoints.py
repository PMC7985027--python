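"""Serology correlation and time-to-ESLD survival on a synthetic cohort.

Simulates clinical records whose hazard doubles per fibrosis stage
(log HR = 0.693) with serology markers monotone in stage, then reproduces the
endpoint analyses: Spearman serology correlations, Kaplan-Meier curves with a
log-rank test on the F >= 3.5 dichotomy, and a Cox model adjusting for age
and BMI.
"""

import numpy as np
import pandas as pd

from vtstain import clinical as clin
from vtstain import synthetic

rng = np.random.default_rng(2)
stages = rng.integers(0, 5, size=280).astype(float)
clinical = synthetic.simulate_clinical(stages, log_hr_per_stage=0.693,
                                       censor_rate=0.6, seed=8)
summaries = pd.DataFrame({"case_id": clinical["case_id"], "median_real": stages,
                          "median_virtual": stages, "residual": 0.0,
                          "iqr_real": 0.0})

table = clin.serology_correlations(summaries, clinical,
                                   markers=["ast", "albumin", "sodium", "meld"])
sub = table[table["stage_variable"] == "median_real"]
print(sub[["marker", "rho", "p"]].to_string(index=False))
print("AST/MELD rise and albumin/sodium fall with stage, as planted.\n")

km = clin.km_logrank(summaries, clinical, grouping="dichotomized_3_5")
print(f"log-rank (F>=3.5 vs F<3.5): chi2 = {km.logrank_stat:.1f}, "
      f"p = {km.logrank_p:.2e}")

cox = clin.coxph(summaries, clinical, stage_col="median_real",
                 covariates=("age", "bmi"))
print(f"Cox HR per stage = {cox['hr']:.2f} [{cox['ci_low']:.2f}, "
      f"{cox['ci_high']:.2f}], concordance {cox['concordance']:.2f} "
      f"(planted HR 2.0)")
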