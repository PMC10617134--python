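"""Genetic risk score and Wald-ratio causal estimate for one outcome.

Builds the externally weighted HMGCR score, regresses an apolipoprotein-B
outcome and LDL-C on it (adjusted for age, sex, 6 ancestry PCs), and
forms the ratio: SD change in the outcome per SD-lower LDL-C.
"""

import targetmr as tmr
from targetmr.estimators import wald_ratio
from targetmr.grs import DEFAULT_COVARIATES, build_grs, fit_covariate_adjusted, standardize_outcome
from targetmr.pipeline import PipelineConfig, select_for_target
from targetmr.synthetic import simulate_study

study = simulate_study(tmr.default_config(seed=1))
cohort = study.cohort
region = study.config.regions[0].gene  # HMGCR

iset, _ = select_for_target(study, region, PipelineConfig(seed=1))
score = build_grs(cohort, iset)
covars = cohort.data[DEFAULT_COVARIATES]

den = fit_covariate_adjusted(cohort.data["ldl_std"], score, covars)
y = standardize_outcome(cohort.data["apob"])
num = fit_covariate_adjusted(y, score, covars)
est = wald_ratio(num, den, ldl_decrease=True)

print(f"{region.name} GRS on LDL-C: beta = {den.beta:.3f} (se {den.se:.3f}), "
      f"partial R² = {100 * den.partial_r2:.2f}%")
print(f"{region.name} GRS on ApoB:  beta = {num.beta:.3f} (se {num.se:.3f}), "
      f"n = {num.n_used}")
print(f"Wald ratio: {est.beta:.2f} SD ApoB per SD-lower LDL-C "
      f"[95% CI {est.ci_low:.2f}, {est.ci_high:.2f}], p = {est.pvalue:.2g}")
print()
print("A negative estimate means genetic inhibition of the target (lower")
print("LDL-C) lowers ApoB — the expected on-target efficacy signal.")
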