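"""Correlated-variant IVW for the binary positive-control outcome.

Combines instrument effects on LDL-C with their effects on CAD from an
independent case-control GWAS, weighting by an LD-aware covariance, and
reports the odds ratio per SD-lower LDL-C with Cochran's Q.
"""

import numpy as np

import targetmr as tmr
from targetmr.estimators import ivw_correlated
from targetmr.pipeline import PipelineConfig, select_for_target
from targetmr.sumstats import harmonize_tables, CANONICAL_COLUMNS
from targetmr.synthetic import simulate_study

study = simulate_study(tmr.default_config(seed=1))

for region_spec in study.config.regions[:2]:  # HMGCR, PCSK9
    region = region_spec.gene
    iset, _ = select_for_target(study, region, PipelineConfig(seed=1))
    pairs = harmonize_tables(iset.variants[CANONICAL_COLUMNS], study.gwas_cad)
    est = ivw_correlated(pairs["beta"], pairs["internal_beta"],
                         pairs["internal_se"], iset.ld.subset(list(pairs["variant_id"])))
    or_per_lower = float(np.exp(-est.beta))
    ci = (float(np.exp(-est.beta - 1.96 * est.se)),
          float(np.exp(-est.beta + 1.96 * est.se)))
    print(f"{region.name}: CAD OR {or_per_lower:.2f} per SD-lower LDL-C "
          f"[95% CI {min(ci):.2f}, {max(ci):.2f}]  "
          f"Q = {est.q:.2f} (df {est.q_df}, p = {est.q_pvalue:.2f})")

print()
print("Odds ratios below 1 reproduce the protective effect of LDL-C")
print("lowering on coronary artery disease; a small Q p-value would flag")
print("heterogeneity between the per-variant ratio estimates.")
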