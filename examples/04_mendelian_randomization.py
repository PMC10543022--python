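"""Two-sample Mendelian randomization from simulated GWAS summary statistics.

Generates paired exposure (metabolite) and outcome (depression) GWAS with a
known causal effect of 0.09 log-odds per SD on two metabolites, selects
instruments (MAF, strand-ambiguity, p < 5e-8, LD clumping), harmonizes
alleles and runs IVW, weighted-median, MR-Egger and the heterogeneity /
pleiotropy diagnostics.
"""

import numpy as np

from mwaskit import mr, simulate

exposures, outcome, ld, truth = simulate.simulate_sumstats(simulate.MrSimConfig(seed=1))
results, details, skipped = mr.mr_pipeline(exposures, outcome, ld, mr.MrConfig(seed=1))

causal = set(truth.theta[truth.theta != 0].index)
print(f"metabolites tested: {len(results)}, skipped: {len(skipped)}, "
      f"truly causal: {sorted(causal)} (theta = 0.09)")
cols = ["metabolite_id", "n_snps", "ivw_or", "ivw_ci_low", "ivw_ci_high",
        "ivw_pvalue", "qvalue", "egger_intercept_pvalue", "cochran_q_pvalue",
        "presso_global_pvalue", "min_f_statistic"]
print(results.sort_values("ivw_pvalue")[cols].head(5).round(4).to_string(index=False))

sig = results.loc[results["qvalue"] < 0.05, "metabolite_id"]
print(f"\nMR-significant at FDR 5%: {sorted(sig)}")
top = results.sort_values("ivw_pvalue").iloc[0]
print(f"top metabolite OR per SD: IVW {top['ivw_or']:.3f} "
      f"({top['ivw_ci_low']:.3f}-{top['ivw_ci_high']:.3f}), "
      f"weighted median {top['wm_or']:.3f}, Egger {top['egger_or']:.3f}")
# An OR near exp(0.09) = 1.094 for the causal metabolites, null ORs near 1,
# non-significant Egger intercepts and outlier tests indicate clean
# instruments; min F > 10 marks adequate instrument strength.
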