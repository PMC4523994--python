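"""Attach bootstrap uncertainty to an FDR analysis of one P-value set.

Simulates a study-scale experiment (2000 features, 10% true signals),
estimates local FDRs and q-values, declares significance at q <= 0.05,
and bootstraps the P-values to put standard errors on every FDR index.
"""

import fdrboot as fb

truth = fb.simulate_pvalues(fb.MixtureParams(m=2000, eta0=0.9, mu=2.5),
                            seed=11)
pv = truth.pvalue_vector()

fit = fb.local_fdr(pv)
S = fb.significant_set(fit, alpha=0.05)
summ = fb.run_bootstrap(pv, fit, S, B=2000, seed=11)

print(f"features:               {pv.m}")
print(f"estimated eta0:         {fit.eta0:.3f}   (true 0.9)")
print(f"significant at q<=0.05: r = {S.r}")
print(f"q-value over S:         {fit.fdr[S.members].mean():.4f} "
      f"+/- {summ.se_q:.4f} (bootstrap SE)")
print(f"FDP standard error:     {summ.se_fdp:.4f}")
print(f"largest local-FDR SE among significant features: "
      f"{summ.se_lfdr[S.members].max():.4f}")

# The q-value says the *average* false-positive probability over the
# significant set is ~5%, but individual significant features can carry
# a much higher local FDR, and the realized false discovery proportion
# varies around q by roughly +/- 2 SE(FDP) from experiment to experiment.
worst = S.members[fit.fdr[S.members].argmax()]
print(f"worst significant feature: local FDR "
      f"{fit.fdr[worst]:.3f} +/- {summ.se_lfdr[worst]:.3f}")
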