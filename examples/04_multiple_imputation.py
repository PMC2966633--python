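"""Handle missing ER status by multiple imputation and Rubin's rules.

A quarter of ER values are masked completely at random; three completed
cohorts are imputed by chained logistic regressions with posterior-draw
parameters, the model is fitted to each, and the fits are pooled.  The pooled
estimates track the complete-data fit, with total variance honestly inflated
by the between-imputation spread.
"""

import aftprog as ap
from aftprog.imputation import ImputationConfig, impute, pool_fits

truth = ap.default_true_coefficients()
complete, _ = ap.simulate_cohort(ap.SimulationConfig(n=2000, seed=4,
                                                     true_coeffs=truth))
masked, _ = ap.simulate_cohort(ap.SimulationConfig(n=2000, seed=4,
                                                   true_coeffs=truth,
                                                   er_missing_rate=0.25))
n_miss = sum(r.er.value == "" for r in masked)
print(f"{n_miss}/{len(masked)} ER values missing "
      f"({100 * n_miss / len(masked):.1f}%)")

fit_complete = ap.fit_aft(complete, ap.DesignSpec(), family="gamma")
fits = [ap.fit_aft(c, ap.DesignSpec(), family="gamma")
        for c in impute(masked, ImputationConfig(m=3, seed=1))]
pooled = pool_fits(fits)

print(f"\n{'term':24s} {'complete':>9s} {'pooled':>8s} {'W':>8s} {'B':>8s} "
      f"{'total se':>9s}")
for term in ("ln_nodes", "grade", "ercat", "ercat_x_adjhormones"):
    print(f"{term:24s} {fit_complete.coeffs.betas[term]:9.3f} "
          f"{pooled.coeffs.betas[term]:8.3f} {pooled.within[term]:8.4f} "
          f"{pooled.between[term]:8.4f} {pooled.se(term):9.4f}")
print("\nB > 0 only for coefficients touched by the imputed variable; the "
      "total variance T = W + (1 + 1/m)B carries imputation uncertainty.")
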