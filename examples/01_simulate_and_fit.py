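"""Simulate a breast-cancer cohort with known ground truth and refit the model.

The generator draws covariates around the average development-cohort patient,
event times from the generalized-gamma AFT model, and censoring from
other-cause death, loss to follow-up and staggered end of follow-up.
Refitting then recovers the generating time ratios.
"""

import aftprog as ap

cohort, truth = ap.simulate_cohort(ap.SimulationConfig(n=2000, seed=1))
print(f"cohort: {len(cohort)} women, {cohort.n_events} first recurrent events "
      f"({100 * cohort.n_events / len(cohort):.1f}%)")

fit = ap.fit_aft(cohort, ap.DesignSpec(), family="gamma", seed=1)
true = ap.default_true_coefficients()
print(f"\nfitted generalized-gamma AFT (AIC {fit.aic:.1f}, "
      f"sigma {fit.coeffs.sigma:.3f}, kappa {fit.coeffs.kappa:.3f})")
print(f"{'term':24s} {'fitted TR':>10s} {'true TR':>9s} {'z vs truth':>10s}")
for term, tr in fit.coeffs.time_ratios().items():
    z = (fit.coeffs.betas[term] - true.betas[term]) / fit.se(term)
    print(f"{term:24s} {tr:10.3f} {true.time_ratios()[term]:9.3f} {z:10.2f}")
print("\nA time ratio < 1 shortens time to recurrence; each fitted ratio "
      "should sit within a couple of standard errors of the generating value.")
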