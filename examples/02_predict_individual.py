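"""Individual prognosis from the published coefficient table.

The published model omits its intercept, so absolute predictions first anchor
it: the average patient (56.6 y, 1.2 nodes, grade 2, ER+, 2.2 cm) is assigned
a 5-year baseline recurrence-free probability of 0.70.  Predictions for other
women then follow from their time ratios; external randomized hazard ratios
adjust for any adjuvant treatment they receive.
"""

import aftprog as ap
from aftprog.aft import average_patient
from aftprog.data_model import DAYS_PER_YEAR
from aftprog.prognosis import DEFAULT_TREATMENT_EFFECTS, combined_hazard_ratio

coeffs = ap.published_coefficients().with_anchored_intercept(
    average_patient(), 0.7, 5 * DAYS_PER_YEAR)

patients = {
    "average": average_patient(),
    "node-positive grade 3": dict(average_patient(), nodes=5, grade=3),
    "small grade 1, older": dict(average_patient(), size_cm=1.0, grade=1, age=70),
}
print("baseline (untreated) recurrence-free survival:")
print(f"{'patient':24s} {'5y':>6s} {'10y':>6s} {'15y':>6s}")
for name, p in patients.items():
    probs = [ap.predict_survival(p, coeffs, y * DAYS_PER_YEAR,
                                 include_treatments=False)
             for y in (5, 10, 15)]
    print(f"{name:24s} " + " ".join(f"{s:6.3f}" for s in probs))

hr = combined_hazard_ratio(DEFAULT_TREATMENT_EFFECTS,
                           ["radiotherapy", "hormone"], er_positive=True)
s5 = ap.predict_survival(patients["node-positive grade 3"], coeffs,
                         5 * DAYS_PER_YEAR, include_treatments=False)
print(f"\nnode-positive grade 3 with radiotherapy + hormone therapy "
      f"(combined HR {hr:.3f}): S(5y) rises from {s5:.3f} to {s5**hr:.3f}")
print("Treatment multiplies the cumulative hazard, so S_adj = S_base^HR.")
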