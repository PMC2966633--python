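"""Fixed-horizon validation of survival predictions.

A model is judged at one landmark time (5 years by default) on three axes:

* **calibration** — the ratio of mean predicted to observed (Kaplan–Meier)
  recurrence-free survival across the whole cohort, as a percentage;
* **accuracy** — the mean Brier score, the squared gap between each patient's
  predicted event probability and her binary outcome at the horizon (0 =
  perfect forecasts, 1 = worst possible);
* **discrimination** — overall C, the probability that a random patient who
  recurred was given a higher predicted risk than a random patient who did
  not (0.5 = no discrimination, 1 = perfect).

Accuracy and discrimination need the outcome at the horizon, so they use only
patients whose status there is observable; calibration, being censoring-aware
through the Kaplan–Meier estimate, uses everyone.  A Hosmer–Lemeshow-style
grouped test compares observed and expected event counts across risk deciles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .aft import CoefficientSet, predict_survival
from .data_model import Cohort, Event, HorizonStatus, horizon_status
from .prognosis import TreatmentEffectTable, combined_hazard_ratio, received_treatments
from .data_model import ER

__all__ = [
    "kaplan_meier",
    "calibration_ratio",
    "brier",
    "overall_c",
    "hosmer_lemeshow",
    "validate",
    "ValidationReport",
]


def kaplan_meier(times, events, query_times=None):
    """Product-limit estimate of the survivor function.

    Returns ``(times, survival)`` step-function arrays, or the survival
    probabilities at ``query_times`` when given.  Censored observations tied
    with event times are handled events-first, the product-limit convention.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one observation")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    if query_times is not None:
        q = np.asarray(query_times, dtype=float)
        s = kmf.survival_function_at_times(q).to_numpy()
        return s if np.ndim(query_times) else float(s[0])
    sf = kmf.survival_function_
    return sf.index.to_numpy(), sf.iloc[:, 0].to_numpy()


def calibration_ratio(mean_predicted_pct: float, observed_km_pct: float):
    """Predicted / observed survival at the horizon, as a percentage.

    Returns ``(rounded_int, unrounded)``; the headline figure is conventionally
    quoted to the nearest integer percent.
    """
    if observed_km_pct <= 0:
        raise ValueError("observed survival must be > 0")
    ratio = 100.0 * mean_predicted_pct / observed_km_pct
    return int(round(ratio)), ratio


def brier(predicted_event_prob, observed_event):
    """Mean Brier score with its naive standard error.

    ``predicted_event_prob`` are horizon event probabilities (1 - S(horizon));
    ``observed_event`` the binary outcomes of evaluable patients.
    """
    p = np.asarray(predicted_event_prob, dtype=float)
    y = np.asarray(observed_event, dtype=float)
    if p.size == 0:
        raise ValueError("no evaluable patients")
    scores = (p - y) ** 2
    se = float(scores.std(ddof=1) / math.sqrt(scores.size)) if scores.size > 1 else float("nan")
    return float(scores.mean()), se


def overall_c(predicted_event_prob, observed_event, ci_level: float = 0.95,
              ci_method: str = "delong", n_boot: int = 2000, seed: int = 0):
    """Concordance between predicted risk and binary outcome, with CI.

    C is the probability that a randomly chosen patient with the event has a
    higher predicted risk than one without, ties counted one half — the area
    under the ROC curve.  The confidence interval uses the DeLong structural
    components by default, or a bootstrap.
    """
    p = np.asarray(predicted_event_prob, dtype=float)
    y = np.asarray(observed_event, dtype=bool)
    pos, neg = p[y], p[~y]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one event and one non-event")
    # placement values: V10[i] = P(neg < pos_i) + P(neg == pos_i)/2
    v10 = np.array([(np.sum(neg < x) + 0.5 * np.sum(neg == x)) / neg.size for x in pos])
    v01 = np.array([(np.sum(x < pos) + 0.5 * np.sum(x == pos)) / pos.size for x in neg])
    c = float(v10.mean())
    z = stats.norm.ppf(0.5 + ci_level / 2)
    if ci_method == "delong":
        var = (np.var(v10, ddof=1) / pos.size if pos.size > 1 else 0.0) + \
              (np.var(v01, ddof=1) / neg.size if neg.size > 1 else 0.0)
        half = z * math.sqrt(var)
        lo, hi = c - half, c + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = p.size
        cs = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if yb.all() or not yb.any():
                continue
            pb = p[idx]
            posb, negb = pb[yb], pb[~yb]
            cs.append(np.mean([(np.sum(negb < x) + 0.5 * np.sum(negb == x)) / negb.size
                               for x in posb]))
        lo, hi = np.quantile(cs, [(1 - ci_level) / 2, 0.5 + ci_level / 2])
    else:
        raise ValueError("ci_method must be 'delong' or 'bootstrap'")
    return c, (max(0.0, float(lo)), min(1.0, float(hi)))


def hosmer_lemeshow(predicted_event_prob, observed_event, g: int = 10):
    """Grouped observed-vs-expected test of fit at the horizon.

    Patients are split into ``g`` quantile groups of predicted risk; the
    statistic sums (O_g - E_g)^2 / (E_g (1 - E_g/n_g)) and is referred to a
    chi-square with g - 2 degrees of freedom.  Groups with expected counts of
    0 or n_g are merged into a neighbour.
    """
    p = np.asarray(predicted_event_prob, dtype=float)
    y = np.asarray(observed_event, dtype=float)
    if g < 2:
        raise ValueError("need at least 2 groups")
    order = np.argsort(p, kind="stable")
    splits = np.array_split(order, g)
    groups = []
    for idx in splits:
        if idx.size == 0:
            continue
        groups.append({"n": idx.size, "observed": float(y[idx].sum()),
                       "expected": float(p[idx].sum()),
                       "mean_predicted": float(p[idx].mean())})
    # merge degenerate groups (expected 0 or n) into the previous/next one
    merged = []
    for grp in groups:
        if merged and (grp["expected"] <= 0 or grp["expected"] >= grp["n"]):
            for k in ("n", "observed", "expected"):
                merged[-1][k] += grp[k]
        else:
            merged.append(dict(grp))
    if merged and (merged[0]["expected"] <= 0 or merged[0]["expected"] >= merged[0]["n"]):
        if len(merged) > 1:
            nxt = merged.pop(1)
            for k in ("n", "observed", "expected"):
                merged[0][k] += nxt[k]
    chi2 = 0.0
    for grp in merged:
        e, n_g, o = grp["expected"], grp["n"], grp["observed"]
        denom = e * (1.0 - e / n_g)
        if denom <= 0:
            raise ValueError("degenerate risk group; cannot form the statistic")
        chi2 += (o - e) ** 2 / denom
    df = max(len(merged) - 2, 1)
    pval = float(stats.chi2.sf(chi2, df))
    table = pd.DataFrame(merged)
    return float(chi2), df, pval, table


@dataclass
class ValidationReport:
    """Fixed-horizon performance summary of a prognostic model on a cohort."""

    horizon_days: float
    mode: str
    n_total: int
    n_evaluable: int
    n_unobservable: int
    mean_predicted_surv: float
    observed_km_surv: float
    calibration_pct: int
    calibration_unrounded: float
    brier_mean: float
    brier_se: float
    c_statistic: float
    c_ci: tuple[float, float]
    hl_chi2: float
    hl_df: int
    hl_p: float
    hl_table: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "horizon_days", "mode", "n_total", "n_evaluable", "n_unobservable",
            "mean_predicted_surv", "observed_km_surv", "calibration_pct",
            "calibration_unrounded", "brier_mean", "brier_se", "c_statistic",
            "hl_chi2", "hl_df", "hl_p")}
        d["c_ci"] = list(self.c_ci)
        d["hl_table"] = self.hl_table.to_dict(orient="records")
        return d


def _predicted_survival_at(record, coeffs: CoefficientSet, horizon: float,
                           mode: str, effects: TreatmentEffectTable | None) -> float:
    if mode == "factors_only":
        return predict_survival(record, coeffs, horizon, include_treatments=False)
    if mode != "with_treatment":
        raise ValueError("mode must be 'with_treatment' or 'factors_only'")
    if effects is None:
        # internal validation: the model's own treatment coefficients
        return predict_survival(record, coeffs, horizon, include_treatments=True)
    # external validation: published HRs applied to the baseline risk
    s_base = predict_survival(record, coeffs, horizon, include_treatments=False)
    hr = combined_hazard_ratio(effects, received_treatments(record),
                               record.er is ER.POSITIVE)
    return s_base**hr


def validate(cohort: Cohort, coeffs: CoefficientSet, horizon: float,
             mode: str = "with_treatment",
             effects: TreatmentEffectTable | None = None,
             hl_groups: int = 10) -> ValidationReport:
    """Full fixed-horizon validation of a coefficient set on a cohort.

    Calibration compares mean predicted survival with the Kaplan–Meier
    estimate at the horizon over the *whole* cohort; Brier, C and the grouped
    fit test use only patients whose horizon status is observable.  With
    ``effects`` given, predictions replace the model's own treatment terms by
    the published hazard ratios applied to baseline risk.
    """
    coeffs.require_intercept()
    pred_surv = np.array([
        _predicted_survival_at(r, coeffs, horizon, mode, effects) for r in cohort
    ])
    statuses = [horizon_status(r, horizon) for r in cohort]
    evaluable = np.array([s is not HorizonStatus.UNOBSERVABLE for s in statuses])
    y = np.array([s is HorizonStatus.EVENT_BY_HORIZON for s in statuses])

    observed = kaplan_meier([r.time_days for r in cohort],
                            [r.event is Event.RECURRENCE for r in cohort],
                            query_times=horizon)
    cal_int, cal_raw = calibration_ratio(100.0 * float(pred_surv.mean()),
                                         100.0 * observed)
    p_event = 1.0 - pred_surv[evaluable]
    y_eval = y[evaluable]
    b_mean, b_se = brier(p_event, y_eval)
    c, ci = overall_c(p_event, y_eval)
    chi2, df, pval, table = hosmer_lemeshow(p_event, y_eval, g=hl_groups)
    return ValidationReport(
        horizon_days=float(horizon), mode=mode, n_total=len(cohort),
        n_evaluable=int(evaluable.sum()), n_unobservable=int((~evaluable).sum()),
        mean_predicted_surv=float(pred_surv.mean()), observed_km_surv=float(observed),
        calibration_pct=cal_int, calibration_unrounded=cal_raw,
        brier_mean=b_mean, brier_se=b_se, c_statistic=c, c_ci=ci,
        hl_chi2=chi2, hl_df=df, hl_p=pval, hl_table=table,
    )
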