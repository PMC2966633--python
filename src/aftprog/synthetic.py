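"""Synthetic early-breast-cancer cohorts with known ground truth.

No patient-level data accompany the published model, so every fitting and
validation routine in this package is exercised on simulated cohorts built to
resemble a UK hospital series from the 1980s–90s: covariate marginals centred
on the "average patient" of the development data (age ~56.6 years, 1.2
positive nodes, grade 2, ER-positive tumour 2.2 cm in diameter), event times
drawn from the generalized-gamma AFT model at each woman's linear predictor,
and censoring from death without recurrence from unrelated causes, loss to
follow-up, and staggered administrative end of follow-up.

Treatment allocation can be confounded by indication (chemotherapy targeted
at the women with the poorest simulated prognoses), reproducing the reason
observational treatment coefficients are biased and external randomized
hazard ratios are preferred for absolute predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import gengamma
from .aft import (CoefficientSet, average_patient, build_design_row,
                  published_coefficients)
from .data_model import DAYS_PER_YEAR, ER, Cohort, Event, PatientRecord

__all__ = ["SimulationConfig", "simulate_cohort", "make_validation_fixture",
           "default_true_coefficients", "ValidationFixture"]

FIVE_YEARS = 5.0 * DAYS_PER_YEAR


def default_true_coefficients(anchor_probability: float = 0.7) -> CoefficientSet:
    """The published coefficient table with an intercept anchored so the
    average patient's 5-year baseline recurrence-free probability equals
    ``anchor_probability`` (a fixture choice — the true constant was never
    published)."""
    return published_coefficients().with_anchored_intercept(
        average_patient(), anchor_probability, FIVE_YEARS)


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults emulate the development series.

    Covariates: age is truncated normal (mean 56.6 y), node count
    zero-inflated negative binomial (mean 1.2), tumour size log-normal
    (median 2.2 cm), grade categorical with mode 2, ER Bernoulli.  ``rho``
    is a Gaussian-copula correlation among nodes/size/grade — the joint
    distribution of the original series is unpublished, so this is an
    arbitrary severity-correlation knob, not an estimate.
    Censoring: other-cause death is exponential, a ``loss_prob`` fraction is
    lost to follow-up uniformly over ``loss_window_years``, and staggered
    accrual censors everyone administratively at a uniform time over
    ``admin_window_years``.
    """

    n: int = 2000
    seed: int = 0
    # covariates
    age_mean: float = 56.6
    age_sd: float = 11.0
    age_bounds: tuple[float, float] = (25.0, 92.0)
    nodes_mean: float = 1.2
    nodes_zero_inflation: float = 0.55
    nodes_dispersion: float = 0.9        # NB size parameter of the non-zero part
    size_median_cm: float = 2.2
    size_log_sd: float = 0.45
    size_bounds_cm: tuple[float, float] = (0.2, 10.0)
    grade_probs: tuple[float, float, float] = (0.22, 0.46, 0.32)
    er_positive_prob: float = 0.75
    rho: float = 0.3
    # treatment assignment
    confounding_by_indication: bool = True
    p_radiotherapy: float = 0.75
    p_hormone_er_pos: float = 0.65
    p_hormone_er_neg: float = 0.20
    p_chemo_base: float = 0.25
    chemo_risk_slope: float = 1.5        # log-odds per unit of (worse) prognosis
    # outcome model
    true_coeffs: CoefficientSet | None = None
    # censoring
    other_cause_rate_py: float = 0.010   # deaths from unrelated causes per year
    loss_prob: float = 0.08
    loss_window_years: tuple[float, float] = (0.5, 18.0)
    admin_window_years: tuple[float, float] = (6.0, 22.0)
    # missingness
    er_missing_rate: float = 0.0
    er_missing_mechanism: str = "mcar"   # "mcar" or "mar" (older women missing more)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for name in ("nodes_zero_inflation", "er_positive_prob", "p_radiotherapy",
                     "p_hormone_er_pos", "p_hormone_er_neg", "p_chemo_base",
                     "loss_prob", "er_missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if abs(sum(self.grade_probs) - 1.0) > 1e-9:
            raise ValueError("grade_probs must sum to 1")
        if self.er_missing_mechanism not in ("mcar", "mar"):
            raise ValueError("er_missing_mechanism must be 'mcar' or 'mar'")


def _zinb_ppf(u: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Quantile function of the zero-inflated negative binomial node count."""
    pi = cfg.nodes_zero_inflation
    mean_pos = cfg.nodes_mean / max(1.0 - pi, 1e-9)
    r = cfg.nodes_dispersion
    p = r / (r + mean_pos)
    kmax = 60
    pmf = stats.nbinom.pmf(np.arange(kmax + 1), r, p)
    cdf = pi + (1.0 - pi) * np.cumsum(pmf)
    cdf[0] = pi + (1.0 - pi) * pmf[0]
    return np.searchsorted(cdf, u, side="left").clip(0, kmax)


def _draw_covariates(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n
    a, b = cfg.age_bounds
    age = stats.truncnorm.ppf(rng.uniform(size=n),
                              (a - cfg.age_mean) / cfg.age_sd,
                              (b - cfg.age_mean) / cfg.age_sd,
                              loc=cfg.age_mean, scale=cfg.age_sd)
    # Gaussian copula ties nodes, size and grade to a common severity axis
    cov = np.full((3, 3), cfg.rho)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(3), cov, size=n)
    u = stats.norm.cdf(z)
    nodes = _zinb_ppf(u[:, 0], cfg)
    size = np.clip(np.exp(math.log(cfg.size_median_cm) +
                          cfg.size_log_sd * stats.norm.ppf(u[:, 1])),
                   *cfg.size_bounds_cm)
    gcut = np.cumsum(cfg.grade_probs)
    grade = 1 + np.searchsorted(gcut[:-1], u[:, 2], side="right")
    er = rng.uniform(size=n) < cfg.er_positive_prob
    return age, nodes.astype(int), grade.astype(int), size, er


def _assign_treatments(cfg, rng, age, nodes, grade, size, er, coeffs):
    n = cfg.n
    radio = rng.uniform(size=n) < cfg.p_radiotherapy
    p_horm = np.where(er, cfg.p_hormone_er_pos, cfg.p_hormone_er_neg)
    hormone = rng.uniform(size=n) < p_horm
    p_chemo = np.full(n, cfg.p_chemo_base)
    if cfg.confounding_by_indication:
        # worse prognostic index (lower treatment-free predictor) -> more chemo
        pi = np.array([
            sum(coeffs.betas[t] * x for t, x in build_design_row(
                {"age": age[i], "nodes": nodes[i], "grade": grade[i],
                 "size_cm": size[i], "er": er[i]},
                _prognostic_spec(coeffs)).items())
            for i in range(n)
        ])
        centred = pi - pi.mean()
        logit = math.log(cfg.p_chemo_base / (1 - cfg.p_chemo_base)) \
            - cfg.chemo_risk_slope * centred
        p_chemo = 1.0 / (1.0 + np.exp(-logit))
    chemo = rng.uniform(size=n) < p_chemo
    return radio, hormone, chemo


def _prognostic_spec(coeffs: CoefficientSet):
    from .aft import DesignSpec
    return DesignSpec(terms=coeffs.spec().prognostic_terms(),
                      node_offset=coeffs.node_offset)


def simulate_cohort(config: SimulationConfig = SimulationConfig()):
    """Generate a cohort plus its ground truth.

    Returns ``(cohort, truth)`` where ``truth`` is a DataFrame holding each
    woman's latent event time, censoring cause and true (pre-masking) ER
    status.  Identical configs and seeds give identical cohorts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    coeffs = cfg.true_coeffs or default_true_coefficients()
    coeffs.require_intercept()
    age, nodes, grade, size, er = _draw_covariates(cfg, rng)
    radio, hormone, chemo = _assign_treatments(cfg, rng, age, nodes, grade, size,
                                               er, coeffs)
    n = cfg.n
    mu = np.empty(n)
    for i in range(n):
        row = build_design_row(
            {"age": age[i], "nodes": nodes[i], "grade": grade[i],
             "size_cm": size[i], "er": er[i], "radiotherapy": radio[i],
             "hormone": hormone[i], "chemo": chemo[i]}, coeffs.spec())
        mu[i] = coeffs.intercept + sum(coeffs.betas[t] * row[t] for t in coeffs.betas)
    u = rng.uniform(size=n)
    z = stats.norm.ppf(u)
    if coeffs.family != "gamma":
        raise ValueError("simulation currently draws from the gamma family")
    t_event = np.array([
        gengamma.quantile(u[i], gengamma.GenGammaParams(mu[i], coeffs.sigma, coeffs.kappa))
        for i in range(n)
    ])
    # censoring processes, in days
    t_death = rng.exponential(1.0 / max(cfg.other_cause_rate_py, 1e-12), size=n) \
        * DAYS_PER_YEAR
    lost = rng.uniform(size=n) < cfg.loss_prob
    t_loss = np.where(
        lost,
        rng.uniform(*cfg.loss_window_years, size=n) * DAYS_PER_YEAR,
        np.inf,
    )
    t_admin = rng.uniform(*cfg.admin_window_years, size=n) * DAYS_PER_YEAR
    t_cens = np.minimum(np.minimum(t_death, t_loss), t_admin)
    observed = np.maximum(np.minimum(t_event, t_cens), 0.5)  # at least half a day
    event = t_event <= t_cens

    # ER missingness mask
    er_missing = np.zeros(n, dtype=bool)
    if cfg.er_missing_rate > 0:
        if cfg.er_missing_mechanism == "mcar":
            er_missing = rng.uniform(size=n) < cfg.er_missing_rate
        else:  # MAR: pre-screening-era (older) women more often unassayed
            lo = np.quantile(age, 0.5)
            p = np.where(age >= lo, 1.6 * cfg.er_missing_rate,
                         0.4 * cfg.er_missing_rate).clip(0, 1)
            er_missing = rng.uniform(size=n) < p

    records = []
    for i in range(n):
        records.append(PatientRecord(
            id=f"S{i:06d}",
            age=float(age[i]), nodes=int(nodes[i]), grade=int(grade[i]),
            size_cm=float(size[i]),
            er=ER.MISSING if er_missing[i] else (ER.POSITIVE if er[i] else ER.NEGATIVE),
            radiotherapy=bool(radio[i]), hormone=bool(hormone[i]), chemo=bool(chemo[i]),
            time_days=float(observed[i]),
            event=Event.RECURRENCE if event[i] else Event.CENSORED,
        ))
    cohort = Cohort(records, name=f"synthetic(seed={cfg.seed},n={cfg.n})")
    truth = pd.DataFrame({
        "id": [r.id for r in records],
        "true_event_time_days": t_event,
        "censor_time_days": t_cens,
        "event_observed": event,
        "true_er_positive": er,
        "er_masked": er_missing,
        "mu": mu,
    })
    return cohort, truth


# ---------------------------------------------------------------------------
# small hand-checkable fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationFixture:
    """A tiny cohort with independently hand-computed metric values."""

    cohort: Cohort
    predictions: np.ndarray | None
    horizon_days: float | None
    oracle: dict


def _mk(i, time, event, **kw) -> PatientRecord:
    defaults = dict(age=55.0, nodes=1, grade=2, size_cm=2.0, er=ER.POSITIVE,
                    radiotherapy=False, hormone=False, chemo=False)
    defaults.update(kw)
    return PatientRecord(id=f"F{i}", time_days=float(time),
                         event=Event.RECURRENCE if event else Event.CENSORED,
                         **defaults)


def make_validation_fixture(kind: str) -> ValidationFixture:
    """Deterministic micro-cohorts whose metric values are hand products.

    ``"km_hand"``: six patients, alternating events and censorings — the
    product-limit estimate is 5/6 after the first event, 5/8 after the
    second, 5/16 after the third.
    ``"km_no_censoring"``: four uncensored patients; the estimator must equal
    the empirical survival function.
    ``"concordance"``: four patients at horizon 100 d with predicted risks
    {0.1, 0.4, 0.4, 0.9} and outcomes {0, 0, 1, 1}; exhaustive pair counting
    gives C = 3.5/4 = 0.875 and mean Brier = 0.135.
    """
    if kind == "km_hand":
        records = [_mk(1, 2, True), _mk(2, 4, False), _mk(3, 6, True),
                   _mk(4, 8, False), _mk(5, 10, True), _mk(6, 12, False)]
        oracle = {"S": {2.0: 5 / 6, 6.0: 5 / 8, 10.0: 5 / 16},
                  "S_between": {5.0: 5 / 6, 7.0: 5 / 8, 11.0: 5 / 16}}
        return ValidationFixture(Cohort(records, "km_hand"), None, None, oracle)
    if kind == "km_no_censoring":
        records = [_mk(i, t, True) for i, t in enumerate([1, 2, 3, 4], start=1)]
        oracle = {"S": {0.5: 1.0, 1.0: 0.75, 2.5: 0.5, 4.0: 0.0}}
        return ValidationFixture(Cohort(records, "km_no_censoring"), None, None, oracle)
    if kind == "concordance":
        horizon = 100.0
        records = [
            _mk(1, 150, False),           # event-free at horizon, risk 0.1
            _mk(2, 200, True),            # event after horizon -> y = 0
            _mk(3, 50, True),             # event by horizon, risk 0.4
            _mk(4, 30, True),             # event by horizon, risk 0.9
        ]
        preds = np.array([0.1, 0.4, 0.4, 0.9])
        oracle = {"c": 0.875, "brier": 0.135,
                  "y": np.array([False, False, True, True])}
        return ValidationFixture(Cohort(records, "concordance"), preds, horizon, oracle)
    raise ValueError(f"unknown fixture kind {kind!r}")
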