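"""Accelerated failure time regression for recurrence-free survival.

Time from surgery to first recurrent event is regressed, on the log-time
scale, against prognostic factors (positive axillary nodes, tumour grade,
tumour size, ER status, age), adjuvant-treatment indicators and
treatment-by-factor interactions.  Candidate error families are generalized
gamma, log-normal and log-logistic; AIC selects between them.  Exponentiated
coefficients are time ratios: a ratio above one stretches the survivor
function along the time axis (longer recurrence-free survival), below one
shrinks it.

Covariate transforms follow the final published form: ``ln(nodes + offset)``
for node count and the repeated-power-2 fractional polynomial
``size**2, size**2 * ln(size)`` for tumour diameter; grade and age enter
linearly, ER as a binary indicator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from . import gengamma
from .data_model import ER, Cohort, Event, PatientRecord

__all__ = [
    "DesignSpec",
    "CoefficientSet",
    "AFTFit",
    "build_design_row",
    "build_design_matrix",
    "linear_predictor",
    "size_effect_turning_point",
    "fit_aft",
    "fit_aft_matrix",
    "select_family",
    "fp_search",
    "predict_survival",
    "published_coefficients",
    "average_patient",
    "read_coefficients",
    "write_coefficients",
]

FAMILIES = ("gamma", "lognormal", "loglogistic")
#: deterministic preference when AIC values tie within 2
FAMILY_PREFERENCE = ("gamma", "lognormal", "loglogistic")

#: canonical term order of the final model
DEFAULT_TERMS = (
    "ln_nodes", "size2", "size2_lnsize", "grade", "age", "ercat",
    "adjrt", "adjhormones", "adjchemo",
    "ercat_x_adjhormones", "adjchemo_x_age", "ln_nodes_x_adjchemo",
)
#: terms dropped when predicting baseline (treatment-free) prognosis
TREATMENT_TERMS = frozenset({
    "adjrt", "adjhormones", "adjchemo",
    "ercat_x_adjhormones", "adjchemo_x_age", "ln_nodes_x_adjchemo",
})

_LOGNORMAL_GUARD = 1e-7
_TINY = 1e-300


@dataclass(frozen=True)
class DesignSpec:
    """Covariate-transform recipe mapping a patient to named model terms.

    ``node_offset`` is added inside the node log transform, ``ln(nodes +
    offset)``, so that node-negative women have a finite value; every
    coefficient file records the offset it was estimated with.
    """

    terms: tuple[str, ...] = DEFAULT_TERMS
    node_offset: float = 1.0

    def prognostic_terms(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if t not in TREATMENT_TERMS)


def _as_values(source) -> dict:
    """Normalize a PatientRecord or plain mapping to a covariate dict."""
    if isinstance(source, PatientRecord):
        if source.er is ER.MISSING:
            raise ValueError(f"patient {source.id}: ER status missing — impute upstream")
        return {
            "age": source.age,
            "nodes": float(source.nodes),
            "grade": float(source.grade),
            "size_cm": source.size_cm,
            "er": source.er is ER.POSITIVE,
            "radiotherapy": source.radiotherapy,
            "hormone": source.hormone,
            "chemo": source.chemo,
        }
    return dict(source)


def _require(values: dict, key: str) -> float:
    v = values.get(key)
    if v is None:
        raise ValueError(f"required field {key!r} is missing — impute or supply it upstream")
    return float(v)


def build_design_row(source, spec: DesignSpec = DesignSpec()) -> dict[str, float]:
    """Compute the named model terms for one patient.

    ``source`` is a :class:`PatientRecord` or a mapping with keys ``age``,
    ``nodes``, ``grade``, ``size_cm``, ``er`` (truthy = positive) and, for
    treatment terms, ``radiotherapy``/``hormone``/``chemo``.  Interactions are
    literal products of their parent columns.  A missing required field raises
    — it is never silently coded as zero.
    """
    v = _as_values(source)
    out: dict[str, float] = {}
    for term in spec.terms:
        if term == "ln_nodes":
            out[term] = math.log(_require(v, "nodes") + spec.node_offset)
        elif term == "size2":
            out[term] = _require(v, "size_cm") ** 2
        elif term == "size2_lnsize":
            s = _require(v, "size_cm")
            out[term] = s**2 * math.log(s)
        elif term == "grade":
            out[term] = _require(v, "grade")
        elif term == "age":
            out[term] = _require(v, "age")
        elif term == "ercat":
            out[term] = float(bool(_require(v, "er")))
        elif term == "adjrt":
            out[term] = float(bool(_require(v, "radiotherapy")))
        elif term == "adjhormones":
            out[term] = float(bool(_require(v, "hormone")))
        elif term == "adjchemo":
            out[term] = float(bool(_require(v, "chemo")))
        elif term == "ercat_x_adjhormones":
            out[term] = float(bool(_require(v, "er"))) * float(bool(_require(v, "hormone")))
        elif term == "adjchemo_x_age":
            out[term] = float(bool(_require(v, "chemo"))) * _require(v, "age")
        elif term == "ln_nodes_x_adjchemo":
            out[term] = math.log(_require(v, "nodes") + spec.node_offset) * float(
                bool(_require(v, "chemo"))
            )
        else:
            raise KeyError(f"unknown design term {term!r}")
    return out


def build_design_matrix(cohort: Cohort, spec: DesignSpec = DesignSpec()):
    """Design matrix (n × terms), follow-up times (days) and event indicator."""
    rows = [build_design_row(r, spec) for r in cohort]
    X = np.array([[row[t] for t in spec.terms] for row in rows], dtype=float)
    t = np.array([r.time_days for r in cohort], dtype=float)
    e = np.array([r.event is Event.RECURRENCE for r in cohort], dtype=bool)
    return X, t, e


@dataclass
class CoefficientSet:
    """Regression coefficients of a fitted (or published) AFT model.

    ``betas`` live on the log-time-ratio scale: ``exp(beta)`` is the time
    ratio.  ``sigma``/``kappa`` are the ancillary scale and shape of the
    error family (``kappa`` unused by the log-logistic).  ``intercept`` may be
    ``None`` for a published table whose constant was never printed; absolute
    survival prediction then requires anchoring
    (:meth:`with_anchored_intercept`) or a user-supplied value.
    """

    family: str
    intercept: float | None
    betas: dict[str, float]
    sigma: float
    kappa: float | None = None
    node_offset: float = 1.0
    provenance: str = "fitted"
    se: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.betas)

    def time_ratios(self) -> dict[str, float]:
        return {k: math.exp(b) for k, b in self.betas.items()}

    def spec(self) -> DesignSpec:
        return DesignSpec(terms=self.terms, node_offset=self.node_offset)

    def require_intercept(self) -> float:
        if self.intercept is None:
            raise ValueError(
                "coefficient set has no intercept: supply one or anchor it to a "
                "reference patient (with_anchored_intercept)"
            )
        return self.intercept

    def with_anchored_intercept(self, reference, probability: float, horizon_days: float
                                ) -> "CoefficientSet":
        """Fix the intercept so ``reference`` attains the given recurrence-free
        probability at ``horizon_days`` under the baseline (treatment-free)
        model.  Used when the published constant is unavailable."""
        if not (0 < probability < 1):
            raise ValueError("anchor probability must be in (0,1)")
        eta = _eta_for_survival(probability, self.sigma, self.kappa, self.family)
        row = build_design_row(reference, self.spec())
        contrib = sum(self.betas[t] * row[t] for t in self.betas if t not in TREATMENT_TERMS)
        mu = math.log(horizon_days) - eta
        return CoefficientSet(
            family=self.family, intercept=mu - contrib, betas=dict(self.betas),
            sigma=self.sigma, kappa=self.kappa, node_offset=self.node_offset,
            provenance=self.provenance + "+anchored", se=self.se,
        )


def _eta_for_survival(s: float, sigma: float, kappa, family: str) -> float:
    """sigma*z such that S = s at log-time mu + sigma*z (family quantile)."""
    if family == "gamma":
        p = gengamma.GenGammaParams(0.0, sigma, kappa)
        return math.log(gengamma.quantile(1.0 - s, p))
    if family == "lognormal":
        return sigma * stats.norm.ppf(1.0 - s)
    # log-logistic: S = 1/(1+e^z)
    return sigma * math.log((1.0 - s) / s)


def linear_predictor(source, coeffs: CoefficientSet, include_treatments: bool = True) -> float:
    """mu = intercept + sum(beta * x) on the log-time scale.

    With ``include_treatments=False`` every treatment indicator and
    treatment interaction is dropped — algebraically identical to setting the
    indicator variables to zero, which is how the model predicts baseline
    prognosis in the absence of adjuvant therapy.
    """
    spec = coeffs.spec()
    if not include_treatments:
        spec = DesignSpec(terms=coeffs.spec().prognostic_terms(), node_offset=coeffs.node_offset)
    row = build_design_row(source, spec)
    return coeffs.require_intercept() + sum(coeffs.betas[t] * row[t] for t in spec.terms)


def size_effect_turning_point(coeffs: CoefficientSet) -> float:
    """Tumour diameter (cm) at which the modelled size effect reverses.

    The size contribution to the log-time predictor is
    ``a*s**2 + b*s**2*ln(s)``; its stationary point is
    ``s* = exp(-(2a + b) / (2b))``.  With the published ratios this falls at
    about 7 cm: predicted recurrence-free survival worsens with diameter up to
    that point and improves beyond it.
    """
    try:
        a = coeffs.betas["size2"]
        b = coeffs.betas["size2_lnsize"]
    except KeyError as e:
        raise ValueError(f"size term {e} absent from coefficient set") from e
    if b == 0:
        raise ValueError("size2_lnsize coefficient is zero: the size effect is monotone, "
                         "no turning point exists")
    return math.exp(-(2 * a + b) / (2 * b))


# ---------------------------------------------------------------------------
# censored maximum likelihood
# ---------------------------------------------------------------------------

def _logf_logS(logt: np.ndarray, mu: np.ndarray, sigma: float, kappa: float, family: str):
    """Vectorized log-density and log-survival for all three families."""
    z = (logt - mu) / sigma
    if family == "lognormal" or (family == "gamma" and abs(kappa) < _LOGNORMAL_GUARD):
        logf = stats.norm.logpdf(z) - math.log(sigma) - logt
        logS = stats.norm.logsf(z)
    elif family == "gamma":
        logf = gengamma._gengamma_logf_z(z, kappa) - math.log(sigma) - logt
        gam = kappa**-2
        u = gam * np.exp(np.clip(kappa * z, -200.0, 200.0))
        S = special.gammaincc(gam, u) if kappa > 0 else special.gammainc(gam, u)
        logS = np.log(np.maximum(S, _TINY))
    elif family == "loglogistic":
        # S(t) = 1 / (1 + (t/e^mu)^(1/sigma)) = 1 / (1 + e^z)
        sp = np.logaddexp(0.0, z)  # softplus
        logS = -sp
        logf = z - 2.0 * sp - math.log(sigma) - logt
    else:
        raise ValueError(f"unknown family {family!r}")
    return logf, logS


def _n_shape_params(family: str) -> int:
    return 2 if family == "gamma" else 1  # (ln sigma, kappa) vs (ln sigma,)


def _unpack(theta: np.ndarray, p: int, family: str):
    intercept = theta[0]
    beta = theta[1 : 1 + p]
    sigma = math.exp(theta[1 + p])
    kappa = theta[2 + p] if family == "gamma" else (0.0 if family == "lognormal" else None)
    return intercept, beta, sigma, kappa


def _negloglik(theta, X, logt, event, family):
    p = X.shape[1]
    # reject wild shape/scale values before they overflow
    if abs(theta[1 + p]) > 12 or (family == "gamma" and abs(theta[2 + p]) > 8):
        return 1e12
    intercept, beta, sigma, kappa = _unpack(theta, p, family)
    mu = intercept + X @ beta
    logf, logS = _logf_logS(logt, mu, sigma, kappa, family)
    ll = np.sum(np.where(event, logf, logS))
    return -ll if np.isfinite(ll) else 1e12


def _numerical_grad(f, x, step=1e-6):
    g = np.empty_like(x)
    h = step * (1.0 + np.abs(x))
    for i in range(len(x)):
        e = np.zeros_like(x); e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2 * h[i])
    return g


def _newton_polish(f, x, max_steps=10):
    """A few damped Newton steps with numerical derivatives.

    Quasi-Newton alone stalls in the nearly flat shape direction of the
    generalized-gamma likelihood; explicit Newton steps with the true
    curvature finish the job.  Returns (x, f(x), newton_decrement)."""
    fx = f(x)
    decrement = np.inf
    for _ in range(max_steps):
        g = _numerical_grad(f, x)
        H = _numerical_hessian(f, x)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        decrement = float(abs(g @ step)) / 2.0
        if decrement < 1e-9:
            break
        lam, improved = 1.0, False
        while lam > 1e-4:
            x_new = x - lam * step
            f_new = f(x_new)
            if f_new < fx - 1e-12:
                x, fx, improved = x_new, f_new, True
                break
            lam /= 2.0
        if not improved:
            break
    return x, fx, decrement


def _numerical_hessian(f, x, step=1e-4):
    n = len(x)
    H = np.empty((n, n))
    h = step * (1.0 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej); fpm = f(x + ei - ej)
            fmp = f(x - ei + ej); fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


@dataclass
class AFTFit:
    """A fitted AFT model: coefficients plus fit diagnostics.

    ``cov`` is the variance–covariance matrix on the estimation scale —
    (intercept, betas..., ln sigma[, kappa]) — with row/column names in
    ``cov_names``; Rubin's-rules pooling operates on exactly this scale.
    """

    coeffs: CoefficientSet
    loglik: float
    aic: float
    n: int
    n_events: int
    converged: bool
    grad_norm: float
    cov: np.ndarray | None = None
    cov_names: tuple[str, ...] = ()

    def se(self, name: str) -> float:
        if self.cov is not None:
            i = self.cov_names.index(name)
            return math.sqrt(self.cov[i, i])
        if self.coeffs.se and name in self.coeffs.se:
            return self.coeffs.se[name]
        raise ValueError(f"no standard error available for {name!r}")

    def params_on_estimation_scale(self) -> dict[str, float]:
        c = self.coeffs
        out = {"intercept": c.intercept, **c.betas, "ln_sigma": math.log(c.sigma)}
        if c.family == "gamma":
            out["kappa"] = c.kappa
        return out


def fit_aft_matrix(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    term_names: Sequence[str],
    family: str = "gamma",
    node_offset: float = 1.0,
    min_events: int = 10,
    max_restarts: int = 3,
    seed: int = 0,
) -> AFTFit:
    """Censored maximum-likelihood fit of an AFT model on a raw design matrix.

    Maximizes sum over events of ln f(t_i) plus sum over censored of
    ln S(t_i) in (intercept, beta, ln sigma[, kappa]) by quasi-Newton descent
    with jittered restarts; the generalized-gamma likelihood can be multimodal
    in kappa, so the best of the restarts is kept.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    n, p = X.shape
    if event.sum() < min_events:
        raise ValueError(f"need >= {min_events} events to fit, got {int(event.sum())}")
    if p:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
        if rank < p + 1:
            raise np.linalg.LinAlgError(
                f"singular design: {p + 1} columns (incl. intercept) but rank {rank}; "
                f"check collinearity among {list(term_names)}"
            )
    logt = np.log(time)

    # log-normal moment start: exact MLE when there is no censoring
    x0 = np.zeros(1 + p + _n_shape_params(family))
    x0[0] = float(np.mean(logt))
    x0[1 + p] = math.log(max(float(np.std(logt)), 1e-3))
    if family == "gamma":
        x0[2 + p] = 0.1

    rng = np.random.default_rng(seed)
    nll = lambda th: _negloglik(th, X, logt, event, family)
    best_x, best_f = None, np.inf
    decrement = np.inf
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(scale=0.3, size=x0.shape)
        res = optimize.minimize(nll, start, method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        x_pol, f_pol, dec = _newton_polish(nll, res.x)
        if f_pol < best_f - 1e-10:
            best_x, best_f, decrement = x_pol, f_pol, dec
        if decrement < 1e-8:
            break
    theta = best_x
    loglik = -best_f
    gnorm = float(np.max(np.abs(_numerical_grad(nll, theta))))
    converged = bool(decrement < 1e-6)
    if not converged and decrement > 1e-2:
        raise RuntimeError(
            f"AFT fit did not converge after {max_restarts + 1} starts "
            f"(Newton decrement {decrement:.3g}, gradient max-norm {gnorm:.3g})"
        )

    intercept, beta, sigma, kappa = _unpack(theta, p, family)
    k = len(theta)
    aic = 2 * k - 2 * loglik
    names = ("intercept", *term_names, "ln_sigma") + (("kappa",) if family == "gamma" else ())
    cov = None
    se = None
    try:
        H = _numerical_hessian(nll, theta)
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if np.all(d > 0):
            se = {nm: math.sqrt(d[i]) for i, nm in enumerate(names)}
        else:
            cov = None
    except np.linalg.LinAlgError:
        cov = None
    coeffs = CoefficientSet(
        family=family, intercept=float(intercept),
        betas={nm: float(b) for nm, b in zip(term_names, beta)},
        sigma=float(sigma), kappa=(float(kappa) if kappa is not None else None),
        node_offset=node_offset, provenance="fitted", se=se,
    )
    return AFTFit(coeffs=coeffs, loglik=float(loglik), aic=float(aic), n=n,
                  n_events=int(event.sum()), converged=converged, grad_norm=gnorm,
                  cov=cov, cov_names=names)


def fit_aft(cohort: Cohort, spec: DesignSpec = DesignSpec(), family: str = "gamma",
            **kw) -> AFTFit:
    """Fit an AFT model to a cohort with complete covariate data."""
    X, t, e = build_design_matrix(cohort, spec)
    return fit_aft_matrix(X, t, e, spec.terms, family=family,
                          node_offset=spec.node_offset, **kw)


def select_family(cohort: Cohort, spec: DesignSpec = DesignSpec(), **kw):
    """Fit all three candidate families and pick the smallest AIC.

    Ties within two AIC points are broken by the fixed preference order
    gamma > log-normal > log-logistic and flagged.  Returns
    ``(family, {family: AFTFit}, tie_flag)``; families whose fit fails are
    excluded with a warning entry of ``None``.
    """
    fits: dict[str, AFTFit | None] = {}
    for fam in FAMILIES:
        try:
            fits[fam] = fit_aft(cohort, spec, family=fam, **kw)
        except (RuntimeError, np.linalg.LinAlgError, ValueError):
            fits[fam] = None
    ok = {f: fit for f, fit in fits.items() if fit is not None}
    if not ok:
        raise RuntimeError("all candidate family fits failed")
    best_aic = min(fit.aic for fit in ok.values())
    contenders = [f for f in FAMILY_PREFERENCE if f in ok and ok[f].aic < best_aic + 2.0]
    tie = len(contenders) > 1
    return contenders[0], fits, tie


# ---------------------------------------------------------------------------
# fractional polynomials
# ---------------------------------------------------------------------------

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def _fp_column(x: np.ndarray, power: float) -> np.ndarray:
    return np.log(x) if power == 0.0 else x**power


def _fp_terms(x: np.ndarray, powers: tuple[float, ...]):
    """FP basis columns; a repeated power p contributes x^p and x^p*ln x."""
    if len(powers) == 2 and powers[0] == powers[1]:
        base = _fp_column(x, powers[0])
        return [base, base * np.log(x)]
    return [_fp_column(x, p) for p in powers]


@dataclass
class FPResult:
    powers: tuple[float, ...] | None   # None = covariate excluded
    degree: int                        # 0 excluded, 1 linear/FP1, 2 FP2
    label: str                         # "excluded" | "linear" | "FP1" | "FP2"
    deviances: dict
    pvalues: dict


def fp_search(
    cohort: Cohort,
    covariate: str,
    base_spec: DesignSpec,
    family: str = "gamma",
    alpha: float = 0.05,
    shift: float = 0.0,
    seed: int = 0,
) -> FPResult:
    """Fractional-polynomial search for one continuous covariate.

    Fits the base model plus FP transforms of ``covariate`` over the standard
    power grid (power 0 meaning ln x; a repeated power p meaning x^p and
    x^p ln x) and applies the closed test at level ``alpha``: best FP2 against
    the covariate-free model (4 df), against linear (3 df), then against the
    best FP1 (2 df), stopping at the first non-significant comparison.
    """
    Xb, t, e = build_design_matrix(cohort, base_spec)
    x = np.array([getattr(r, covariate) for r in cohort], dtype=float) + shift
    if np.any(x <= 0):
        raise ValueError(
            f"{covariate} has non-positive values; supply a positive shift"
        )

    def deviance(extra_cols, extra_names):
        X = np.column_stack([Xb, *extra_cols]) if extra_cols else Xb
        fit = fit_aft_matrix(X, t, e, tuple(base_spec.terms) + tuple(extra_names),
                             family=family, node_offset=base_spec.node_offset, seed=seed)
        return -2.0 * fit.loglik

    dev: dict = {"null": deviance([], [])}
    dev["linear"] = deviance([x], [f"{covariate}_p1"])
    fp1 = {}
    for pw in FP_POWERS:
        fp1[(pw,)] = deviance(_fp_terms(x, (pw,)), [f"{covariate}_fp1"])
    best1 = min(fp1, key=lambda k: (fp1[k], k))
    fp2 = {}
    for i, p1 in enumerate(FP_POWERS):
        for p2 in FP_POWERS[i:]:
            fp2[(p1, p2)] = deviance(_fp_terms(x, (p1, p2)),
                                     [f"{covariate}_fp2a", f"{covariate}_fp2b"])
    best2 = min(fp2, key=lambda k: (fp2[k], k))

    def pval(d_big_minus_small, df):
        return float(stats.chi2.sf(max(d_big_minus_small, 0.0), df))

    p_any = pval(dev["null"] - fp2[best2], 4)
    p_nonlin = pval(dev["linear"] - fp2[best2], 3)
    p_fp2 = pval(fp1[best1] - fp2[best2], 2)
    pvalues = {"any_effect": p_any, "nonlinearity": p_nonlin, "fp2_vs_fp1": p_fp2}
    deviances = {"null": dev["null"], "linear": dev["linear"],
                 "best_fp1": (best1, fp1[best1]), "best_fp2": (best2, fp2[best2])}
    if p_any > alpha:
        return FPResult(None, 0, "excluded", deviances, pvalues)
    if p_nonlin > alpha:
        return FPResult((1.0,), 1, "linear", deviances, pvalues)
    if p_fp2 > alpha:
        return FPResult(best1, 1, "FP1", deviances, pvalues)
    return FPResult(best2, 2, "FP2", deviances, pvalues)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def survival_given_mu(t, mu: float, coeffs: CoefficientSet):
    """S(t) for a patient whose linear predictor is ``mu``."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("time must be > 0")
    if coeffs.family == "gamma":
        return gengamma.survival(t, gengamma.GenGammaParams(mu, coeffs.sigma, coeffs.kappa))
    z = (np.log(t) - mu) / coeffs.sigma
    if coeffs.family == "lognormal":
        s = stats.norm.sf(z)
    else:  # loglogistic
        s = special.expit(-z)
    return s if np.ndim(s) else float(s)


def predict_survival(source, coeffs: CoefficientSet, t, include_treatments: bool = True):
    """Predicted recurrence-free survival probability at time ``t`` (days)."""
    mu = linear_predictor(source, coeffs, include_treatments=include_treatments)
    return survival_given_mu(t, mu, coeffs)


# ---------------------------------------------------------------------------
# published coefficient table and JSON serialization
# ---------------------------------------------------------------------------

#: exponentiated coefficients (time ratios) of the final aggregated model
PUBLISHED_TIME_RATIOS = {
    "ln_nodes": 0.402,
    "size2": 0.898,
    "size2_lnsize": 1.045,
    "grade": 0.647,
    "age": 1.015,
    "ercat": 1.209,
    "adjrt": 1.546,
    "adjhormones": 1.230,
    "adjchemo": 0.357,
    "ercat_x_adjhormones": 1.226,
    "adjchemo_x_age": 1.023,
    "ln_nodes_x_adjchemo": 1.418,
}
#: printed ancillary parameters of the generalized gamma error distribution
PUBLISHED_ANCILLARY_1 = 1.698   # sigma
PUBLISHED_ANCILLARY_2 = 0.567   # kappa (direct reading; see ancillary_scale)

#: the "average" development-cohort patient used as a reference profile
AVERAGE_PATIENT = {
    "age": 56.6, "nodes": 1.2, "grade": 2, "size_cm": 2.2, "er": True,
    "radiotherapy": False, "hormone": False, "chemo": False,
}


def average_patient() -> dict:
    """Covariate profile of the average development-cohort patient
    (56.6 years, 1.2 positive nodes, grade 2, ER-positive, 2.2 cm)."""
    return dict(AVERAGE_PATIENT)


def published_coefficients(ancillary_scale: str = "direct",
                           node_offset: float = 1.0,
                           intercept: float | None = None) -> CoefficientSet:
    """The published aggregated model as a :class:`CoefficientSet`.

    The covariate rows are printed as time ratios, so betas are their natural
    logs.  The two ancillary rows are ambiguous: the special-case conditions
    quoted for them (both equal to 1 for the exponential submodel, the second
    equal to 0 for log-normal) only hold on the original scale, which suggests
    the printed 1.698/0.567 are sigma and kappa directly
    (``ancillary_scale="direct"``, the default); if instead they were
    exponentiated like the covariate rows, kappa = ln 0.567
    (``ancillary_scale="exponentiated"``).  The intercept was never published:
    it defaults to ``None`` and must be anchored or supplied before absolute
    survival prediction.
    """
    sigma = PUBLISHED_ANCILLARY_1
    if ancillary_scale == "direct":
        kappa = PUBLISHED_ANCILLARY_2
    elif ancillary_scale == "exponentiated":
        kappa = math.log(PUBLISHED_ANCILLARY_2)
    else:
        raise ValueError("ancillary_scale must be 'direct' or 'exponentiated'")
    betas = {k: math.log(v) for k, v in PUBLISHED_TIME_RATIOS.items()}
    return CoefficientSet(family="gamma", intercept=intercept, betas=betas,
                          sigma=sigma, kappa=kappa, node_offset=node_offset,
                          provenance="published")


def write_coefficients(coeffs: CoefficientSet, path) -> None:
    obj = {
        "family": coeffs.family,
        "intercept": coeffs.intercept,
        "terms": {
            name: {
                "beta": beta,
                "time_ratio": math.exp(beta),
                **({"se": coeffs.se[name]} if coeffs.se and name in coeffs.se else {}),
            }
            for name, beta in coeffs.betas.items()
        },
        "sigma": coeffs.sigma,
        "kappa": coeffs.kappa,
        "node_offset": coeffs.node_offset,
        "provenance": coeffs.provenance,
    }
    if coeffs.se is not None:
        obj["se"] = coeffs.se
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


def read_coefficients(path) -> CoefficientSet:
    with open(path) as fh:
        obj = json.load(fh)
    betas = {name: d["beta"] for name, d in obj["terms"].items()}
    se = obj.get("se") or \
        ({name: d["se"] for name, d in obj["terms"].items() if "se" in d} or None)
    return CoefficientSet(
        family=obj["family"], intercept=obj["intercept"], betas=betas,
        sigma=obj["sigma"], kappa=obj.get("kappa"),
        node_offset=obj.get("node_offset", 1.0),
        provenance=obj.get("provenance", "fitted"), se=se,
    )
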