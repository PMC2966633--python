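"""Baseline-risk prediction, external treatment-effect adjustment, prognostic
indices and risk grouping.

Because treatment coefficients estimated from observational cohorts are
confounded by indication (the sickest women get chemotherapy), absolute
predictions for treated patients apply *published* hazard ratios from
randomized meta-analyses to the model's baseline risk instead:
``S_adj(t) = S_base(t)**HR`` with the combined HR the product over received
treatments, the hormone-therapy HR conditional on ER status.

Patients are ranked by a prognostic index (PI) — the treatment-free linear
predictor — and grouped by cut points chosen to minimize Cox's information
loss L, the weighted within-group variance of the index divided by its total
variance.  The Nottingham Prognostic Index (node stage + grade + 0.2 x size)
is provided as the standard comparator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aft import CoefficientSet, linear_predictor, predict_survival
from .data_model import DAYS_PER_YEAR, ER, PatientRecord

__all__ = [
    "TreatmentEffectTable",
    "PrognosticGroupScheme",
    "OPI_GROUPS",
    "NPI_GROUPS",
    "DEFAULT_TREATMENT_EFFECTS",
    "baseline_survival",
    "combined_hazard_ratio",
    "adjust_for_treatment",
    "opi",
    "npi",
    "assign_group",
    "cox_information_loss",
    "optimal_grouping",
    "optimal_grouping_normal",
    "reference_table",
]


@dataclass(frozen=True)
class TreatmentEffectTable:
    """Hazard ratios for adjuvant treatments, applied to baseline risk.

    ``hormone_er_pos``/``hormone_er_neg`` split the hormone-therapy effect by
    ER status (endocrine therapy helps ER-positive disease).  HR = 1 encodes
    no effect; all HRs must be positive.
    """

    radiotherapy: float = 0.70
    hormone_er_pos: float = 0.58
    hormone_er_neg: float = 0.94
    chemo: float = 0.74

    def __post_init__(self) -> None:
        for k, v in self.as_dict().items():
            if not (v > 0):
                raise ValueError(f"hazard ratio {k} must be > 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {
            "radiotherapy": self.radiotherapy,
            "hormone_er_pos": self.hormone_er_pos,
            "hormone_er_neg": self.hormone_er_neg,
            "chemo": self.chemo,
        }

    def hormone(self, er_positive: bool) -> float:
        return self.hormone_er_pos if er_positive else self.hormone_er_neg


#: meta-analysis-style default HRs; configurable, never treated as ground truth
DEFAULT_TREATMENT_EFFECTS = TreatmentEffectTable()

_KNOWN_TREATMENTS = frozenset({"radiotherapy", "hormone", "chemo"})


@dataclass(frozen=True)
class PrognosticGroupScheme:
    """Ordered cut points on a continuous index with group labels.

    Intervals are closed on the upper end: value <= first cut point gets the
    first label, and so on; values above the last cut point get the final
    label.  ``higher_is_better`` records the orientation of the index (true
    for a time-ratio-scale PI, false for the NPI).
    """

    index_name: str
    cutpoints: tuple[float, ...]
    labels: tuple[str, ...]
    higher_is_better: bool

    def __post_init__(self) -> None:
        if list(self.cutpoints) != sorted(self.cutpoints):
            raise ValueError("cut points must be strictly ascending")
        if len(set(self.cutpoints)) != len(self.cutpoints):
            raise ValueError("cut points must be strictly ascending")
        if len(self.labels) != len(self.cutpoints) + 1:
            raise ValueError("need exactly one more label than cut points")


#: published PI cut points for the model's index (higher = better prognosis).
#: Shipped as metadata: they depend on the unpublished model constant and the
#: original cohort, so they are not recomputable here.
OPI_GROUPS = PrognosticGroupScheme(
    index_name="OPI",
    cutpoints=(6.42, 7.59, 8.32, 8.86),
    labels=("poor", "moderate II", "moderate I", "good", "excellent"),
    higher_is_better=True,
)

#: conventional NPI cut points (higher = worse prognosis)
NPI_GROUPS = PrognosticGroupScheme(
    index_name="NPI",
    cutpoints=(2.4, 3.4, 4.4, 5.4),
    labels=("excellent", "good", "moderate I", "moderate II", "poor"),
    higher_is_better=False,
)


def baseline_survival(record, coeffs: CoefficientSet, t):
    """Recurrence-free survival with all treatment indicators at zero."""
    return predict_survival(record, coeffs, t, include_treatments=False)


def combined_hazard_ratio(effects: TreatmentEffectTable,
                          received: Sequence[str] | set,
                          er_positive: bool) -> float:
    """Product of the HRs of the treatments actually received."""
    hr = 1.0
    for treatment in received:
        if treatment not in _KNOWN_TREATMENTS:
            raise KeyError(f"unknown treatment {treatment!r}; expected one of "
                           f"{sorted(_KNOWN_TREATMENTS)}")
        if treatment == "radiotherapy":
            hr *= effects.radiotherapy
        elif treatment == "hormone":
            hr *= effects.hormone(er_positive)
        else:
            hr *= effects.chemo
    return hr


def adjust_for_treatment(s_base: Callable, effects: TreatmentEffectTable,
                         received: Sequence[str] | set, er_positive: bool) -> Callable:
    """Apply external treatment hazard ratios to a baseline survival function.

    The HRs act proportionally on the baseline cumulative hazard, so
    ``S_adj(t) = S_base(t)**HR``; the order treatments are listed in is
    immaterial.  Returns a new survival function of t.
    """
    hr = combined_hazard_ratio(effects, received, er_positive)

    def s_adj(t):
        return np.asarray(s_base(t), dtype=float) ** hr

    return s_adj


def received_treatments(record: PatientRecord) -> set[str]:
    """The treatments a patient's indicators mark as received (missing -> error)."""
    out = set()
    for name in ("radiotherapy", "hormone", "chemo"):
        v = getattr(record, name)
        if v is None:
            raise ValueError(f"patient {record.id}: treatment indicator {name} missing")
        if v:
            out.add(name)
    return out


def opi(record, coeffs: CoefficientSet) -> float:
    """Prognostic index: the treatment-free linear predictor.

    Higher values mean longer predicted time to recurrence.  When the
    coefficient set has no intercept the centred index (intercept omitted) is
    still a valid ranking; callers needing the published cut points must
    anchor the intercept first.
    """
    if coeffs.intercept is None:
        shifted = CoefficientSet(
            family=coeffs.family, intercept=0.0, betas=dict(coeffs.betas),
            sigma=coeffs.sigma, kappa=coeffs.kappa, node_offset=coeffs.node_offset,
            provenance=coeffs.provenance, se=coeffs.se)
        return linear_predictor(record, shifted, include_treatments=False)
    return linear_predictor(record, coeffs, include_treatments=False)


def _node_stage(nodes: int) -> int:
    if nodes < 0:
        raise ValueError("nodes must be >= 0")
    return 1 if nodes == 0 else (2 if nodes <= 3 else 3)


def npi(record) -> float:
    """Nottingham Prognostic Index: node stage + grade + 0.2 x size (cm)."""
    if isinstance(record, PatientRecord):
        nodes, grade, size = record.nodes, record.grade, record.size_cm
    else:
        nodes, grade, size = record["nodes"], record["grade"], record["size_cm"]
    if nodes is None or grade is None or size is None:
        raise ValueError("NPI needs nodes, grade and size")
    return _node_stage(int(nodes)) + grade + 0.2 * size


def assign_group(value: float, scheme: PrognosticGroupScheme) -> str:
    """Label the group a value falls in (upper-closed intervals)."""
    if not np.isfinite(value):
        raise ValueError(f"index value must be finite, got {value}")
    for cut, label in zip(scheme.cutpoints, scheme.labels):
        if value <= cut:
            return label
    return scheme.labels[-1]


# ---------------------------------------------------------------------------
# Cox's information loss and optimal grouping
# ---------------------------------------------------------------------------

def cox_information_loss(values, cutpoints: Sequence[float]) -> float:
    """Information lost by grouping a continuous index.

    L = sum_g (n_g / n) Var_g / Var_total with population (divide-by-n)
    variances, so 0 <= L <= 1: 0 when every group is internally constant,
    1 when grouping explains nothing.
    """
    v = np.asarray(values, dtype=float)
    total = float(np.var(v))
    if total == 0:
        raise ValueError("index has zero variance; L is undefined")
    edges = [-np.inf, *sorted(cutpoints), np.inf]
    num = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        grp = v[(v > lo) & (v <= hi)]
        if grp.size:
            num += grp.size * float(np.var(grp))
    return num / (v.size * total)


def _within_group_sse_matrix(v: np.ndarray) -> np.ndarray:
    """sse[i, j] = within-SSE of sorted v[i..j] inclusive, via prefix sums."""
    n = v.size
    cs = np.concatenate([[0.0], np.cumsum(v)])
    cs2 = np.concatenate([[0.0], np.cumsum(v * v)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cnt = (j - i + 1).astype(float)
    s = cs[j + 1] - cs[i]
    s2 = cs2[j + 1] - cs2[i]
    with np.errstate(invalid="ignore"):
        sse = s2 - s * s / cnt
    return np.where(j >= i, np.maximum(sse, 0.0), np.inf)


def optimal_grouping(values, k: int):
    """Cut points minimizing L for an empirical sample, by exact dynamic
    programming over boundaries between sorted observations.

    Returns ``(cutpoints, proportions, L)``; cut points are midpoints between
    the adjacent order statistics that separate the optimal groups, and among
    equal-L solutions the lexicographically smallest cut-point vector wins.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(v).size < k:
        raise ValueError(f"need at least {k} distinct values for {k} groups")
    sse = _within_group_sse_matrix(v)
    # dp[g, j] = min within-SSE of partitioning v[0..j] into g+1 groups
    dp = np.full((k, n), np.inf)
    arg = np.zeros((k, n), dtype=int)
    dp[0] = sse[0]
    for g in range(1, k):
        for j in range(g, n):
            cand = dp[g - 1, g - 1 : j] + sse[g : j + 1, j]
            i = int(np.argmin(cand))  # first minimum = smallest boundary
            dp[g, j] = cand[i]
            arg[g, j] = g + i  # start index of group g+1
    # backtrack group start indices
    starts = []
    j = n - 1
    for g in range(k - 1, 0, -1):
        s = arg[g, j]
        starts.append(s)
        j = s - 1
    starts = sorted(starts)
    cutpoints = tuple((v[s - 1] + v[s]) / 2.0 for s in starts)
    bounds = [0, *starts, n]
    proportions = tuple((b - a) / n for a, b in zip(bounds[:-1], bounds[1:]))
    L = dp[k - 1, n - 1] / (n * float(np.var(v)))
    return cutpoints, proportions, float(L)


def optimal_grouping_normal(k: int, tol: float = 1e-12, max_iter: int = 10_000):
    """Cut points minimizing L for a standard normal index (fixed point).

    At an optimum each cut point equals the mean of the conditional means of
    the two groups it separates (the stationarity condition of the weighted
    within-group variance), so Lloyd-style iteration from equiprobable start
    points converges to the optimal quantizer.  Returns
    ``(cutpoints, proportions_pct, L)``; proportions are percentages.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    c = stats.norm.ppf(np.linspace(0, 1, k + 1)[1:-1])
    for _ in range(max_iter):
        edges = np.concatenate([[-np.inf], c, [np.inf]])
        # conditional means of N(0,1) on (a, b]: (phi(a)-phi(b)) / (Phi(b)-Phi(a))
        phi = stats.norm.pdf(edges[:-1]) - stats.norm.pdf(edges[1:])
        mass = stats.norm.cdf(edges[1:]) - stats.norm.cdf(edges[:-1])
        m = phi / mass
        new_c = (m[:-1] + m[1:]) / 2.0
        if np.max(np.abs(new_c - c)) < tol:
            c = new_c
            break
        c = new_c
    edges = np.concatenate([[-np.inf], c, [np.inf]])
    mass = stats.norm.cdf(edges[1:]) - stats.norm.cdf(edges[:-1])
    phi = stats.norm.pdf(edges[:-1]) - stats.norm.pdf(edges[1:])
    m = phi / mass
    # L = 1 - between-variance (total variance is 1)
    L = 1.0 - float(np.sum(mass * m**2))
    return tuple(float(x) for x in c), tuple(float(100 * p) for p in mass), L


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------

DEFAULT_HORIZONS_YEARS = (5.0, 10.0, 15.0)


def reference_table(
    coeffs: CoefficientSet,
    effects: TreatmentEffectTable = DEFAULT_TREATMENT_EFFECTS,
    grid: Mapping[str, Sequence] | None = None,
    horizons_years: Sequence[float] = DEFAULT_HORIZONS_YEARS,
    treatments: Sequence[str] = ("radiotherapy", "hormone", "chemo"),
) -> pd.DataFrame:
    """Tabulate recurrence-free probabilities over a covariate grid.

    One row per grid cell; columns give the baseline probability at each
    horizon and the probability adjusted for the listed external treatment
    effects.  Requires a fitted or anchored intercept.
    """
    coeffs.require_intercept()
    grid = dict(grid or {})
    grid.setdefault("nodes", [0, 1, 3, 5, 10])
    grid.setdefault("grade", [1, 2, 3])
    grid.setdefault("size_cm", [1.0, 2.0, 3.0, 5.0])
    grid.setdefault("age", [50.0])
    grid.setdefault("er", [True])
    rows = []
    keys = list(grid)
    mesh = np.meshgrid(*[np.arange(len(grid[k])) for k in keys], indexing="ij")
    for idx in zip(*[m.ravel() for m in mesh]):
        patient = {k: grid[k][i] for k, i in zip(keys, idx)}
        patient.setdefault("er", True)
        row = dict(patient)
        hr = combined_hazard_ratio(effects, treatments, bool(patient["er"]))
        for hy in horizons_years:
            s = baseline_survival(patient, coeffs, hy * DAYS_PER_YEAR)
            row[f"baseline_{hy:g}y"] = s
            row[f"treated_{hy:g}y"] = s**hr
        rows.append(row)
    return pd.DataFrame(rows)
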