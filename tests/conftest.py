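"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately naive (explicit loops,
recursive products) so they stay independent of the vectorized library code
they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

import aftprog as ap
from aftprog.data_model import ER, Cohort, Event, PatientRecord


def make_record(i, time=1000.0, event=False, **kw) -> PatientRecord:
    defaults = dict(age=55.0, nodes=1, grade=2, size_cm=2.0, er=ER.POSITIVE,
                    radiotherapy=True, hormone=False, chemo=False)
    defaults.update(kw)
    return PatientRecord(id=f"P{i}", time_days=float(time),
                         event=Event.RECURRENCE if event else Event.CENSORED,
                         **defaults)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    rng = np.random.default_rng(42)
    records = []
    for i in range(100):
        records.append(make_record(
            i,
            time=float(rng.uniform(30, 6000)),
            event=bool(rng.uniform() < 0.4),
            age=float(rng.uniform(30, 80)),
            nodes=int(rng.poisson(1.5)),
            grade=int(rng.integers(1, 4)),
            size_cm=float(rng.uniform(0.5, 6)),
            er=[ER.POSITIVE, ER.NEGATIVE, ER.MISSING][int(rng.integers(0, 3))],
            radiotherapy=bool(rng.integers(0, 2)),
            hormone=[True, False, None][int(rng.integers(0, 3))],
            chemo=bool(rng.integers(0, 2)),
        ))
    return Cohort(records, name="random100")


@pytest.fixture(scope="session")
def sim_cohort_2000():
    """One simulated cohort shared by fitting tests."""
    return ap.simulate_cohort(ap.SimulationConfig(n=2000, seed=7))


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def km_brute(times, events, t_query):
    """Product-limit estimate by direct recursion over distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    s = 1.0
    for te in sorted(set(times[events])):
        if te > t_query:
            break
        at_risk = np.sum(times >= te)
        d = np.sum((times == te) & events)
        s *= 1.0 - d / at_risk
    return s


def c_brute(pred, y):
    """Concordance by exhaustive pair counting, ties = 1/2."""
    pred, y = np.asarray(pred, float), np.asarray(y, bool)
    num = den = 0.0
    for i in range(len(pred)):
        for j in range(len(pred)):
            if y[i] and not y[j]:
                den += 1
                if pred[i] > pred[j]:
                    num += 1
                elif pred[i] == pred[j]:
                    num += 0.5
    return num / den


def brier_brute(pred, y):
    total = 0.0
    for p, yi in zip(pred, y):
        total += (p - float(yi)) ** 2
    return total / len(pred)


def cox_l_brute(values, cutpoints):
    """Cox's information loss via explicit per-group population variances."""
    v = np.asarray(values, float)
    groups = []
    edges = [-np.inf, *sorted(cutpoints), np.inf]
    for lo, hi in zip(edges[:-1], edges[1:]):
        g = [x for x in v if lo < x <= hi]
        if g:
            groups.append(np.asarray(g))
    num = sum(len(g) * np.mean((g - g.mean()) ** 2) for g in groups)
    return num / (len(v) * np.mean((v - v.mean()) ** 2))


def optimal_grouping_brute(values, k):
    """Exhaustive search over all placements of group boundaries."""
    v = np.sort(np.asarray(values, float))
    n = len(v)
    best = (np.inf, None)
    for starts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *starts, n]
        sse = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            g = v[a:b]
            sse += len(g) * np.mean((g - g.mean()) ** 2)
        L = sse / (n * np.mean((v - v.mean()) ** 2))
        if L < best[0] - 1e-12:
            cuts = tuple((v[s - 1] + v[s]) / 2 for s in starts)
            best = (L, cuts)
    return best[1], best[0]
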