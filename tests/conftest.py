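from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import coclaims as cc

FOLLOWUP_DAYS = 365


@dataclass
class Member:
    """Minimal cohort-member stub for single-member operations."""

    person_id: str
    followup_start: pd.Timestamp
    followup_end: pd.Timestamp = None

    def __post_init__(self):
        self.followup_start = pd.Timestamp(self.followup_start)
        if self.followup_end is None:
            self.followup_end = (self.followup_start
                                 + pd.Timedelta(days=FOLLOWUP_DAYS))
        else:
            self.followup_end = pd.Timestamp(self.followup_end)


@pytest.fixture
def member():
    return Member("P1", "2015-01-01")


@pytest.fixture(scope="session")
def config():
    return cc.default_codelists()


@pytest.fixture(scope="session")
def synth500():
    """Moderate synthetic dataset shared across read-only tests."""
    params = cc.SimulationParams(n_patients=500, seed=7)
    dataset, truth = cc.generate(params)
    return params, dataset, truth


def make_dispensations(rows):
    """rows: (person_id, prescriber, din, date, qty) tuples."""
    return pd.DataFrame(
        [dict(person_id=p, prescriber_id=pr, din=d,
              dispense_date=pd.Timestamp(dt), quantity=q,
              total_cost=50.0, govt_paid_fraction=0.5)
         for p, pr, d, dt, q in rows])


def make_service_claims(rows):
    """rows: (person_id, provider, ptype, date) or with fee/valid/setting
    extras as dict."""
    out = []
    for r in rows:
        base = dict(person_id=r[0], provider_id=r[1], provider_type=r[2],
                    service_date=pd.Timestamp(r[3]), diagnosis_code=None,
                    fee_code="VISIT", setting="outpatient", valid=True,
                    in_province=True)
        if len(r) > 4:
            base.update(r[4])
        out.append(base)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Independent day-by-day PDC oracles

def oracle_covered_accumulate(dispensations, window_days=FOLLOWUP_DAYS):
    """Tablet total with end-of-window truncation, walked day by day: each
    dispensation's tablets are consumed one per day from its dispense date
    and tablets that would be consumed after the window end are discarded.

    Same-day dispensations pool their tablets (product switching), so a
    split dispensation covers the same days as the whole.

    ``dispensations``: iterable of (day_offset, quantity).
    """
    by_day = {}
    for day, qty in dispensations:
        by_day[day] = by_day.get(day, 0) + qty
    covered = 0
    for day, qty in by_day.items():
        d = day
        remaining = qty
        while remaining > 0 and d < window_days:
            covered += 1
            remaining -= 1
            d += 1
    return covered


def oracle_covered_no_carryover(dispensations, window_days=FOLLOWUP_DAYS):
    """Day-by-day walk where a refill resets the stock (same-day refills
    pool); covered days are days with stock on hand."""
    by_day = {}
    for day, qty in dispensations:
        by_day[day] = by_day.get(day, 0) + qty
    stock = 0
    covered = 0
    for d in range(window_days):
        if d in by_day:
            stock = by_day[d]
        if stock > 0:
            covered += 1
            stock -= 1
    return covered


def random_refill_history(rng, max_refills=8):
    """Random refill pattern inside the follow-up year."""
    k = int(rng.integers(1, max_refills + 1))
    days = sorted(int(d) for d in rng.integers(0, FOLLOWUP_DAYS, size=k))
    qtys = [int(q) for q in rng.integers(1, 200, size=k)]
    return list(zip(days, qtys))
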