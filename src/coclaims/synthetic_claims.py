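"""Synthetic generator for the five linked claims tables.

Emulates the statistical structure the continuity-of-care analysis assumes,
not real provincial prevalence or fee schedules.  Each patient carries a
latent "coordinated care" flag ``C``: coordinated patients concentrate their
GP visits on a principal GP, have that GP prescribe their statin, and have
that GP bill a complete medical examination (CME), with per-arm
probabilities.  Optimal adherence is drawn from a logistic model with the
planted log-odds ``beta_c`` on ``C``; dispensation quantities are then
back-solved so the proportion-of-days-covered (PDC) algorithm reproduces the
drawn outcome exactly, under both the accumulating and the no-carryover
variant.  This makes ``exp(beta_c)`` the exact ground-truth odds ratio for
parameter-recovery tests.

One RNG stream per table, seeded from ``params.seed`` via fixed offsets, so
enlarging the patient roster does not reshuffle unrelated tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_model import (
    ClaimsDataset, CodeListConfig, default_codelists, empty_dataset,
    normalize_coverage,
)

DAY = pd.Timedelta(days=1)
FOLLOWUP_DAYS = 365
OPTIMAL_PDC = 0.80

# diagnosis pool: prefixes from the default Charlson/condition maps plus
# neutral filler codes; a random digit is appended at draw time
_DX_PREFIXES = ["410", "428", "250", "496", "582", "401", "786", "729",
                "715", "780", "462", "724"]
_NONSTATIN_DINS = [f"RX{i:02d}" for i in range(1, 30)] + ["DMRX01"]


@dataclass
class SimulationParams:
    """Study conditions for the synthetic cohort.

    Defaults are chosen to resemble the cohort the analysis targets: new
    statin users accrued over 2012-2017, a median of about six GP visits per
    year, roughly a fifth of patients with a hospitalization or an ED visit
    in the prior year, about 28% of patients in the coordinated arm, and an
    unadjusted coordinated-care odds ratio of 1.45 on optimal adherence.
    """

    n_patients: int = 2000
    n_gps: int = 200
    n_specialists: int = 80
    study_window: tuple[str, str] = ("2012-01-01", "2017-12-31")
    coordinated_fraction: float = 0.28
    loyalty_coordinated: float = 0.95
    loyalty_uncoordinated: float = 0.50
    prescriber_match_coordinated: float = 0.90
    prescriber_match_uncoordinated: float = 0.35
    cme_prob_coordinated: float = 0.95
    cme_prob_uncoordinated: float = 0.25
    specialist_cme_prob: float = 0.02
    gp_visit_rate: float = 6.0
    specialist_visit_rate: float = 3.0
    hospital_rate: float = 0.25
    ed_rate: float = 0.25
    baseline_adherence_logit: float = 0.0
    coordinated_log_or: float = math.log(1.45)
    covariate_effects: dict[str, float] = field(default_factory=lambda: {
        "female": -0.10, "age_per_decade": 0.10,
        "prior_hospitalization": -0.20})
    refill_size: int = 90
    seed: int = 0

    def __post_init__(self):
        probs = [self.coordinated_fraction, self.loyalty_coordinated,
                 self.loyalty_uncoordinated, self.prescriber_match_coordinated,
                 self.prescriber_match_uncoordinated,
                 self.cme_prob_coordinated, self.cme_prob_uncoordinated,
                 self.specialist_cme_prob]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        rates = [self.gp_visit_rate, self.specialist_visit_rate,
                 self.hospital_rate, self.ed_rate]
        if any(r < 0 for r in rates):
            raise ValueError("rates must be >= 0")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.refill_size < 1:
            raise ValueError("refill_size must be >= 1")
        if self.n_gps < 2 or self.n_specialists < 1:
            raise ValueError("need >= 2 GPs and >= 1 specialist")


@dataclass
class GroundTruth:
    """Latent per-patient state and the planted effect size."""

    patients: pd.DataFrame  # person_id, coordinated, optimal, index_date
    planted_or: float

    def __post_init__(self):
        if not self.planted_or > 0:
            raise ValueError("planted OR must be > 0")


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2 ** 31), offset])


def _draw_dx(rng: np.random.Generator, n: int) -> list[str]:
    pre = rng.choice(_DX_PREFIXES, size=n)
    suf = rng.integers(0, 10, size=n)
    return [f"{p}{s}" for p, s in zip(pre, suf)]


def _merged_followup_hospital_days(stays: list[tuple[int, int]]) -> int:
    """Days in the union of [admit, discharge) stay intervals, clipped to
    the 365-day follow-up (day offsets relative to index)."""
    covered = np.zeros(FOLLOWUP_DAYS, dtype=bool)
    for a, d in stays:
        covered[max(a, 0):max(min(d, FOLLOWUP_DAYS), 0)] = True
    return int(covered.sum())


def generate(params: SimulationParams) -> tuple[ClaimsDataset, GroundTruth]:
    """Generate the five linked tables plus ground truth.

    Deterministic given ``params.seed``.  Every patient receives their first
    statin dispensation at an index date inside the study window and none
    before it, so the new-user filter passes by construction.
    """
    p = params
    if p.n_patients == 0:
        truth = GroundTruth(
            patients=pd.DataFrame(columns=["person_id", "coordinated",
                                           "optimal", "index_date"]),
            planted_or=math.exp(p.coordinated_log_or))
        return empty_dataset(), truth

    start = pd.Timestamp(p.study_window[0])
    end = pd.Timestamp(p.study_window[1])
    n = p.n_patients
    gp_ids = np.array([f"GP{i:04d}" for i in range(p.n_gps)])
    sp_ids = np.array([f"SP{i:04d}" for i in range(p.n_specialists)])

    rng_person = _rng(p.seed, 1)
    rng_visit = _rng(p.seed, 2)
    rng_disp = _rng(p.seed, 3)
    rng_hosp = _rng(p.seed, 4)
    rng_ed = _rng(p.seed, 5)
    rng_outcome = _rng(p.seed, 6)

    # --- persons -----------------------------------------------------------
    person_id = np.array([f"P{i:06d}" for i in range(n)])
    coordinated = rng_person.random(n) < p.coordinated_fraction
    principal = rng_person.integers(0, p.n_gps, size=n)
    accrual_days = (end - start).days
    index_offset = rng_person.integers(0, accrual_days + 1, size=n)
    index_date = start + pd.to_timedelta(index_offset, unit="D")
    age_at_index = rng_person.integers(30, 86, size=n)
    birth_date = index_date - pd.to_timedelta(
        age_at_index * 365 + rng_person.integers(0, 365, size=n), unit="D")
    female = rng_person.random(n) < 0.44
    rural = rng_person.random(n) < 0.32
    quintile = rng_person.integers(1, 6, size=n).astype(object)
    quintile[rng_person.random(n) < 0.05] = pd.NA

    persons = pd.DataFrame({
        "person_id": person_id,
        "birth_date": birth_date,
        "sex": np.where(female, "F", "M"),
        "residence": np.where(rural, "rural", "urban"),
        "income_quintile": quintile,
        "ltc_admission_dates": [[] for _ in range(n)],
    })
    coverage = pd.DataFrame({
        "person_id": person_id,
        "start": index_date - pd.Timedelta(days=2010),
        "end": index_date + pd.Timedelta(days=400),
    })

    # --- physician service claims ------------------------------------------
    loyalty = np.where(coordinated, p.loyalty_coordinated,
                       p.loyalty_uncoordinated)
    srv_pid, srv_prov, srv_ptype, srv_date, srv_fee = [], [], [], [], []

    def add_claims(pids, provs, ptype, dates, fee):
        size = len(pids)
        srv_pid.append(np.asarray(pids, dtype=object))
        srv_prov.append(np.asarray(provs, dtype=object))
        srv_ptype.append(np.full(size, ptype, dtype=object))
        srv_date.append(np.asarray(dates, dtype="datetime64[ns]"))
        srv_fee.append(np.full(size, fee, dtype=object))

    # GP visit days, prior year and follow-up
    for window_lo, window_hi in ((-365, 0), (0, FOLLOWUP_DAYS)):
        counts = np.maximum(rng_visit.poisson(p.gp_visit_rate, size=n), 1)
        rep = np.repeat(np.arange(n), counts)
        days = rng_visit.integers(window_lo, window_hi, size=rep.size)
        to_principal = rng_visit.random(rep.size) < loyalty[rep]
        other = rng_visit.integers(0, p.n_gps - 1, size=rep.size)
        other = np.where(other >= principal[rep], other + 1, other)
        gp_idx = np.where(to_principal, principal[rep], other)
        dates = (index_date[rep] + pd.to_timedelta(days, unit="D")).values
        add_claims(person_id[rep], gp_ids[gp_idx], "GP", dates, "VISIT")
        # a small fraction of same-day duplicate and invalid claims, to
        # exercise the dedup/validity filters downstream
        dup = rng_visit.random(rep.size) < 0.04
        add_claims(person_id[rep][dup], gp_ids[gp_idx][dup], "GP",
                   dates[dup], "VISIT2")

    # specialist visits over the two-year window
    counts = rng_visit.poisson(p.specialist_visit_rate, size=n)
    rep = np.repeat(np.arange(n), counts)
    days = rng_visit.integers(-365, FOLLOWUP_DAYS, size=rep.size)
    sp_idx = rng_visit.integers(0, p.n_specialists, size=rep.size)
    add_claims(person_id[rep], sp_ids[sp_idx], "specialist",
               (index_date[rep] + pd.to_timedelta(days, unit="D")).values,
               "CONS")

    # complete medical examinations: principal GP with per-arm probability,
    # specialists as rare background
    cme_p = np.where(coordinated, p.cme_prob_coordinated,
                     p.cme_prob_uncoordinated)
    has_cme = rng_visit.random(n) < cme_p
    idx = np.flatnonzero(has_cme)
    days = rng_visit.integers(0, FOLLOWUP_DAYS, size=idx.size)
    add_claims(person_id[idx], gp_ids[principal[idx]], "GP",
               (index_date[idx] + pd.to_timedelta(days, unit="D")).values,
               "CME-A")
    sp_cme = np.flatnonzero(rng_visit.random(n) < p.specialist_cme_prob)
    days = rng_visit.integers(0, FOLLOWUP_DAYS, size=sp_cme.size)
    add_claims(person_id[sp_cme],
               sp_ids[rng_visit.integers(0, p.n_specialists,
                                         size=sp_cme.size)],
               "specialist",
               (index_date[sp_cme] + pd.to_timedelta(days, unit="D")).values,
               "CME-A")

    srv_pid = np.concatenate(srv_pid)
    srv_fee = np.concatenate(srv_fee)
    m = len(srv_pid)
    # 2% invalid-flagged claims; CME claims are kept valid so the latent
    # coordinated flag maps exactly onto the integrated measure under
    # perfect-fidelity arm settings
    validity = rng_visit.random(m) >= 0.02
    validity = validity | np.isin(srv_fee, ["CME-A", "CME-CDM"])
    service_claims = pd.DataFrame({
        "person_id": srv_pid,
        "provider_id": np.concatenate(srv_prov),
        "provider_type": np.concatenate(srv_ptype),
        "service_date": pd.DatetimeIndex(np.concatenate(srv_date)),
        "diagnosis_code": _draw_dx(rng_visit, m),
        "fee_code": srv_fee,
        "setting": "outpatient",
        "valid": validity,
        "in_province": True,
    })

    # --- hospital stays and ED visits --------------------------------------
    h_pid, h_admit, h_disch, h_type, h_dx = [], [], [], [], []
    fu_hospital_days = np.zeros(n, dtype=int)
    prior_hosp = np.zeros(n, dtype=bool)
    counts = rng_hosp.poisson(p.hospital_rate, size=n)
    for i in np.flatnonzero(counts):
        stays = []
        for _ in range(min(int(counts[i]), 3)):
            a = int(rng_hosp.integers(-365, FOLLOWUP_DAYS))
            length = 1 + min(int(rng_hosp.poisson(4)), 13)
            stays.append((a, a + length))
            if a < 0:
                prior_hosp[i] = True
            h_pid.append(person_id[i])
            h_admit.append(index_date[i] + a * DAY)
            h_disch.append(index_date[i] + (a + length) * DAY)
            h_type.append("acute" if rng_hosp.random() < 0.9 else "alternative")
            h_dx.append(_draw_dx(rng_hosp, int(rng_hosp.integers(1, 4))))
        fu_hospital_days[i] = _merged_followup_hospital_days(stays)
    hospital_stays = pd.DataFrame({
        "person_id": h_pid, "admit_date": h_admit, "discharge_date": h_disch,
        "diagnoses": h_dx, "care_type": h_type,
    }) if h_pid else empty_dataset().hospital_stays

    counts = rng_ed.poisson(p.ed_rate, size=n)
    rep = np.repeat(np.arange(n), counts)
    days = rng_ed.integers(-365, FOLLOWUP_DAYS, size=rep.size)
    ed_visits = pd.DataFrame({
        "person_id": person_id[rep],
        "admit_date": index_date[rep] + pd.to_timedelta(days, unit="D"),
        "discharge_date": index_date[rep] + pd.to_timedelta(days + 1,
                                                            unit="D"),
        "main_diagnosis": _draw_dx(rng_ed, rep.size),
    }) if rep.size else empty_dataset().ed_visits

    # --- outcome and statin dispensations -----------------------------------
    lin = (p.baseline_adherence_logit
           + p.coordinated_log_or * coordinated.astype(float))
    eff = p.covariate_effects
    if "female" in eff:
        lin = lin + eff["female"] * female.astype(float)
    if "age_per_decade" in eff:
        lin = lin + eff["age_per_decade"] * (age_at_index - 60) / 10.0
    if "prior_hospitalization" in eff:
        lin = lin + eff["prior_hospitalization"] * prior_hosp.astype(float)
    optimal = rng_outcome.random(n) < 1.0 / (1.0 + np.exp(-lin))

    match_p = np.where(coordinated, p.prescriber_match_coordinated,
                       p.prescriber_match_uncoordinated)
    matched = rng_disp.random(n) < match_p
    alt_is_sp = rng_disp.random(n) < 0.6
    alt_sp = sp_ids[rng_disp.integers(0, p.n_specialists, size=n)]
    alt_gp_i = rng_disp.integers(0, p.n_gps - 1, size=n)
    alt_gp_i = np.where(alt_gp_i >= principal, alt_gp_i + 1, alt_gp_i)
    prescriber = np.where(matched, gp_ids[principal],
                          np.where(alt_is_sp, alt_sp, gp_ids[alt_gp_i]))

    statin_pool = sorted(default_codelists().statin_dins)
    r = p.refill_size
    d_idx, d_din, d_day, d_qty = [], [], [], []
    denom = np.maximum(FOLLOWUP_DAYS - fu_hospital_days, 1)
    gaps = rng_disp.integers(0, 60, size=n)
    jmax = max(r // 6, 1)
    min_gap = max(r - jmax + 1, 1)
    n_jit = min(FOLLOWUP_DAYS, FOLLOWUP_DAYS // min_gap + 2)
    jitter = rng_disp.integers(0, jmax, size=(n, n_jit))
    n_din = max(n_jit, FOLLOWUP_DAYS // r + 2)
    din_idx = rng_disp.integers(0, len(statin_pool), size=(n, n_din))
    for i in range(n):
        if optimal[i]:
            # refills spanning the whole window; early-refill jitter creates
            # carryover and the final refill straddles the window end
            day, k = 0, 0
            days = []
            while day < FOLLOWUP_DAYS:
                days.append(day)
                day += r - int(jitter[i, k])
                k += 1
            qtys = [r] * len(days)
        else:
            target = max(int(math.floor(OPTIMAL_PDC * denom[i])) - 1
                         - int(gaps[i]), 1)
            k, rem = divmod(target, r)
            days = [j * r for j in range(k)]
            qtys = [r] * k
            if rem >= 1:
                days.append(k * r)
                qtys.append(rem)
        for k, (day, q) in enumerate(zip(days, qtys)):
            d_idx.append(i)
            d_din.append(statin_pool[din_idx[i, k % n_din]])
            d_day.append(day)
            d_qty.append(q)

    # non-statin prior-year dispensations for the treatment/cost covariates
    counts = rng_disp.poisson(3.0, size=n)
    rep = np.repeat(np.arange(n), counts)
    days = rng_disp.integers(-365, 0, size=rep.size)
    other = pd.DataFrame({
        "person_id": person_id[rep],
        "prescriber_id": gp_ids[rng_disp.integers(0, p.n_gps,
                                                  size=rep.size)],
        "din": rng_disp.choice(_NONSTATIN_DINS, size=rep.size),
        "dispense_date": index_date[rep] + pd.to_timedelta(days, unit="D"),
        "quantity": rng_disp.integers(10, 101, size=rep.size),
        "total_cost": np.round(rng_disp.lognormal(3.0, 0.8, size=rep.size),
                               2),
        "govt_paid_fraction": np.round(rng_disp.beta(2, 1, size=rep.size),
                                       3),
    })
    d_idx = np.asarray(d_idx, dtype=int)
    statin = pd.DataFrame({
        "person_id": person_id[d_idx],
        "prescriber_id": prescriber[d_idx],
        "din": d_din,
        "dispense_date": index_date[d_idx]
        + pd.to_timedelta(d_day, unit="D"),
        "quantity": d_qty,
        "total_cost": np.round(30.0 + 0.5 * np.asarray(d_qty, float), 2),
        "govt_paid_fraction": np.round(
            rng_disp.beta(2, 1, size=len(d_idx)), 3),
    })
    dispensations = pd.concat([statin, other], ignore_index=True)

    def stable_sort(df, cols):
        return df.sort_values(cols, kind="mergesort").reset_index(drop=True)

    ds = ClaimsDataset(
        persons=persons.reset_index(drop=True),
        service_claims=stable_sort(service_claims,
                                   ["person_id", "service_date",
                                    "provider_id", "fee_code"]),
        dispensations=stable_sort(dispensations,
                                  ["person_id", "dispense_date", "din"]),
        hospital_stays=stable_sort(hospital_stays,
                                   ["person_id", "admit_date"]),
        ed_visits=stable_sort(ed_visits, ["person_id", "admit_date"]),
        coverage=normalize_coverage(coverage),
    )
    ds.validate()
    truth = GroundTruth(
        patients=pd.DataFrame({
            "person_id": person_id, "coordinated": coordinated,
            "optimal": optimal, "index_date": index_date}),
        planted_or=math.exp(p.coordinated_log_or))
    return ds, truth


# ---------------------------------------------------------------------------
# Exclusion-criterion perturbation

EXCLUSION_KINDS = ("missing_demog", "under_18", "coverage_gap", "ltc",
                   "out_province_hospital", "pregnancy", "no_gp_visits")


def perturb_for_exclusions(
        dataset: ClaimsDataset, params: SimulationParams,
        counts: dict[str, int] | None = None,
) -> tuple[ClaimsDataset, dict[str, list[str]]]:
    """Inject patients that each violate exactly one exclusion criterion.

    ``counts`` maps a criterion kind (see :data:`EXCLUSION_KINDS`) to the
    number of violating patients to add; kinds not listed default to 0.
    Returns the augmented dataset and the injected person ids per kind, so a
    cohort flow report can be cross-checked exactly.  Injected patients are
    otherwise clean new users whose earlier criteria all pass, ensuring
    first-failure attribution lands on the intended criterion.
    """
    counts = dict(counts or {})
    unknown = set(counts) - set(EXCLUSION_KINDS)
    if unknown:
        raise ValueError(f"unknown exclusion kinds: {sorted(unknown)}")
    if all(v == 0 for v in counts.values()):
        return dataset, {k: [] for k in EXCLUSION_KINDS}

    rng = _rng(params.seed, 7)
    start = pd.Timestamp(params.study_window[0])
    end = pd.Timestamp(params.study_window[1])
    mid = start + (end - start) / 2
    index_date = pd.Timestamp(mid.date())

    new_persons, new_cov, new_srv, new_disp, new_hosp = [], [], [], [], []
    injected: dict[str, list[str]] = {k: [] for k in EXCLUSION_KINDS}
    serial = 0
    for kind in EXCLUSION_KINDS:
        for _ in range(int(counts.get(kind, 0))):
            pid = f"X{serial:05d}"
            serial += 1
            injected[kind].append(pid)
            birth = index_date - pd.Timedelta(days=50 * 365)
            sex = "F" if rng.random() < 0.5 else "M"
            ltc: list = []
            cov = (index_date - pd.Timedelta(days=2010),
                   index_date + pd.Timedelta(days=400))
            if kind == "missing_demog":
                sex = None
            elif kind == "under_18":
                birth = index_date - pd.Timedelta(days=10 * 365)
            elif kind == "coverage_gap":
                cov = (index_date - pd.Timedelta(days=3 * 365),
                       index_date + pd.Timedelta(days=400))
            elif kind == "ltc":
                ltc = [index_date - pd.Timedelta(days=100)]
            new_persons.append(dict(
                person_id=pid, birth_date=birth, sex=sex, residence="urban",
                income_quintile=3, ltc_admission_dates=ltc))
            new_cov.append(dict(person_id=pid, start=cov[0], end=cov[1]))
            new_disp.append(dict(
                person_id=pid, prescriber_id="GP0000", din="STATIN01",
                dispense_date=index_date, quantity=90, total_cost=75.0,
                govt_paid_fraction=0.5))
            if kind != "no_gp_visits":
                new_srv.append(dict(
                    person_id=pid, provider_id="GP0000", provider_type="GP",
                    service_date=index_date + pd.Timedelta(days=30),
                    diagnosis_code="4011", fee_code="VISIT",
                    setting="outpatient", valid=True, in_province=True))
            if kind == "out_province_hospital":
                new_srv.append(dict(
                    person_id=pid, provider_id="GP9999", provider_type="GP",
                    service_date=index_date + pd.Timedelta(days=60),
                    diagnosis_code="7861", fee_code="VISIT",
                    setting="in_hospital", valid=True, in_province=False))
            if kind == "pregnancy":
                new_hosp.append(dict(
                    person_id=pid,
                    admit_date=index_date + pd.Timedelta(days=90),
                    discharge_date=index_date + pd.Timedelta(days=92),
                    diagnoses=["O211"], care_type="acute"))

    def extend(df, rows):
        if not rows:
            return df
        return pd.concat([df, pd.DataFrame(rows)], ignore_index=True)

    out = ClaimsDataset(
        persons=extend(dataset.persons, new_persons),
        service_claims=extend(dataset.service_claims, new_srv),
        dispensations=extend(dataset.dispensations, new_disp),
        hospital_stays=extend(dataset.hospital_stays, new_hosp),
        ed_visits=dataset.ed_visits.copy(),
        coverage=extend(dataset.coverage, new_cov),
        integrity_flags=dataset.integrity_flags.copy(),
    )
    out.validate()
    return out, injected
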