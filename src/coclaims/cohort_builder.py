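"""New-user cohort construction: index dates, exclusion waterfall, covariates.

A new user is a person whose earliest statin dispensation inside the accrual
window is preceded by a five-year statin-free clean period.  The index date
is that dispensation's date and follow-up is the half-open 365-day window
``[index, index + 365)``.  Seven exclusion criteria are applied in a fixed
order with first-failure attribution, producing a flow-chart style report.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .claims_model import ClaimsDataset, CodeListConfig
from .coc_measures import eligible_gp_visits_table

DAY = pd.Timedelta(days=1)
FOLLOWUP_DAYS = 365
CLEAN_PERIOD_DAYS = 5 * 365

EXCLUSION_ORDER = [
    "missing_demog",        # 1: missing age or sex in the registry
    "under_18",             # 2: age < 18 at index
    "coverage_gap",         # 3: not continuously covered, index-5y .. index+365d
    "ltc",                  # 4: long-term-care admission in the same window
    "out_province_hospital",  # 5: out-of-province hospitalization in follow-up
    "pregnancy",            # 6: pregnancy code within +/- 365 days of index
    "no_gp_visits",         # 7: zero eligible GP visits in follow-up
]

DEFAULT_CONDITION_FLOOR = pd.Timestamp("1996-01-01")


@dataclass
class FlowReport:
    """Waterfall of candidate counts through the exclusion criteria."""

    n_candidates: int
    removed: dict[str, int]
    n_final: int

    def to_frame(self) -> pd.DataFrame:
        rows = [("candidates", self.n_candidates)]
        rows += [(f"excluded_{k}", self.removed[k]) for k in EXCLUSION_ORDER]
        rows.append(("final_cohort", self.n_final))
        return pd.DataFrame(rows, columns=["stage", "n"])


def find_new_users(dataset: ClaimsDataset, config: CodeListConfig,
                   accrual_window: tuple[str, str]) -> pd.DataFrame:
    """Earliest in-window statin dispensation per person, with the five-year
    clean period enforced.

    Returns a frame with columns person_id, index_date, sorted by person_id.
    """
    lo, hi = pd.Timestamp(accrual_window[0]), pd.Timestamp(accrual_window[1])
    if hi < lo:
        raise ValueError("empty accrual window")
    disp = dataset.dispensations
    statin = disp[disp["din"].isin(config.statin_dins)]
    if len(statin) == 0:
        return pd.DataFrame(columns=["person_id", "index_date"])
    in_window = statin[(statin["dispense_date"] >= lo)
                       & (statin["dispense_date"] <= hi)]
    first = (in_window.groupby("person_id", sort=True)["dispense_date"]
             .min().rename("index_date").reset_index())
    # clean period: no statin dispensation in [index - 5y, index)
    merged = statin.merge(first, on="person_id")
    dirty = merged[
        (merged["dispense_date"] < merged["index_date"])
        & (merged["dispense_date"]
           >= merged["index_date"] - CLEAN_PERIOD_DAYS * DAY)]
    clean = first[~first["person_id"].isin(dirty["person_id"])]
    return clean.reset_index(drop=True)


def _prefix_regex(prefixes) -> re.Pattern | None:
    if not prefixes:
        return None
    return re.compile("^(?:" + "|".join(
        re.escape(p) for p in sorted(prefixes)) + ")")


def _pregnancy_persons(cand: pd.DataFrame, dataset: ClaimsDataset,
                       config: CodeListConfig) -> set[str]:
    """Persons with a pregnancy-prefix code within [index-365d, index+365d],
    both endpoints inclusive, in service claims, hospital or ED diagnoses."""
    pat = _prefix_regex(config.pregnancy_prefixes)
    if pat is None:
        return set()
    hits: set[str] = set()
    window = cand[["person_id", "index_date"]]

    def scan(df, date_col, code_values, pid):
        m = pd.DataFrame({"person_id": pid, "date": df[date_col].to_numpy(),
                          "code": code_values}).merge(window, on="person_id")
        m = m[(m["date"] >= m["index_date"] - FOLLOWUP_DAYS * DAY)
              & (m["date"] <= m["index_date"] + FOLLOWUP_DAYS * DAY)]
        codes = m["code"].astype(str)
        return set(m.loc[codes.str.match(pat), "person_id"])

    sc = dataset.service_claims
    if len(sc):
        hits |= scan(sc, "service_date", sc["diagnosis_code"].to_numpy(),
                     sc["person_id"].to_numpy())
    hs = dataset.hospital_stays
    if len(hs):
        ex = hs[["person_id", "admit_date", "diagnoses"]].explode("diagnoses")
        ex = ex.dropna(subset=["diagnoses"])
        if len(ex):
            hits |= scan(ex, "admit_date", ex["diagnoses"].to_numpy(),
                         ex["person_id"].to_numpy())
    ed = dataset.ed_visits
    if len(ed):
        hits |= scan(ed, "admit_date", ed["main_diagnosis"].to_numpy(),
                     ed["person_id"].to_numpy())
    return hits


def _coverage_ok(cand: pd.DataFrame, coverage: pd.DataFrame,
                 grace_days: int) -> pd.Series:
    """Continuous registration over [index-5y, index+365d), gaps of at most
    ``grace_days`` days tolerated between closed coverage intervals."""
    lo = cand["index_date"] - CLEAN_PERIOD_DAYS * DAY
    hi = cand["index_date"] + FOLLOWUP_DAYS * DAY  # exclusive
    ok = pd.Series(False, index=cand.index)
    if len(coverage) == 0:
        return ok
    n_intervals = coverage.groupby("person_id").size()
    # fast path: a single interval must span the whole window
    single_pids = set(n_intervals.index[n_intervals == 1])
    single_mask = cand["person_id"].isin(single_pids)
    if single_mask.any():
        one = coverage[coverage["person_id"].isin(single_pids)].set_index(
            "person_id")
        sub = cand[single_mask]
        s = one["start"].reindex(sub["person_id"]).to_numpy()
        e = one["end"].reindex(sub["person_id"]).to_numpy()
        ok[sub.index] = ((s <= lo[sub.index].to_numpy())
                         & (e >= (hi[sub.index] - DAY).to_numpy()))
    multi = cand[~single_mask & cand["person_id"].isin(n_intervals.index)]
    if len(multi):
        grace = grace_days * DAY
        cov_by = {pid: grp[["start", "end"]].sort_values("start")
                  for pid, grp in coverage[coverage["person_id"].isin(
                      set(multi["person_id"]))].groupby("person_id")}
        for i, pid in zip(multi.index, multi["person_id"]):
            iv = cov_by[pid]
            pos = lo[i]  # first day still needing coverage
            for s, e in zip(iv["start"], iv["end"]):
                if s > pos + grace:
                    break
                if e + DAY > pos:
                    pos = e + DAY
                if pos >= hi[i]:
                    break
            ok[i] = pos >= hi[i]
    return ok


def apply_exclusions(candidates: pd.DataFrame, dataset: ClaimsDataset,
                     config: CodeListConfig, grace_days: int = 0,
                     ) -> tuple[pd.DataFrame, FlowReport]:
    """Apply the seven exclusion criteria in order with first-failure
    attribution.

    Returns (cohort, flow_report): the cohort frame has columns person_id,
    index_date, age_at_index, followup_start, followup_end (half-open);
    excluded candidates are dropped from it but counted per criterion in the
    report.
    """
    cand = candidates.reset_index(drop=True).copy()
    removed = {k: 0 for k in EXCLUSION_ORDER}
    if len(cand) == 0:
        return (pd.DataFrame(columns=["person_id", "index_date",
                                      "age_at_index", "followup_start",
                                      "followup_end"]),
                FlowReport(0, removed, 0))
    cand["followup_start"] = cand["index_date"]
    cand["followup_end"] = cand["index_date"] + FOLLOWUP_DAYS * DAY
    persons = dataset.persons.set_index("person_id")
    cand = cand.join(persons[["birth_date", "sex", "ltc_admission_dates"]],
                     on="person_id")

    fail = pd.DataFrame(index=cand.index)
    # 1: missing age or sex
    fail["missing_demog"] = (cand["birth_date"].isna()
                             | cand["sex"].isna()
                             | ~cand["person_id"].isin(persons.index))
    # 2: age < 18 at index (integer years, floor)
    age = (cand["index_date"] - cand["birth_date"]).dt.days // 365
    fail["under_18"] = age.fillna(0) < 18
    # 3: coverage gap over [index-5y, index+365d)
    fail["coverage_gap"] = ~_coverage_ok(cand, dataset.coverage, grace_days)
    # 4: LTC admission in [index-5y, index+365d)
    lo = cand["index_date"] - CLEAN_PERIOD_DAYS * DAY
    fail["ltc"] = [
        any(l <= d < h for d in (dates if isinstance(dates, list) else []))
        for dates, l, h in zip(cand["ltc_admission_dates"], lo,
                               cand["followup_end"])]
    # 5: out-of-province hospitalization during follow-up (in-hospital
    # service claims from an out-of-province provider)
    sc = dataset.service_claims
    oop = sc[(sc["setting"] == "in_hospital")
             & ~sc["in_province"].astype(bool)]
    if len(oop):
        m = oop.merge(cand[["person_id", "followup_start", "followup_end"]],
                      on="person_id")
        m = m[(m["service_date"] >= m["followup_start"])
              & (m["service_date"] < m["followup_end"])]
        fail["out_province_hospital"] = cand["person_id"].isin(
            set(m["person_id"]))
    else:
        fail["out_province_hospital"] = False
    # 6: pregnancy code within +/- 365 days of index, inclusive
    fail["pregnancy"] = cand["person_id"].isin(
        _pregnancy_persons(cand, dataset, config))
    # 7: zero deduplicated eligible GP visits during follow-up
    visits = eligible_gp_visits_table(dataset.service_claims, cand)
    fail["no_gp_visits"] = ~cand["person_id"].isin(
        set(visits["person_id"]))

    fail = fail[EXCLUSION_ORDER]
    any_fail = fail.any(axis=1)
    first = fail.idxmax(axis=1).where(any_fail)
    removed = {k: int((first == k).sum()) for k in EXCLUSION_ORDER}
    kept = cand[~any_fail]
    cohort = pd.DataFrame({
        "person_id": kept["person_id"].to_numpy(),
        "index_date": kept["index_date"].to_numpy(),
        "age_at_index": age[kept.index].astype(int).to_numpy(),
        "followup_start": kept["followup_start"].to_numpy(),
        "followup_end": kept["followup_end"].to_numpy(),
    })
    report = FlowReport(n_candidates=len(cand), removed=removed,
                        n_final=len(cohort))
    assert sum(removed.values()) + len(cohort) == len(cand)
    return cohort, report


# ---------------------------------------------------------------------------
# Covariates

def _window_merge(df: pd.DataFrame, cohort: pd.DataFrame, date_col: str,
                  lo_offset_days: int, hi_offset_days: int,
                  lo_inclusive: bool = True, hi_inclusive: bool = False
                  ) -> pd.DataFrame:
    """Rows of ``df`` falling in a window around each member's index date."""
    m = df.merge(cohort[["person_id", "index_date"]], on="person_id")
    lo = m["index_date"] + lo_offset_days * DAY
    hi = m["index_date"] + hi_offset_days * DAY
    mask = (m[date_col] >= lo) if lo_inclusive else (m[date_col] > lo)
    mask &= (m[date_col] <= hi) if hi_inclusive else (m[date_col] < hi)
    return m[mask]


def _count_by_person(df: pd.DataFrame, index: pd.Index) -> pd.Series:
    return df.groupby("person_id").size().reindex(index, fill_value=0)


def build_covariates(cohort: pd.DataFrame, dataset: ClaimsDataset,
                     config: CodeListConfig,
                     condition_floor: pd.Timestamp = DEFAULT_CONDITION_FLOOR,
                     ) -> pd.DataFrame:
    """Per-member covariate vector, one row per cohort member.

    Prior-year counts use [index - 365d, index); condition flags look back to
    ``condition_floor`` (inclusive of the index date); the Charlson score sums
    config weights over distinct conditions matched by ICD prefix in
    prior-year service claims and hospital diagnoses; govt_paid_pct is the
    cost-weighted fraction paid by government insurance over prior-year
    dispensations (0 if none).
    """
    persons = dataset.persons.set_index("person_id")
    idx = pd.Index(cohort["person_id"], name="person_id")
    out = pd.DataFrame(index=idx)
    joined = persons.reindex(idx)
    out["age"] = cohort["age_at_index"].to_numpy()
    out["sex"] = joined["sex"].to_numpy()
    out["residence"] = joined["residence"].to_numpy()
    out["income_quintile"] = [
        "missing" if pd.isna(q) else str(int(q))
        for q in joined["income_quintile"]]

    # prior-year visit counts, deduplicated (provider, date)
    sc_prior = _window_merge(dataset.service_claims, cohort, "service_date",
                             -FOLLOWUP_DAYS, 0)
    visits = sc_prior.drop_duplicates(
        ["person_id", "provider_id", "service_date", "provider_type"])
    out["n_gp_visits_prior"] = _count_by_person(
        visits[visits["provider_type"] == "GP"], idx)
    out["n_specialist_visits_prior"] = _count_by_person(
        visits[visits["provider_type"] == "specialist"], idx)

    hosp_prior = _window_merge(dataset.hospital_stays, cohort, "admit_date",
                               -FOLLOWUP_DAYS, 0)
    out["n_hospitalizations_prior"] = _count_by_person(
        hosp_prior[hosp_prior["care_type"] == "acute"], idx)
    ed_prior = _window_merge(dataset.ed_visits, cohort, "admit_date",
                             -FOLLOWUP_DAYS, 0)
    out["n_ed_visits_prior"] = _count_by_person(ed_prior, idx)

    disp_prior = _window_merge(dataset.dispensations, cohort,
                               "dispense_date", -FOLLOWUP_DAYS, 0)
    out["n_distinct_drugs_prior"] = (disp_prior.groupby("person_id")["din"]
                                     .nunique().reindex(idx, fill_value=0))
    paid = disp_prior.assign(
        paid=disp_prior["total_cost"] * disp_prior["govt_paid_fraction"])
    sums = paid.groupby("person_id")[["paid", "total_cost"]].sum()
    pct = (sums["paid"] / sums["total_cost"]).where(sums["total_cost"] > 0,
                                                    0.0)
    out["govt_paid_pct"] = pct.reindex(idx, fill_value=0.0)

    # Charlson: prior-year diagnoses from claims + hospital abstracts
    prior_dx = pd.concat([
        pd.DataFrame({"person_id": sc_prior["person_id"],
                      "code": sc_prior["diagnosis_code"]}),
        (hosp_prior[["person_id", "diagnoses"]].explode("diagnoses")
         .rename(columns={"diagnoses": "code"})),
    ], ignore_index=True).dropna(subset=["code"])
    out["charlson_score"] = _charlson(prior_dx, config, idx)

    # condition flags over [floor_date, index]
    all_dx = pd.concat([
        pd.DataFrame({"person_id": dataset.service_claims["person_id"],
                      "date": dataset.service_claims["service_date"],
                      "code": dataset.service_claims["diagnosis_code"]}),
        (dataset.hospital_stays[["person_id", "admit_date", "diagnoses"]]
         .explode("diagnoses")
         .rename(columns={"admit_date": "date", "diagnoses": "code"})),
    ], ignore_index=True).dropna(subset=["code"])
    all_dx = all_dx.merge(cohort[["person_id", "index_date"]],
                          on="person_id")
    all_dx = all_dx[(all_dx["date"] >= condition_floor)
                    & (all_dx["date"] <= all_dx["index_date"])]
    hist_disp = dataset.dispensations.merge(
        cohort[["person_id", "index_date"]], on="person_id")
    hist_disp = hist_disp[
        (hist_disp["dispense_date"] >= condition_floor)
        & (hist_disp["dispense_date"] <= hist_disp["index_date"])]
    for name in sorted(config.condition_definitions):
        spec = config.condition_definitions[name]
        pat = _prefix_regex(spec.get("icd_prefixes", []))
        flagged: set[str] = set()
        if pat is not None and len(all_dx):
            hit = all_dx["code"].astype(str).str.match(pat)
            flagged |= set(all_dx.loc[hit, "person_id"])
        dins = set(spec.get("dins", []))
        if dins and len(hist_disp):
            flagged |= set(hist_disp.loc[hist_disp["din"].isin(dins),
                                         "person_id"])
        out[f"cond_{name}"] = idx.isin(flagged)
    return out.reset_index()


def _charlson(dx: pd.DataFrame, config: CodeListConfig,
              idx: pd.Index) -> pd.Series:
    """Sum of weights over distinct matched conditions per person."""
    if len(dx) == 0 or not config.charlson_map:
        return pd.Series(0, index=idx)
    codes = dx["code"].astype(str)
    pieces = []
    for prefix, (cond, weight) in config.charlson_map.items():
        hit = codes.str.startswith(prefix)
        if hit.any():
            pieces.append(pd.DataFrame({
                "person_id": dx.loc[hit, "person_id"],
                "cond": cond, "weight": weight}))
    if not pieces:
        return pd.Series(0, index=idx)
    matched = (pd.concat(pieces, ignore_index=True)
               .drop_duplicates(["person_id", "cond"]))
    return (matched.groupby("person_id")["weight"].sum()
            .reindex(idx, fill_value=0).astype(int))
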