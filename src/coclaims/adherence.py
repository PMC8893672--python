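"""Proportion of days covered (PDC) over the 365-day follow-up.

One tablet equals one day of supply (once-daily statin dosing), so days
supplied are read directly from quantities dispensed.  Switching between
statin products is allowed: all statin dispensations count, pooled by date.
Quantities dispensed near the window end are truncated to the days
remaining.  The denominator is 365 minus days spent in hospital (admission
day counted, discharge day not, overlapping stays merged).  Optimal
adherence is PDC >= 80%.

Two variants:

* ``accumulate`` (primary) — tablets stockpile across refills; covered days
  are the truncated tablet total.
* ``no_carryover`` (sensitivity) — each dispensation restarts coverage and
  any remainder of the previous supply is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .claims_model import ClaimsDataset, CodeListConfig

DAY = pd.Timedelta(days=1)
FOLLOWUP_DAYS = 365
OPTIMAL_THRESHOLD = 0.80


@dataclass
class AdherenceResult:
    person_id: str
    covered_days: float
    hospital_days: int
    denominator_days: int
    pdc: float | None
    optimal: bool | None
    method: str
    undefined: bool = False  # denominator < 1: whole year in hospital


def hospital_days(member, stays: pd.DataFrame,
                  include_alternative_care: bool = True) -> int:
    """Days in hospital within the member's follow-up window.

    Overlapping stays are merged; the admission day counts, the discharge day
    does not.  Alternative-care stays are included by default (the patient is
    still not self-administering); set ``include_alternative_care=False`` to
    count acute stays only.
    """
    s = stays[stays["person_id"] == member.person_id]
    if not include_alternative_care:
        s = s[s["care_type"] == "acute"]
    if len(s) == 0:
        return 0
    intervals = sorted(
        (max(a, member.followup_start), min(d, member.followup_end))
        for a, d in zip(s["admit_date"], s["discharge_date"]))
    total = 0
    cur_s = cur_e = None
    for a, d in intervals:
        if d <= a:
            continue
        if cur_s is None:
            cur_s, cur_e = a, d
        elif a <= cur_e:
            cur_e = max(cur_e, d)
        else:
            total += (cur_e - cur_s).days
            cur_s, cur_e = a, d
    if cur_s is not None:
        total += (cur_e - cur_s).days
    return total


def _hospital_days_by_person(cohort: pd.DataFrame, stays: pd.DataFrame,
                             include_alternative_care: bool) -> pd.Series:
    """Vectorized hospital-day counts for every cohort member."""
    out = pd.Series(0, index=cohort["person_id"], dtype=int)
    if len(stays) == 0:
        return out
    s = stays if include_alternative_care else \
        stays[stays["care_type"] == "acute"]
    merged = s.merge(cohort[["person_id", "followup_start", "followup_end"]],
                     on="person_id")
    if len(merged) == 0:
        return out
    a = merged["admit_date"].where(
        merged["admit_date"] > merged["followup_start"],
        merged["followup_start"])
    d = merged["discharge_date"].where(
        merged["discharge_date"] < merged["followup_end"],
        merged["followup_end"])
    clipped = pd.DataFrame({"person_id": merged["person_id"],
                            "a": a, "d": d})
    clipped = clipped[clipped["d"] > clipped["a"]]
    for pid, grp in clipped.sort_values(["person_id", "a"]).groupby(
            "person_id", sort=False):
        total, cur_s, cur_e = 0, None, None
        for aa, dd in zip(grp["a"], grp["d"]):
            if cur_s is None:
                cur_s, cur_e = aa, dd
            elif aa <= cur_e:
                cur_e = max(cur_e, dd)
            else:
                total += (cur_e - cur_s).days
                cur_s, cur_e = aa, dd
        total += (cur_e - cur_s).days
        out.loc[pid] = total
    return out


def _covered_days(dispensations: pd.DataFrame, cohort: pd.DataFrame,
                  config: CodeListConfig, method: str) -> pd.Series:
    """Covered days per cohort member under the chosen variant."""
    d = dispensations
    win = d[d["din"].isin(config.statin_dins)].merge(
        cohort[["person_id", "followup_start", "followup_end"]],
        on="person_id")
    win = win[(win["dispense_date"] >= win["followup_start"])
              & (win["dispense_date"] < win["followup_end"])]
    # switching allowed: pool tablets across products dispensed the same day
    pooled = (win.groupby(["person_id", "dispense_date"], as_index=False)
              .agg(quantity=("quantity", "sum"),
                   followup_start=("followup_start", "first"),
                   followup_end=("followup_end", "first"))
              .sort_values(["person_id", "dispense_date"]))
    covered = pd.Series(0.0, index=cohort["person_id"])
    if len(pooled) == 0:
        return covered
    qty = pooled["quantity"].to_numpy(float)
    if method == "accumulate":
        remaining = (pooled["followup_end"]
                     - pooled["dispense_date"]).dt.days.to_numpy(float)
        per_claim = np.minimum(qty, remaining)
    else:  # no_carryover: the next refill truncates the open interval
        supply_end = pooled["dispense_date"] + pd.to_timedelta(
            pooled["quantity"], unit="D")
        next_date = pooled.groupby("person_id")["dispense_date"].shift(-1)
        end = supply_end.where(
            next_date.isna() | (supply_end < next_date), next_date)
        end = end.where(end < pooled["followup_end"], pooled["followup_end"])
        start = pooled["dispense_date"].where(
            pooled["dispense_date"] > pooled["followup_start"],
            pooled["followup_start"])
        per_claim = np.maximum((end - start).dt.days.to_numpy(float), 0.0)
    sums = pd.Series(per_claim).groupby(
        pooled["person_id"].to_numpy()).sum()
    covered.loc[sums.index] = sums
    return covered


def compute_adherence(dataset: ClaimsDataset, cohort: pd.DataFrame,
                      config: CodeListConfig, method: str = "accumulate",
                      include_alternative_care: bool = True,
                      cap_pdc: bool = True) -> pd.DataFrame:
    """Adherence results for every cohort member, as a tidy frame.

    Members whose denominator falls below one day (the whole year in
    hospital) get pdc/optimal as NA with undefined=True; the pipeline drops
    them from models with a logged count.
    """
    if method not in ("accumulate", "no_carryover"):
        raise ValueError(f"unknown PDC method {method!r}")
    hosp = _hospital_days_by_person(cohort, dataset.hospital_stays,
                                    include_alternative_care)
    covered = _covered_days(dataset.dispensations, cohort, config, method)
    out = pd.DataFrame({
        "person_id": cohort["person_id"].to_numpy(),
        "covered_days": covered.to_numpy(float),
        "hospital_days": hosp.to_numpy(int),
    })
    out["denominator_days"] = FOLLOWUP_DAYS - out["hospital_days"]
    out["undefined"] = out["denominator_days"] < 1
    pdc = out["covered_days"] / out["denominator_days"].where(
        ~out["undefined"])
    if cap_pdc:
        pdc = pdc.clip(upper=1.0)
    out["pdc"] = pdc
    out["optimal"] = (pdc >= OPTIMAL_THRESHOLD).where(~out["undefined"])
    out["method"] = method
    return out


def _single_member_result(member, dispensations, hosp, config, method,
                          cap_pdc) -> AdherenceResult:
    cohort = pd.DataFrame([{
        "person_id": member.person_id,
        "followup_start": member.followup_start,
        "followup_end": member.followup_end}])
    covered = float(_covered_days(dispensations, cohort, config,
                                  method).iloc[0])
    denominator = FOLLOWUP_DAYS - hosp
    if denominator < 1:
        return AdherenceResult(member.person_id, covered, hosp, denominator,
                               None, None, method, undefined=True)
    pdc = covered / denominator
    if cap_pdc:
        pdc = min(1.0, pdc)
    return AdherenceResult(member.person_id, covered, hosp, denominator,
                           pdc, pdc >= OPTIMAL_THRESHOLD, method)


def pdc_accumulate(member, dispensations: pd.DataFrame, hosp: int,
                   config: CodeListConfig, cap_pdc: bool = True
                   ) -> AdherenceResult:
    """Primary PDC: truncated tablet total over the hospital-adjusted year.

    covered = sum over statin dispensations in follow-up of min(quantity,
    days from the dispensation to the window end); pdc = min(1, covered /
    (365 - hospital days)).
    """
    return _single_member_result(member, dispensations, hosp, config,
                                 "accumulate", cap_pdc)


def pdc_no_carryover(member, dispensations: pd.DataFrame, hosp: int,
                     config: CodeListConfig, cap_pdc: bool = True
                     ) -> AdherenceResult:
    """Sensitivity PDC: a refill restarts coverage, discarding any remainder
    of the previous supply (no stockpiling).

    Each dispensation opens [date, date + quantity); the next dispensation
    truncates the open interval at its own date; the union is intersected
    with the follow-up window.
    """
    return _single_member_result(member, dispensations, hosp, config,
                                 "no_carryover", cap_pdc)
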