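"""Continuity-of-care measures from physician claims.

Implements, per patient over the 365-day follow-up:

* the usual care provider — the GP (or tied GPs) with the most deduplicated
  eligible visits;
* the usual provider continuity index, UPCI = n_max / N, where n_max is the
  visit count of the most-visited GP and N the total GP visit count;
* the high/low UPCI split at a cohort percentile (median by default);
* the usual statin prescriber(s) (USP) — physician(s) of any specialty on
  the most statin dispensation claims;
* the complete-medical-examination provider set (CMEP) — physicians of any
  specialty with at least one CME fee-code claim;
* the integrated continuity flag — true when a single GP is simultaneously
  a usual care provider, a USP, and a CMEP.

Visit eligibility: claims in the follow-up window, by a GP, marked valid,
delivered outpatient, from an in-province provider; multiple claims by the
same GP on the same date count as one visit.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .claims_model import ClaimsDataset, CodeListConfig


@dataclass
class ThresholdSpec:
    """Cohort percentile defining the high/low UPCI split."""

    percentile: int = 50

    def __post_init__(self):
        if self.percentile not in (25, 50, 75):
            raise ValueError("percentile must be one of {25, 50, 75}")


def eligible_gp_visits_table(service_claims: pd.DataFrame,
                             cohort: pd.DataFrame) -> pd.DataFrame:
    """Deduplicated eligible GP visits for every cohort member.

    ``cohort`` needs columns person_id, followup_start, followup_end
    (half-open window).  Returns columns person_id, provider_id, visit_date.
    """
    sc = service_claims
    elig = sc[(sc["provider_type"] == "GP")
              & sc["valid"].astype(bool)
              & (sc["setting"] == "outpatient")
              & sc["in_province"].astype(bool)]
    merged = elig.merge(
        cohort[["person_id", "followup_start", "followup_end"]],
        on="person_id", how="inner")
    merged = merged[(merged["service_date"] >= merged["followup_start"])
                    & (merged["service_date"] < merged["followup_end"])]
    visits = (merged[["person_id", "provider_id", "service_date"]]
              .drop_duplicates()
              .rename(columns={"service_date": "visit_date"}))
    return visits.reset_index(drop=True)


def eligible_gp_visits(member, service_claims: pd.DataFrame
                       ) -> list[tuple[str, pd.Timestamp]]:
    """Single-member convenience wrapper around the table version."""
    cohort = pd.DataFrame([{
        "person_id": member.person_id,
        "followup_start": member.followup_start,
        "followup_end": member.followup_end}])
    visits = eligible_gp_visits_table(service_claims, cohort)
    return list(zip(visits["provider_id"], visits["visit_date"]))


def usual_care_provider(visits) -> tuple[set[str], int, int]:
    """(argmax provider set, n_max, N) from (provider, date) visit pairs.

    Ties produce multi-member sets.  An empty visit list is a contract
    violation: the no-GP-visit exclusion should have removed the member.
    """
    visits = list(visits)
    if not visits:
        raise ValueError("no eligible GP visits; member should have been "
                         "excluded under the no-GP-visit criterion")
    counts: dict[str, int] = {}
    for provider, _date in visits:
        counts[provider] = counts.get(provider, 0) + 1
    n = len(visits)
    n_max = max(counts.values())
    ucp = {p for p, c in counts.items() if c == n_max}
    return ucp, n_max, n


def upci(n_max: int, n: int) -> float:
    """Usual provider continuity index n_max / N."""
    if n < 1:
        raise ValueError("N must be >= 1")
    if not 1 <= n_max <= n:
        raise ValueError("need 1 <= n_max <= N")
    return n_max / n


def upci_fraction(n_max: int, n: int) -> Fraction:
    """Exact rational UPCI, for drift-free bookkeeping."""
    if not 1 <= n_max <= n:
        raise ValueError("need 1 <= n_max <= N")
    return Fraction(n_max, n)


def categorize_upci(profiles: pd.DataFrame, spec: ThresholdSpec | None = None
                    ) -> tuple[pd.DataFrame, float]:
    """Set ``upci_high`` (UPCI >= cohort percentile) on a profile frame.

    The threshold is the linear-interpolation (type-7) percentile of the
    analyzed cohort's UPCI values; the realized value is returned so the
    cutoff is reproducible.
    """
    spec = spec or ThresholdSpec()
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    threshold = float(np.percentile(profiles["upci"].to_numpy(float),
                                    spec.percentile, method="linear"))
    out = profiles.copy()
    out["upci_high"] = out["upci"] >= threshold
    return out, threshold


def usual_statin_prescriber(member, dispensations: pd.DataFrame,
                            config: CodeListConfig) -> set[str]:
    """Prescriber(s), any specialty, on the most statin claims in follow-up."""
    d = dispensations
    win = d[(d["person_id"] == member.person_id)
            & d["din"].isin(config.statin_dins)
            & (d["dispense_date"] >= member.followup_start)
            & (d["dispense_date"] < member.followup_end)]
    if len(win) == 0:
        return set()
    counts = win.groupby("prescriber_id").size()
    return set(counts.index[counts == counts.max()])


def cme_providers(member, service_claims: pd.DataFrame,
                  config: CodeListConfig) -> set[str]:
    """Physicians, any specialty, with >= 1 CME fee-code claim in follow-up.

    Only valid in-province claims count; may be empty.
    """
    sc = service_claims
    win = sc[(sc["person_id"] == member.person_id)
             & sc["fee_code"].isin(config.cme_fee_codes)
             & sc["valid"].astype(bool)
             & sc["in_province"].astype(bool)
             & (sc["service_date"] >= member.followup_start)
             & (sc["service_date"] < member.followup_end)]
    return set(win["provider_id"])


def integrated_coc(usual_care: set[str], usp: set[str], cmep: set[str],
                   gp_providers: set[str]) -> bool:
    """True iff some GP is simultaneously in all three provider sets."""
    return bool(usual_care & usp & cmep & gp_providers)


def compute_profiles(dataset: ClaimsDataset, cohort: pd.DataFrame,
                     config: CodeListConfig,
                     spec: ThresholdSpec | None = None
                     ) -> tuple[pd.DataFrame, float]:
    """Per-member continuity profile for the whole cohort.

    Returns (profiles, realized_threshold).  Columns: person_id, n_max, N,
    upci, upci_high, n_ucp_ties, usual_care_providers, usual_statin_prescribers,
    cme_providers (as sorted tuples), integrated_coc.
    """
    visits = eligible_gp_visits_table(dataset.service_claims, cohort)
    visit_counts = (visits.groupby(["person_id", "provider_id"])
                    .size().rename("n").reset_index())

    # GP identity at the claim level: a provider is a GP for the integrated
    # flag if any of their claims carries provider_type == GP
    sc = dataset.service_claims
    gp_providers = set(sc.loc[sc["provider_type"] == "GP", "provider_id"])

    d = dataset.dispensations
    statin = d[d["din"].isin(config.statin_dins)].merge(
        cohort[["person_id", "followup_start", "followup_end"]],
        on="person_id")
    statin = statin[(statin["dispense_date"] >= statin["followup_start"])
                    & (statin["dispense_date"] < statin["followup_end"])]
    statin_counts = (statin.groupby(["person_id", "prescriber_id"])
                     .size().rename("n").reset_index())

    cme = sc[sc["fee_code"].isin(config.cme_fee_codes)
             & sc["valid"].astype(bool)
             & sc["in_province"].astype(bool)].merge(
        cohort[["person_id", "followup_start", "followup_end"]],
        on="person_id")
    cme = cme[(cme["service_date"] >= cme["followup_start"])
              & (cme["service_date"] < cme["followup_end"])]
    cme_sets = cme.groupby("person_id")["provider_id"].agg(
        lambda s: tuple(sorted(set(s))))

    grp = visit_counts.groupby("person_id")["n"]
    totals = grp.sum()
    maxima = grp.max()
    missing = set(cohort["person_id"]) - set(totals.index)
    if missing:
        raise ValueError(
            f"cohort members with no eligible GP visits: "
            f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}")
    is_max = visit_counts["n"].to_numpy() == maxima.reindex(
        visit_counts["person_id"]).to_numpy()
    ucp_sets = (visit_counts[is_max].groupby("person_id")["provider_id"]
                .agg(lambda s: tuple(sorted(s))))
    s_max = statin_counts.groupby("person_id")["n"].max()
    s_is_max = statin_counts["n"].to_numpy() == s_max.reindex(
        statin_counts["person_id"]).to_numpy()
    usp_sets = (statin_counts[s_is_max].groupby("person_id")["prescriber_id"]
                .agg(lambda s: tuple(sorted(s))))

    pid_index = pd.Index(cohort["person_id"])

    def reindex_sets(series: pd.Series) -> list[tuple]:
        return [v if isinstance(v, tuple) else ()
                for v in series.reindex(pid_index).to_numpy(object)]

    profiles = pd.DataFrame({
        "person_id": cohort["person_id"].to_numpy(),
        "n_max": maxima.reindex(pid_index).to_numpy(int),
        "N": totals.reindex(pid_index).to_numpy(int),
        "usual_care_providers": reindex_sets(ucp_sets),
        "usual_statin_prescribers": reindex_sets(usp_sets),
        "cme_providers": reindex_sets(cme_sets),
    })
    profiles["upci"] = profiles["n_max"] / profiles["N"]
    profiles["n_ucp_ties"] = profiles["usual_care_providers"].map(len)
    profiles["integrated_coc"] = [
        integrated_coc(set(u), set(s), set(c), gp_providers)
        for u, s, c in zip(profiles["usual_care_providers"],
                           profiles["usual_statin_prescribers"],
                           profiles["cme_providers"])]
    profiles, threshold = categorize_upci(profiles, spec)
    return profiles, threshold
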