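"""End-to-end orchestration: primary models, subgroups, sensitivity, reports.

``run_primary`` walks a linked claims dataset through cohort construction,
continuity measurement, adherence scoring, diagnostic accuracy of the
UPCI split against the prescriber/examination references, and the paired
logistic models with a DeLong AUROC comparison.  Reports are emitted as
tidy frames with small-cell suppression (groups under six are masked, with
secondary suppression so masked cells cannot be back-calculated from
margins).

The printed counts of the published Saskatchewan cohort are embedded as
inputs for desk-scale recomputation of the report-level quantities (the two
unadjusted odds ratios and the headline percentages); the confidential
cohort itself is not reproducible and all model-level behaviour is verified
on synthetic data instead.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .claims_model import ClaimsDataset, CodeListConfig
from .cohort_builder import (apply_exclusions, build_covariates,
                             find_new_users, FlowReport)
from .coc_measures import ThresholdSpec, compute_profiles, categorize_upci
from .adherence import compute_adherence
from . import stats as st

SUPPRESSED = "suppressed"


@dataclass
class AnalysisPlan:
    accrual_window: tuple[str, str] = ("2012-01-01", "2017-12-31")
    threshold_percentile: int = 50
    pdc_method: str = "accumulate"
    suppression_min: int = 6
    grace_days: int = 0
    fit_adjusted: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.suppression_min < 1:
            raise ValueError("suppression_min must be >= 1")
        if self.threshold_percentile not in (25, 50, 75):
            raise ValueError("threshold_percentile must be 25, 50 or 75")
        if self.pdc_method not in ("accumulate", "no_carryover"):
            raise ValueError("pdc_method must be accumulate or no_carryover")


# ---------------------------------------------------------------------------
# Published-cohort printed counts (report-layer inputs)

PUBLISHED_COUNTS = {
    "cohort_n": 55144,
    # adherent / total by exposure group
    "upci_2x2": dict(exposed_events=15606, exposed_total=27859,
                     unexposed_events=13604, unexposed_total=27285),
    "integrated_2x2": dict(exposed_events=9277, exposed_total=15579,
                           unexposed_events=19933, unexposed_total=39565),
    "single_ucp_n": 51071,
    "tied_ucp_n": 4073,
    "integrated_n": 15579,
    "gp_cme_n": 22017,
}


def percent(numerator: float, denominator: float) -> float:
    """Report-layer percentage convention: one decimal place."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, 1)


def compute_published_estimates() -> dict:
    """Recompute the report-level quantities from the embedded printed counts."""
    c = PUBLISHED_COUNTS
    or_upci = st.odds_ratio_2x2(**c["upci_2x2"])
    or_int = st.odds_ratio_2x2(**c["integrated_2x2"])
    n = c["cohort_n"]
    return {
        "or_upci_unadjusted": or_upci,
        "or_integrated_unadjusted": or_int,
        "pct_optimal_integrated": percent(
            c["integrated_2x2"]["exposed_events"],
            c["integrated_2x2"]["exposed_total"]),
        "pct_optimal_high_upci": percent(
            c["upci_2x2"]["exposed_events"], c["upci_2x2"]["exposed_total"]),
        "pct_integrated": percent(c["integrated_n"], n),
        "pct_gp_cme": percent(c["gp_cme_n"], n),
        "pct_single_ucp": percent(c["single_ucp_n"], n),
        "pct_tied_ucp": percent(c["tied_ucp_n"], n),
    }


# ---------------------------------------------------------------------------
# Design matrix for the adjusted models

NUMERIC_COVARIATES = [
    "age", "n_gp_visits_prior", "n_specialist_visits_prior",
    "n_hospitalizations_prior", "n_ed_visits_prior",
    "n_distinct_drugs_prior", "govt_paid_pct", "charlson_score",
]
INCOME_LEVELS = ["1", "2", "3", "4", "5", "missing"]


def build_design(analysis: pd.DataFrame, exposure: str) -> pd.DataFrame:
    """Numeric design matrix: exposure first, then covariates (categoricals
    one-hot with a reference level; the income 'missing' level is retained)."""
    cols = {exposure: analysis[exposure].astype(int)}
    for c in NUMERIC_COVARIATES:
        cols[c] = analysis[c].astype(float)
    cols["sex_F"] = (analysis["sex"] == "F").astype(int)
    cols["residence_rural"] = (analysis["residence"] == "rural").astype(int)
    for level in INCOME_LEVELS[1:]:  # quintile 1 is the reference
        cols[f"income_{level}"] = (
            analysis["income_quintile"].astype(str) == level).astype(int)
    for c in sorted(col for col in analysis.columns
                    if col.startswith("cond_")):
        cols[c] = analysis[c].astype(int)
    design = pd.DataFrame(cols, index=analysis.index)
    # degenerate columns cannot enter a logistic fit
    keep = [c for c in design.columns
            if c == exposure or design[c].nunique() > 1]
    return design[keep]


def _adjusted_fit(analysis: pd.DataFrame, exposure: str,
                  vif_threshold: float = 2.5) -> st.ModelFit:
    design = build_design(analysis, exposure)
    kept, dropped = st.vif_screen(design, exposure, vif_threshold)
    return st.fit_logistic(analysis["optimal"].astype(int),
                           design[kept], exposure, dropped=dropped)


# ---------------------------------------------------------------------------
# Report tables

def baseline_table(analysis: pd.DataFrame) -> pd.DataFrame:
    """Tidy long-format baseline description, stratified by the two
    continuity exposures (plus the full cohort)."""
    strata = [("all", analysis),
              ("upci_high", analysis[analysis["upci_high"]]),
              ("upci_low", analysis[~analysis["upci_high"]]),
              ("integrated_yes", analysis[analysis["integrated_coc"]]),
              ("integrated_no", analysis[~analysis["integrated_coc"]])]
    rows = []

    def add(stratum, characteristic, category, count=None, pct=None,
            median=None, q1=None, q3=None):
        rows.append(dict(stratum=stratum, characteristic=characteristic,
                         category=category, count=count, pct=pct,
                         median=median, q1=q1, q3=q3))

    for name, df in strata:
        n = len(df)
        add(name, "n", "", count=n)
        if n == 0:
            continue
        q = df["age"].quantile([0.25, 0.5, 0.75])
        add(name, "age", "", median=q[0.5], q1=q[0.25], q3=q[0.75])
        add(name, "sex", "F", count=int((df["sex"] == "F").sum()),
            pct=percent((df["sex"] == "F").sum(), n))
        add(name, "hospitalized_prior", ">=1",
            count=int((df["n_hospitalizations_prior"] >= 1).sum()),
            pct=percent((df["n_hospitalizations_prior"] >= 1).sum(), n))
        q = df["n_gp_visits_prior"].quantile([0.25, 0.5, 0.75])
        add(name, "gp_visits_prior", "", median=q[0.5], q1=q[0.25],
            q3=q[0.75])
        q = df["n_specialist_visits_prior"].quantile([0.25, 0.5, 0.75])
        add(name, "specialist_visits_prior", "", median=q[0.5], q1=q[0.25],
            q3=q[0.75])
        add(name, "ed_prior", ">=1",
            count=int((df["n_ed_visits_prior"] >= 1).sum()),
            pct=percent((df["n_ed_visits_prior"] >= 1).sum(), n))
        for level in INCOME_LEVELS:
            k = int((df["income_quintile"].astype(str) == level).sum())
            add(name, "income_quintile", level, count=k, pct=percent(k, n))
        for level in ("rural", "urban"):
            k = int((df["residence"] == level).sum())
            add(name, "residence", level, count=k, pct=percent(k, n))
    return pd.DataFrame(rows)


def suppress(report: pd.DataFrame, min_cell: int,
             count_col: str = "count", pct_col: str | None = "pct",
             group_cols: tuple[str, ...] = ("stratum", "characteristic"),
             ) -> pd.DataFrame:
    """Mask counts below ``min_cell`` (and their percentages).

    Secondary suppression: within a group of cells sharing ``group_cols``
    whose counts add to a disclosed margin, a single masked cell could be
    back-calculated, so the smallest remaining cell is masked too.
    """
    out = report.copy()
    out[count_col] = out[count_col].astype(object)
    if pct_col and pct_col in out.columns:
        out[pct_col] = out[pct_col].astype(object)
    primary = out[count_col].map(
        lambda v: v is not None and not pd.isna(v) and v < min_cell)
    masked = primary.copy()
    group_key = [c for c in group_cols if c in out.columns]
    if group_key:
        for _, idx in out.groupby(group_key).groups.items():
            idx = list(idx)
            counted = [i for i in idx
                       if out.at[i, count_col] is not None
                       and not pd.isna(out.at[i, count_col])]
            if len(counted) < 2:
                continue
            hit = [i for i in counted if masked[i]]
            if len(hit) == 1:
                rest = [i for i in counted if not masked[i]]
                if rest:
                    second = min(rest, key=lambda i: out.at[i, count_col])
                    masked[second] = True
    for i in out.index[masked]:
        out.at[i, count_col] = SUPPRESSED
        if pct_col and pct_col in out.columns:
            out.at[i, pct_col] = SUPPRESSED
    return out


# ---------------------------------------------------------------------------
# Primary analysis

@dataclass
class PrimaryResult:
    cohort: pd.DataFrame
    flow: FlowReport
    analysis: pd.DataFrame  # one row per modelled member
    upci_threshold: float
    n_undefined_pdc: int
    table1: pd.DataFrame
    table2: pd.DataFrame
    or_upci_unadjusted: st.EffectEstimate
    or_integrated_unadjusted: st.EffectEstimate
    fit_upci: st.ModelFit | None
    fit_integrated: st.ModelFit | None
    delong: st.DeLongResult | None
    unadjusted_counts: dict


def _accuracy_row(name: str, cm: st.ConfusionMatrix) -> dict:
    rep = st.accuracy(cm)
    row = {"reference": name, "tp": cm.tp, "fp": cm.fp, "fn": cm.fn,
           "tn": cm.tn}
    for metric in ("sensitivity", "specificity", "ppv", "npv", "kappa"):
        m = getattr(rep, metric)
        row[metric] = m.estimate
        row[f"{metric}_lo"] = m.ci_low
        row[f"{metric}_hi"] = m.ci_high
    return row


def assemble_analysis(dataset: ClaimsDataset, config: CodeListConfig,
                      plan: AnalysisPlan):
    """Cohort -> covariates -> continuity profiles -> adherence, merged into
    one analysis frame (undefined-PDC members dropped with a count)."""
    candidates = find_new_users(dataset, config, plan.accrual_window)
    cohort, flow = apply_exclusions(candidates, dataset, config,
                                    grace_days=plan.grace_days)
    covariates = build_covariates(cohort, dataset, config)
    profiles, threshold = compute_profiles(
        dataset, cohort, config, ThresholdSpec(plan.threshold_percentile))
    adherence = compute_adherence(dataset, cohort, config,
                                  method=plan.pdc_method)
    n_undefined = int(adherence["undefined"].sum())
    analysis = (cohort.merge(covariates, on="person_id")
                .merge(profiles, on="person_id")
                .merge(adherence[~adherence["undefined"]]
                       [["person_id", "pdc", "optimal", "covered_days",
                         "denominator_days"]], on="person_id"))
    analysis["optimal"] = analysis["optimal"].astype(bool)
    return analysis, cohort, flow, threshold, n_undefined


def run_primary(dataset: ClaimsDataset, config: CodeListConfig,
                plan: AnalysisPlan | None = None) -> PrimaryResult:
    plan = plan or AnalysisPlan()
    analysis, cohort, flow, threshold, n_undef = assemble_analysis(
        dataset, config, plan)
    if len(analysis) == 0:
        raise ValueError("empty analysis cohort")

    # Table 2: is a usual-care provider also the USP / a CMEP / all three
    ucp = analysis["usual_care_providers"].map(set)
    usp_ref = [bool(u & set(s)) for u, s in
               zip(ucp, analysis["usual_statin_prescribers"])]
    cme_ref = [bool(u & set(s)) for u, s in
               zip(ucp, analysis["cme_providers"])]
    idx = analysis["upci_high"].to_numpy(bool)
    table2 = pd.DataFrame([
        _accuracy_row("usp", st.confusion(idx, usp_ref)),
        _accuracy_row("cmep", st.confusion(idx, cme_ref)),
        _accuracy_row("integrated",
                      st.confusion(idx, analysis["integrated_coc"])),
    ])

    counts = {}
    effects = {}
    for exposure in ("upci_high", "integrated_coc"):
        e = analysis[exposure].to_numpy(bool)
        o = analysis["optimal"].to_numpy(bool)
        counts[exposure] = dict(
            exposed_events=int((e & o).sum()), exposed_total=int(e.sum()),
            unexposed_events=int((~e & o).sum()),
            unexposed_total=int((~e).sum()))
        effects[exposure] = st.odds_ratio_2x2(**counts[exposure])

    fit_upci = fit_int = delong = None
    if plan.fit_adjusted:
        fit_upci = _adjusted_fit(analysis, "upci_high")
        fit_int = _adjusted_fit(analysis, "integrated_coc")
        delong = st.delong_compare(fit_upci.probs, fit_int.probs,
                                   analysis["optimal"].to_numpy(bool))

    return PrimaryResult(
        cohort=cohort, flow=flow, analysis=analysis,
        upci_threshold=threshold, n_undefined_pdc=n_undef,
        table1=baseline_table(analysis), table2=table2,
        or_upci_unadjusted=effects["upci_high"],
        or_integrated_unadjusted=effects["integrated_coc"],
        fit_upci=fit_upci, fit_integrated=fit_int, delong=delong,
        unadjusted_counts=counts)


# ---------------------------------------------------------------------------
# Subgroups and sensitivity

def _stratum_fit(analysis: pd.DataFrame, mask, exposure: str,
                 min_cell: int) -> dict:
    sub = analysis[mask]
    row: dict = {"exposure": exposure, "n": len(sub)}
    if len(sub) < min_cell or sub[exposure].nunique() < 2 \
            or sub["optimal"].nunique() < 2:
        row["status"] = SUPPRESSED if len(sub) < min_cell else "degenerate"
        return row
    fit = _adjusted_fit(sub, exposure)
    row.update(status="ok", or_point=fit.effect.or_point,
               ci_low=fit.effect.ci_low, ci_high=fit.effect.ci_high)
    return row


def run_subgroups(primary: PrimaryResult, plan: AnalysisPlan | None = None
                  ) -> pd.DataFrame:
    """Adjusted ORs within continuity strata.

    Integrated-care effect within the high- and low-UPCI strata; UPCI effect
    within the integrated and non-integrated strata; and the cross-category
    contrast (integrated-with-low-UPCI vs not-integrated-with-high-UPCI).
    """
    plan = plan or AnalysisPlan()
    a = primary.analysis
    rows = []
    for stratum, mask, exposure in [
            ("upci_high", a["upci_high"], "integrated_coc"),
            ("upci_low", ~a["upci_high"], "integrated_coc"),
            ("integrated_yes", a["integrated_coc"], "upci_high"),
            ("integrated_no", ~a["integrated_coc"], "upci_high")]:
        row = _stratum_fit(a, mask, exposure, plan.suppression_min)
        row["stratum"] = stratum
        rows.append(row)
    # cross-category contrast
    cross = a[(a["integrated_coc"] & ~a["upci_high"])
              | (~a["integrated_coc"] & a["upci_high"])].copy()
    cross["integrated_low_upci"] = (cross["integrated_coc"]
                                    & ~cross["upci_high"])
    row = _stratum_fit(cross, np.ones(len(cross), bool),
                       "integrated_low_upci", plan.suppression_min)
    row["stratum"] = "cross_category"
    rows.append(row)
    return pd.DataFrame(rows)


def run_sensitivity(dataset: ClaimsDataset, config: CodeListConfig,
                    plan: AnalysisPlan | None = None,
                    primary: PrimaryResult | None = None) -> pd.DataFrame:
    """Primary models re-run with (a) the no-carryover PDC variant and
    (b) the UPCI split at the 25th and 75th percentiles."""
    plan = plan or AnalysisPlan()
    if primary is None:
        primary = run_primary(dataset, config, plan)
    rows = [_sensitivity_row("primary", primary)]

    alt_plan = AnalysisPlan(**{**asdict(plan), "pdc_method": "no_carryover"})
    rows.append(_sensitivity_row("no_carryover",
                                 run_primary(dataset, config, alt_plan)))

    for pct in (25, 75):
        a = primary.analysis.copy()
        profiles, threshold = categorize_upci(a, ThresholdSpec(pct))
        a["upci_high"] = profiles["upci_high"]
        e = a["upci_high"].to_numpy(bool)
        o = a["optimal"].to_numpy(bool)
        unadj = st.odds_ratio_2x2(
            int((e & o).sum()), int(e.sum()),
            int((~e & o).sum()), int((~e).sum()))
        row = dict(variant=f"threshold_p{pct}", upci_threshold=threshold,
                   n_high_upci=int(e.sum()), n=len(a),
                   or_upci_unadjusted=unadj.or_point,
                   or_integrated_unadjusted=(
                       primary.or_integrated_unadjusted.or_point))
        if plan.fit_adjusted:
            fit_u = _adjusted_fit(a, "upci_high")
            dl = st.delong_compare(fit_u.probs,
                                   primary.fit_integrated.probs, o)
            row.update(or_upci_adjusted=fit_u.effect.or_point,
                       or_upci_ci_low=fit_u.effect.ci_low,
                       or_upci_ci_high=fit_u.effect.ci_high,
                       delong_delta=dl.delta, delong_chi2=dl.chi2,
                       delong_p=dl.p_value)
        rows.append(row)
    return pd.DataFrame(rows)


def _sensitivity_row(name: str, result: PrimaryResult) -> dict:
    row = dict(variant=name, upci_threshold=result.upci_threshold,
               n=len(result.analysis),
               n_high_upci=int(result.analysis["upci_high"].sum()),
               or_upci_unadjusted=result.or_upci_unadjusted.or_point,
               or_integrated_unadjusted=(
                   result.or_integrated_unadjusted.or_point))
    if result.fit_upci is not None:
        row.update(
            or_upci_adjusted=result.fit_upci.effect.or_point,
            or_integrated_adjusted=result.fit_integrated.effect.or_point,
            delong_delta=result.delong.delta,
            delong_chi2=result.delong.chi2, delong_p=result.delong.p_value)
    return row


# ---------------------------------------------------------------------------
# Report bundle

def _effect_row(label: str, eff: st.EffectEstimate) -> dict:
    return dict(term=label, estimate=eff.or_point, ci_low=eff.ci_low,
                ci_high=eff.ci_high, scale=eff.scale)


def write_bundle(result: PrimaryResult, config: CodeListConfig,
                 plan: AnalysisPlan, out_dir: str | Path,
                 subgroups: pd.DataFrame | None = None,
                 sensitivity: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write the tidy report bundle; byte-identical for identical inputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def emit(name: str, df: pd.DataFrame):
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path

    emit("flow", result.flow.to_frame())
    emit("cohort", result.cohort.assign(
        index_date=result.cohort["index_date"].dt.strftime("%Y-%m-%d"))
        [["person_id", "index_date", "age_at_index"]])
    coc_cols = ["person_id", "n_max", "N", "upci", "upci_high", "n_ucp_ties",
                "integrated_coc"]
    emit("coc", result.analysis[coc_cols])
    emit("adherence", result.analysis[
        ["person_id", "covered_days", "denominator_days", "pdc", "optimal"]])
    emit("table1", suppress(result.table1, plan.suppression_min))
    emit("table2", result.table2)
    table3 = [_effect_row("upci_high_unadjusted", result.or_upci_unadjusted),
              _effect_row("integrated_coc_unadjusted",
                          result.or_integrated_unadjusted)]
    if result.fit_upci is not None:
        table3.append(_effect_row("upci_high_adjusted",
                                  result.fit_upci.effect))
        table3.append(_effect_row("integrated_coc_adjusted",
                                  result.fit_integrated.effect))
    emit("table3", pd.DataFrame(table3))
    if result.delong is not None:
        emit("delong", pd.DataFrame([vars(result.delong)]))
    if subgroups is not None:
        emit("subgroups", suppress(subgroups, plan.suppression_min,
                                   count_col="n", pct_col=None,
                                   group_cols=()))
    if sensitivity is not None:
        emit("sensitivity", sensitivity)

    plan_dict = asdict(plan)
    config_digest = hashlib.sha256(json.dumps(
        dict(statin_dins=sorted(config.statin_dins),
             cme_fee_codes=sorted(config.cme_fee_codes),
             pregnancy_prefixes=sorted(config.pregnancy_prefixes)),
        sort_keys=True).encode()).hexdigest()[:16]
    meta = dict(plan=plan_dict, config_sha256=config_digest,
                upci_threshold=result.upci_threshold,
                n_cohort=len(result.cohort),
                n_analyzed=len(result.analysis),
                n_undefined_pdc=result.n_undefined_pdc,
                dropped_covariates={
                    "upci_high": result.fit_upci.dropped_covariates
                    if result.fit_upci else None,
                    "integrated_coc":
                        result.fit_integrated.dropped_covariates
                        if result.fit_integrated else None})
    path = out_dir / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    paths["run_metadata"] = path
    return paths
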