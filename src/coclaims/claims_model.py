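"""Domain model for the five linked administrative claims tables.

The analysis consumes five tables mirroring a provincial claims extract:
a person registry, physician service claims, prescription dispensations,
hospital discharge abstracts, and emergency-department visits.  Tables are
held as pandas DataFrames inside a :class:`ClaimsDataset`; CSV is the
interchange dialect (RFC 4180, UTF-8, header row, ISO-8601 dates, missing
values as empty fields).  Validation never silently drops rows: claims that
reference a person absent from the registry are flagged in an integrity
report and retained.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# Schemas

SEX_LEVELS = ("F", "M")
RESIDENCE_LEVELS = ("rural", "urban")
PROVIDER_TYPES = ("GP", "specialist")
SETTINGS = ("outpatient", "in_hospital")
CARE_TYPES = ("acute", "alternative")

PERSON_COLUMNS = [
    "person_id", "birth_date", "sex", "residence", "income_quintile",
    "ltc_admission_dates",
]
SERVICE_COLUMNS = [
    "person_id", "provider_id", "provider_type", "service_date",
    "diagnosis_code", "fee_code", "setting", "valid", "in_province",
]
DISPENSATION_COLUMNS = [
    "person_id", "prescriber_id", "din", "dispense_date", "quantity",
    "total_cost", "govt_paid_fraction",
]
HOSPITAL_COLUMNS = [
    "person_id", "admit_date", "discharge_date", "diagnoses", "care_type",
]
ED_COLUMNS = ["person_id", "admit_date", "discharge_date", "main_diagnosis"]
COVERAGE_COLUMNS = ["person_id", "start", "end"]

TABLE_FILES = {
    "persons": "persons.csv",
    "service_claims": "service_claims.csv",
    "dispensations": "dispensations.csv",
    "hospital_stays": "hospital_stays.csv",
    "ed_visits": "ed_visits.csv",
    "coverage": "coverage.csv",
}

MAX_HOSPITAL_DIAGNOSES = 25


class ClaimsParseError(ValueError):
    """A malformed value in an input table, located by file, row and column."""

    def __init__(self, file: str, row: int, column: str, message: str):
        self.file, self.row, self.column = file, row, column
        super().__init__(f"{file}, row {row}, column {column!r}: {message}")


class SchemaError(ValueError):
    """Header row does not match the expected schema."""


@dataclass
class CodeListConfig:
    """Configurable code lists driving drug, fee-code and diagnosis lookups.

    ``condition_definitions`` maps a condition name to a dict with keys
    ``icd_prefixes`` (list of ICD prefixes), ``dins`` (drug identification
    numbers) and ``lookback`` (``"floor"`` for all history back to the floor
    date, or an integer number of days).  ``charlson_map`` maps an ICD prefix
    to ``[condition, weight]`` for the comorbidity score.
    """

    statin_dins: set[str]
    cme_fee_codes: set[str]
    pregnancy_prefixes: set[str] = field(default_factory=set)
    condition_definitions: dict[str, dict] = field(default_factory=dict)
    charlson_map: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.statin_dins:
            raise ValueError("statin_dins must be non-empty")
        if not self.cme_fee_codes:
            raise ValueError("cme_fee_codes must be non-empty")
        for prefix, (cond, weight) in self.charlson_map.items():
            if not (isinstance(weight, (int, np.integer)) and weight > 0):
                raise ValueError(
                    f"Charlson weight for {prefix!r} ({cond}) must be a "
                    f"positive integer, got {weight!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeListConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            statin_dins=set(raw["statin_dins"]),
            cme_fee_codes=set(raw["cme_fee_codes"]),
            pregnancy_prefixes=set(raw.get("pregnancy_prefixes", [])),
            condition_definitions=raw.get("condition_definitions", {}),
            charlson_map={k: (v[0], int(v[1]))
                          for k, v in raw.get("charlson_map", {}).items()},
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "statin_dins": sorted(self.statin_dins),
            "cme_fee_codes": sorted(self.cme_fee_codes),
            "pregnancy_prefixes": sorted(self.pregnancy_prefixes),
            "condition_definitions": self.condition_definitions,
            "charlson_map": {k: [v[0], int(v[1])]
                             for k, v in self.charlson_map.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class ClaimsDataset:
    """The five linked tables plus the flattened coverage-interval table.

    ``integrity_flags`` lists claims whose person_id is absent from the
    registry (table, row index, person_id); such rows are flagged, never
    dropped.
    """

    persons: pd.DataFrame
    service_claims: pd.DataFrame
    dispensations: pd.DataFrame
    hospital_stays: pd.DataFrame
    ed_visits: pd.DataFrame
    coverage: pd.DataFrame
    integrity_flags: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["table", "row", "person_id"]))

    def counts(self) -> tuple[int, int, int, int, int]:
        return (len(self.persons), len(self.service_claims),
                len(self.dispensations), len(self.hospital_stays),
                len(self.ed_visits))

    def validate(self) -> None:
        """Raise on any invariant violation (dates, enums, ranges)."""
        p = self.persons
        if p["person_id"].duplicated().any():
            raise ValueError("duplicate person_id in registry")
        bad_q = p["income_quintile"].dropna()
        if len(bad_q) and not bad_q.isin([1, 2, 3, 4, 5]).all():
            raise ValueError("income_quintile outside {1..5, missing}")
        d = self.dispensations
        if len(d):
            if (d["quantity"] < 1).any():
                raise ValueError("dispensation quantity < 1")
            f = d["govt_paid_fraction"]
            if ((f < 0) | (f > 1)).any():
                raise ValueError("govt_paid_fraction outside [0,1]")
        h = self.hospital_stays
        if len(h):
            if (h["discharge_date"] < h["admit_date"]).any():
                raise ValueError("hospital discharge before admission")
            too_many = h["diagnoses"].map(
                lambda ds: len(ds) > MAX_HOSPITAL_DIAGNOSES)
            if too_many.any():
                raise ValueError(
                    f"more than {MAX_HOSPITAL_DIAGNOSES} hospital diagnoses")
        e = self.ed_visits
        if len(e) and (e["discharge_date"] < e["admit_date"]).any():
            raise ValueError("ED discharge before admission")
        c = self.coverage
        if len(c) and (c["end"] < c["start"]).any():
            raise ValueError("coverage interval end before start")
        s = self.service_claims
        if len(s) and (s["fee_code"].astype(str).str.len() == 0).any():
            raise ValueError("empty fee_code in service claims")


def empty_dataset() -> ClaimsDataset:
    return ClaimsDataset(
        persons=_empty(PERSON_COLUMNS, _person_parsers()),
        service_claims=_empty(SERVICE_COLUMNS, _service_parsers()),
        dispensations=_empty(DISPENSATION_COLUMNS, _dispensation_parsers()),
        hospital_stays=_empty(HOSPITAL_COLUMNS, _hospital_parsers()),
        ed_visits=_empty(ED_COLUMNS, _ed_parsers()),
        coverage=_empty(COVERAGE_COLUMNS, _coverage_parsers()),
    )


# ---------------------------------------------------------------------------
# Column parsers: CSV string -> typed value, and typed value -> CSV string.
# Each parser raises ValueError with a bare message; the reader wraps it with
# file/row/column coordinates.

def _parse_date(s: str):
    try:
        return pd.Timestamp(np.datetime64(s, "D"))
    except Exception:
        raise ValueError(f"not an ISO-8601 date: {s!r}")


def _parse_opt_date(s: str):
    return pd.NaT if s == "" else _parse_date(s)


def _parse_enum(levels, optional=False):
    def parse(s: str):
        if s == "":
            if optional:
                return None
            raise ValueError("missing value in required enum field")
        if s not in levels:
            raise ValueError(f"expected one of {levels}, got {s!r}")
        return s
    return parse


def _parse_bool(s: str):
    if s in ("true", "True", "1"):
        return True
    if s in ("false", "False", "0"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _parse_opt_int(s: str):
    if s == "":
        return pd.NA
    return int(s)


def _parse_date_list(s: str):
    return [] if s == "" else [_parse_date(x) for x in s.split(";")]


def _parse_str_list(s: str):
    return [] if s == "" else s.split(";")


def _parse_opt_str(s: str):
    return None if s == "" else s


def _req_str(s: str):
    if s == "":
        raise ValueError("required field is empty")
    return s


def _person_parsers():
    return {
        "person_id": _req_str,
        "birth_date": _parse_opt_date,
        "sex": _parse_enum(SEX_LEVELS, optional=True),
        "residence": _parse_enum(RESIDENCE_LEVELS),
        "income_quintile": _parse_opt_int,
        "ltc_admission_dates": _parse_date_list,
    }


def _service_parsers():
    return {
        "person_id": _req_str,
        "provider_id": _req_str,
        "provider_type": _parse_enum(PROVIDER_TYPES),
        "service_date": _parse_date,
        "diagnosis_code": _parse_opt_str,
        "fee_code": _req_str,
        "setting": _parse_enum(SETTINGS),
        "valid": _parse_bool,
        "in_province": _parse_bool,
    }


def _dispensation_parsers():
    return {
        "person_id": _req_str,
        "prescriber_id": _req_str,
        "din": _req_str,
        "dispense_date": _parse_date,
        "quantity": int,
        "total_cost": float,
        "govt_paid_fraction": float,
    }


def _hospital_parsers():
    return {
        "person_id": _req_str,
        "admit_date": _parse_date,
        "discharge_date": _parse_date,
        "diagnoses": _parse_str_list,
        "care_type": _parse_enum(CARE_TYPES),
    }


def _ed_parsers():
    return {
        "person_id": _req_str,
        "admit_date": _parse_date,
        "discharge_date": _parse_date,
        "main_diagnosis": _parse_opt_str,
    }


def _coverage_parsers():
    return {"person_id": _req_str, "start": _parse_date, "end": _parse_date}


_DATE_COLS = {
    "birth_date", "service_date", "dispense_date", "admit_date",
    "discharge_date", "start", "end",
}


def _empty(columns, parsers):
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in columns})
    for c in columns:
        if c in _DATE_COLS:
            df[c] = pd.Series(dtype="datetime64[ns]")
    return df


def _serialize_value(col: str, v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA \
            or v is pd.NaT:
        return ""
    if isinstance(v, (pd.Timestamp, np.datetime64)):
        return pd.Timestamp(v).strftime("%Y-%m-%d")
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    if isinstance(v, list):
        return ";".join(_serialize_value(col, x) for x in v)
    if col == "total_cost":
        return f"{float(v):.2f}"
    if col == "govt_paid_fraction":
        return repr(float(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return str(v)


def _read_table(path: Path, columns, parsers) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != columns:
        raise SchemaError(
            f"{path.name}: expected columns {columns}, got {list(raw.columns)}")
    out = {}
    for col in columns:
        parse = parsers[col]
        values = []
        for i, s in enumerate(raw[col]):
            try:
                values.append(parse(s))
            except ValueError as exc:
                # CSV data rows start at line 2 (after the header)
                raise ClaimsParseError(path.name, i + 2, col, str(exc))
        out[col] = values
    df = pd.DataFrame(out, columns=columns)
    if len(df) == 0:
        return _empty(columns, parsers)
    for c in columns:
        if c in _DATE_COLS:
            df[c] = pd.to_datetime(df[c])
    return df


def _write_table(df: pd.DataFrame, path: Path, columns) -> None:
    out = pd.DataFrame(
        {c: [_serialize_value(c, v) for v in df[c]] for c in columns},
        columns=columns)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Dataset-level IO

def normalize_coverage(coverage: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent closed coverage intervals per person."""
    if len(coverage) == 0:
        return coverage
    counts = coverage["person_id"].value_counts()
    if (counts == 1).all():
        return (coverage.sort_values(["person_id", "start"])
                .reset_index(drop=True))
    single = coverage[coverage["person_id"].isin(
        counts.index[counts == 1])]
    multi = coverage[coverage["person_id"].isin(counts.index[counts > 1])]
    rows = []
    for pid, grp in multi.sort_values(["person_id", "start"]).groupby(
            "person_id", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + pd.Timedelta(days=1):
                cur_e = max(cur_e, e)
            else:
                rows.append((pid, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((pid, cur_s, cur_e))
    merged = pd.DataFrame(rows, columns=COVERAGE_COLUMNS)
    return (pd.concat([single, merged], ignore_index=True)
            .sort_values(["person_id", "start"]).reset_index(drop=True))


def read_dataset(data_dir: str | Path,
                 config: CodeListConfig | None = None) -> ClaimsDataset:
    """Read the five linked tables (plus coverage.csv) from ``data_dir``.

    Claims referencing a person_id absent from the registry are recorded in
    ``integrity_flags`` and kept.  Raises :class:`ClaimsParseError` naming
    file, row and column on any malformed value.
    """
    data_dir = Path(data_dir)
    tables = {
        "persons": _read_table(data_dir / TABLE_FILES["persons"],
                               PERSON_COLUMNS, _person_parsers()),
        "service_claims": _read_table(data_dir / TABLE_FILES["service_claims"],
                                      SERVICE_COLUMNS, _service_parsers()),
        "dispensations": _read_table(data_dir / TABLE_FILES["dispensations"],
                                     DISPENSATION_COLUMNS,
                                     _dispensation_parsers()),
        "hospital_stays": _read_table(data_dir / TABLE_FILES["hospital_stays"],
                                      HOSPITAL_COLUMNS, _hospital_parsers()),
        "ed_visits": _read_table(data_dir / TABLE_FILES["ed_visits"],
                                 ED_COLUMNS, _ed_parsers()),
        "coverage": _read_table(data_dir / TABLE_FILES["coverage"],
                                COVERAGE_COLUMNS, _coverage_parsers()),
    }
    known = set(tables["persons"]["person_id"])
    flags = []
    for name in ("service_claims", "dispensations", "hospital_stays",
                 "ed_visits", "coverage"):
        df = tables[name]
        orphan = ~df["person_id"].isin(known)
        for row, pid in zip(df.index[orphan], df.loc[orphan, "person_id"]):
            flags.append((name, int(row), pid))
    ds = ClaimsDataset(
        **tables,
        integrity_flags=pd.DataFrame(flags,
                                     columns=["table", "row", "person_id"]),
    )
    ds.validate()
    return ds


def write_dataset(dataset: ClaimsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write all six CSVs; ``read_dataset(write_dataset(d)) == d`` field-for-field."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset.validate()
    spec = {
        "persons": (dataset.persons, PERSON_COLUMNS),
        "service_claims": (dataset.service_claims, SERVICE_COLUMNS),
        "dispensations": (dataset.dispensations, DISPENSATION_COLUMNS),
        "hospital_stays": (dataset.hospital_stays, HOSPITAL_COLUMNS),
        "ed_visits": (dataset.ed_visits, ED_COLUMNS),
        "coverage": (dataset.coverage, COVERAGE_COLUMNS),
    }
    paths = {}
    for name, (df, cols) in spec.items():
        path = out_dir / TABLE_FILES[name]
        _write_table(df, path, cols)
        paths[name] = path
    return paths


def datasets_equal(a: ClaimsDataset, b: ClaimsDataset) -> bool:
    """Field-for-field equality of the six tables (ignoring row index labels)."""
    for name in ("persons", "service_claims", "dispensations",
                 "hospital_stays", "ed_visits", "coverage"):
        da = getattr(a, name).reset_index(drop=True)
        db = getattr(b, name).reset_index(drop=True)
        if da.shape != db.shape or list(da.columns) != list(db.columns):
            return False
        for col in da.columns:
            va, vb = da[col], db[col]
            for x, y in zip(va, vb):
                if isinstance(x, list) or isinstance(y, list):
                    if list(x) != list(y):
                        return False
                elif pd.isna(x) and pd.isna(y):
                    continue
                elif x != y:
                    return False
    return True


# ---------------------------------------------------------------------------
# Default code lists used by the synthetic generator (synthetic identifiers,
# not real DINs or fee schedules)

def default_codelists() -> CodeListConfig:
    return CodeListConfig(
        statin_dins={f"STATIN{i:02d}" for i in range(1, 8)},
        cme_fee_codes={"CME-A", "CME-CDM"},
        pregnancy_prefixes={"641", "V27", "O1", "O21", "O98", "O99", "Z37"},
        condition_definitions={
            "hypertension": {"icd_prefixes": ["401", "I10"],
                             "dins": [], "lookback": "floor"},
            "diabetes": {"icd_prefixes": ["250", "E11"],
                         "dins": ["DMRX01"], "lookback": "floor"},
            "copd": {"icd_prefixes": ["496", "J44"],
                     "dins": [], "lookback": "floor"},
        },
        charlson_map={
            "410": ("myocardial_infarction", 1),
            "I21": ("myocardial_infarction", 1),
            "428": ("heart_failure", 1),
            "I50": ("heart_failure", 1),
            "250": ("diabetes", 1),
            "E11": ("diabetes", 1),
            "496": ("copd", 1),
            "J44": ("copd", 1),
            "582": ("renal_disease", 2),
            "N18": ("renal_disease", 2),
            "196": ("metastatic_cancer", 6),
            "C78": ("metastatic_cancer", 6),
        },
    )
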