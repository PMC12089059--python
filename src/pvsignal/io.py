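"""Parsing and curation of FAERS-style spontaneous report extracts.

A quarterly extract is three "$"-delimited ASCII tables:

* DEMO — one row per report version: case id, version, event date, sex,
  age (value + unit), weight, reporting country, reporter qualification;
* DRUG — one row per drug mention: case id, sequence, verbatim drug name,
  role code (PS primary suspect / SS secondary suspect / C concomitant /
  I interacting);
* REAC — one row per reported event preferred term.

Curation proceeds: parse -> deduplicate -> normalize drug names ->
build the analysis cohort (reporter and drug-role filters).  Every stage
records its report count so the attrition of the cohort is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ._util import drug_name_stem, normalize_term, normalize_text

#: reporter qualification codes (FAERS occp_cod convention)
REPORTER_CODES = {"MD", "PH", "OT", "RN", "CN", "LW"}
#: the healthcare-professional subset: physician, pharmacist,
#: other-health-professional, registered nurse
HCP_CODES = {"MD", "PH", "OT", "RN"}

ROLE_CODES = {"PS", "SS", "C", "I"}

#: age-unit -> years conversion; units outside this map leave age unknown
AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

DEMO_COLUMNS = [
    "case_id",
    "version_id",
    "event_date",
    "sex",
    "age_value",
    "age_unit",
    "weight_kg",
    "country",
    "reporter_qualification",
]
DRUG_COLUMNS = ["case_id", "drug_seq", "verbatim_drug_name", "role_code"]
REAC_COLUMNS = ["case_id", "preferred_term"]


@dataclass
class RawTables:
    """The three parsed tables of one quarter plus a parse/curation report."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    report: dict = field(default_factory=dict)


@dataclass
class DrugSynonymTable:
    """Variant -> canonical drug-name map, matched exactly after normalization.

    Matching is case-insensitive after whitespace/punctuation collapsing; a
    variant that fails to match as a whole is retried on its name stem (the
    tokens before the first dose-like token), still an exact lookup — no
    fuzzy matching.
    """

    mapping: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs) -> "DrugSynonymTable":
        mapping: dict[str, str] = {}
        for variant, canonical in pairs:
            key = normalize_text(variant)
            canon = normalize_text(canonical)
            if key in mapping and mapping[key] != canon:
                raise ValueError(
                    f"conflicting synonym rows: {variant!r} -> {mapping[key]!r} and {canon!r}"
                )
            mapping[key] = canon
        return cls(mapping)

    @classmethod
    def from_tsv(cls, path) -> "DrugSynonymTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"synonym table {path} needs (variant, canonical) columns")
        return cls.from_pairs(df.iloc[:, :2].itertuples(index=False))

    def lookup(self, verbatim: str) -> Optional[str]:
        norm = normalize_text(verbatim)
        hit = self.mapping.get(norm)
        if hit is None:
            stem = drug_name_stem(norm)
            if stem and stem != norm:
                hit = self.mapping.get(stem)
        return hit


def amlodipine_synonyms() -> DrugSynonymTable:
    """Built-in variant list for the drug of interest (amlodipine).

    Covers the besylate salt, common brand names and combination-free
    spellings; dihydropyridine relatives (nimodipine, nifedipine, ...) are
    deliberately absent so they never canonicalize to amlodipine.
    """
    variants = [
        "AMLODIPINE",
        "AMLODIPINE BESYLATE",
        "AMLODIPINE BESILATE",
        "AMLODIPINE MALEATE",
        "AMLODIPINO",
        "NORVASC",
        "ISTIN",
        "AMLODIS",
        "AMLOR",
        "KATERZIA",
        "NORLIQVA",
    ]
    return DrugSynonymTable.from_pairs((v, "amlodipine") for v in variants)


def _read_table(path, columns, delimiter="$") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, engine="python")
    if df.empty and df.shape[1] <= 1:
        raise ValueError(f"{path}: empty file")
    for col in columns:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    return df[columns].copy()


def parse_quarter(demo_path, drug_path, reac_path, delimiter: str = "$") -> RawTables:
    """Parse one quarter's DEMO/DRUG/REAC files.

    Unparseable numeric fields become unknown (NaN) and are counted in the
    parse report; rows are never dropped silently.
    """
    demo = _read_table(demo_path, DEMO_COLUMNS, delimiter)
    drug = _read_table(drug_path, DRUG_COLUMNS, delimiter)
    reac = _read_table(reac_path, REAC_COLUMNS, delimiter)

    failures: dict[str, int] = {}

    def _num(s: pd.Series, col: str) -> pd.Series:
        out = pd.to_numeric(s.replace("", np.nan), errors="coerce")
        failures[col] = int((s.str.strip() != "").sum() - out.notna().sum())
        return out

    demo["version_id"] = _num(demo["version_id"], "version_id").fillna(0).astype(int)
    demo["age_value"] = _num(demo["age_value"], "age_value")
    demo["weight_kg"] = _num(demo["weight_kg"], "weight_kg")
    demo["age_unit"] = demo["age_unit"].str.strip().str.upper()
    demo["sex"] = demo["sex"].str.strip().str.upper()
    demo["reporter_qualification"] = demo["reporter_qualification"].str.strip().str.upper()
    drug["role_code"] = drug["role_code"].str.strip().str.upper()
    failures["role_code"] = int((~drug["role_code"].isin(ROLE_CODES)).sum())
    drug["drug_seq"] = _num(drug["drug_seq"], "drug_seq").fillna(0).astype(int)

    report = {
        "rows": {"demo": len(demo), "drug": len(drug), "reac": len(reac)},
        "coercion_failures": failures,
    }
    return RawTables(demo=demo, drug=drug, reac=reac, report=report)


def write_quarter(raw: RawTables, outdir, delimiter: str = "$") -> None:
    """Serialize RawTables back to the "$"-delimited ASCII dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    demo = raw.demo.copy()
    for col in ("age_value", "weight_kg"):
        demo[col] = demo[col].map(lambda v: "" if pd.isna(v) else f"{v:g}")
    demo.to_csv(outdir / "DEMO.txt", sep=delimiter, index=False)
    raw.drug.to_csv(outdir / "DRUG.txt", sep=delimiter, index=False)
    raw.reac.to_csv(outdir / "REAC.txt", sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# deduplication


def _ps_substance(raw: RawTables) -> pd.Series:
    """Primary-suspect substance per case: canonical name if normalized,
    else the normalized verbatim of the first PS drug row."""
    ps = raw.drug[raw.drug["role_code"] == "PS"].sort_values(["case_id", "drug_seq"])
    ps = ps.drop_duplicates("case_id", keep="first")
    if "canonical_name" in ps.columns:
        name = ps["canonical_name"].where(
            ps["canonical_name"].notna() & (ps["canonical_name"] != ""),
            ps["verbatim_drug_name"].map(normalize_text),
        )
    else:
        name = ps["verbatim_drug_name"].map(normalize_text)
    return pd.Series(name.to_numpy(), index=ps["case_id"].to_numpy())


def deduplicate(raw: RawTables) -> RawTables:
    """Two-stage deduplication.

    1. Within a case id, only the highest version survives.
    2. Across case ids, reports identical on the key tuple (sorted event-term
       set, event date, sex, age, weight, country, primary-suspect substance)
       collapse to one; the lexicographically smallest case id is kept.
    """
    demo = raw.demo.sort_values(["case_id", "version_id"]).drop_duplicates(
        "case_id", keep="last"
    )

    terms = raw.reac.assign(t=raw.reac["preferred_term"].map(normalize_term))
    term_key = terms.groupby("case_id")["t"].apply(lambda s: "|".join(sorted(set(s))))
    subst = _ps_substance(raw)

    key = pd.DataFrame(index=demo["case_id"])
    key["events"] = term_key.reindex(key.index).fillna("")
    key["substance"] = subst.reindex(key.index).fillna("")
    for col in ("event_date", "sex", "country"):
        key[col] = demo.set_index("case_id")[col].fillna("")
    for col in ("age_value", "weight_kg"):
        key[col] = demo.set_index("case_id")[col].map(lambda v: "" if pd.isna(v) else f"{v:g}")
    key["age_unit"] = demo.set_index("case_id")["age_unit"].fillna("")

    keep = (
        key.reset_index()
        .sort_values("case_id")
        .drop_duplicates(subset=[c for c in key.columns], keep="first")["case_id"]
    )
    keep_set = set(keep)

    demo2 = demo[demo["case_id"].isin(keep_set)].reset_index(drop=True)
    drug2 = raw.drug[raw.drug["case_id"].isin(keep_set)].reset_index(drop=True)
    reac2 = raw.reac[raw.reac["case_id"].isin(keep_set)].reset_index(drop=True)
    report = dict(raw.report)
    report["dedup"] = {
        "cases_in": int(raw.demo["case_id"].nunique()),
        "cases_out": len(demo2),
    }
    return RawTables(demo=demo2, drug=drug2, reac=reac2, report=report)


def normalize_drug_names(raw: RawTables, synonyms: DrugSynonymTable) -> RawTables:
    """Attach a canonical_name column to the drug table (None if unmatched)."""
    drug = raw.drug.copy()
    drug["canonical_name"] = drug["verbatim_drug_name"].map(
        lambda v: synonyms.lookup(v) or np.nan
    )
    report = dict(raw.report)
    report["drug_name_normalization"] = {
        "rows": len(drug),
        "matched": int(drug["canonical_name"].notna().sum()),
    }
    return RawTables(demo=raw.demo, drug=drug, reac=raw.reac, report=report)


# ---------------------------------------------------------------------------
# cohort construction


@dataclass
class AnalysisCohort:
    """A curated analysis cohort.

    ``reports`` is indexed by case id with columns sex ({female, male,
    unknown}), age_years (NaN = unknown), weight_kg, country, reporter,
    exposed (bool: primary-suspect = drug of interest), primary_suspect.
    ``events`` is long-format (case_id, term) with normalized terms.
    """

    reports: pd.DataFrame
    events: pd.DataFrame
    drug_of_interest: str
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reports)

    @property
    def n_exposed(self) -> int:
        return int(self.reports["exposed"].sum())


_SEX_MAP = {"F": "female", "M": "male"}


def harmonize_age_years(age_value: pd.Series, age_unit: pd.Series) -> pd.Series:
    factor = age_unit.map(AGE_UNIT_TO_YEARS)
    yrs = age_value * factor
    return yrs.where(yrs.notna() & (yrs < 150))


def filter_hcp(raw: RawTables) -> RawTables:
    """Keep only reports submitted by healthcare professionals."""
    demo = raw.demo[raw.demo["reporter_qualification"].isin(HCP_CODES)].reset_index(drop=True)
    ids = set(demo["case_id"])
    report = dict(raw.report)
    report["hcp_filter"] = {"cases_in": len(raw.demo), "cases_out": len(demo)}
    return RawTables(
        demo=demo,
        drug=raw.drug[raw.drug["case_id"].isin(ids)].reset_index(drop=True),
        reac=raw.reac[raw.reac["case_id"].isin(ids)].reset_index(drop=True),
        report=report,
    )


def build_cohort(
    raw: RawTables,
    drug: str,
    hcp_only: bool = True,
    ps_only: bool = True,
) -> AnalysisCohort:
    """Apply the inclusion filters and assemble the analysis cohort.

    The cohort keeps BOTH exposed and non-exposed reports: the non-exposed
    reports are the comparator background of every 2x2 table.  A report is
    exposed iff some drug row has the canonical drug of interest with the
    primary-suspect role (any role if ``ps_only`` is False).
    """
    if "canonical_name" not in raw.drug.columns:
        raise ValueError("drug names not normalized; run normalize_drug_names first")
    stage_counts = {"input": int(raw.demo["case_id"].nunique())}
    if hcp_only:
        raw = filter_hcp(raw)
    stage_counts["after_reporter_filter"] = len(raw.demo)

    drug_name = normalize_text(drug)
    rows = raw.drug
    hit = rows["canonical_name"] == drug_name
    if ps_only:
        hit &= rows["role_code"] == "PS"
    exposed_ids = set(rows.loc[hit, "case_id"])

    demo = raw.demo.set_index("case_id")
    reports = pd.DataFrame(index=demo.index)
    reports["sex"] = demo["sex"].map(_SEX_MAP).fillna("unknown")
    reports["age_years"] = harmonize_age_years(demo["age_value"], demo["age_unit"])
    reports["weight_kg"] = demo["weight_kg"]
    reports["country"] = demo["country"]
    reports["reporter"] = demo["reporter_qualification"]
    reports["exposed"] = reports.index.isin(exposed_ids)
    subst = _ps_substance(raw)
    reports["primary_suspect"] = subst.reindex(reports.index)

    events = raw.reac.assign(term=raw.reac["preferred_term"].map(normalize_term))[
        ["case_id", "term"]
    ].drop_duplicates()
    has_event = reports.index.isin(set(events["case_id"]))
    stage_counts["dropped_no_events"] = int((~has_event).sum())
    reports = reports[has_event]
    events = events[events["case_id"].isin(reports.index)].reset_index(drop=True)
    stage_counts["cohort"] = len(reports)

    if not reports["exposed"].any():
        raise ValueError(f"no reports with {drug!r} as exposure; no analysis possible")

    provenance = {
        "drug_of_interest": drug_name,
        "hcp_only": hcp_only,
        "ps_only": ps_only,
        "stage_counts": stage_counts,
    }
    return AnalysisCohort(
        reports=reports, events=events, drug_of_interest=drug_name, provenance=provenance
    )


def write_cohort(cohort: AnalysisCohort, outdir) -> None:
    """Write the cohort as TSVs plus a JSON curation log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.reports.to_csv(outdir / "reports.tsv", sep="\t")
    cohort.events.to_csv(outdir / "events.tsv", sep="\t", index=False)
    with open(outdir / "curation_log.json", "w") as fh:
        json.dump(cohort.provenance, fh, indent=2, default=str)


def read_cohort(indir) -> AnalysisCohort:
    indir = Path(indir)
    reports = pd.read_csv(indir / "reports.tsv", sep="\t", index_col=0, dtype={0: str})
    reports.index = reports.index.astype(str)
    events = pd.read_csv(indir / "events.tsv", sep="\t", dtype=str)
    with open(indir / "curation_log.json") as fh:
        provenance = json.load(fh)
    return AnalysisCohort(
        reports=reports,
        events=events,
        drug_of_interest=provenance.get("drug_of_interest", ""),
        provenance=provenance,
    )
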