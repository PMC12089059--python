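"""Synthetic FAERS-like report streams with known ground truth.

The generator emulates the statistical structure a disproportionality
analysis assumes: each case carries demographics drawn from configured
marginals, exactly one primary-suspect drug (the drug of interest with
probability ``exposure_prob``, otherwise one of a pool of background drugs),
and a set of MedDRA-PT-style event terms drawn conditionally independently
given exposure and subgroup.  A planted signal multiplies the *odds* of its
event among exposed cases,

    p' = m * p / (1 - p + m * p),

so the planted multiplier m is exactly the reporting odds ratio the pipeline
estimates — parameter-recovery tests are unbiased in expectation.  Noise
processes (exact-copy duplicate reports under fresh case ids, variant
spellings of the drug name, non-HCP reporters) are injected at configured
rates and recorded, together with the realized per-signal 2x2 counts, in a
ground-truth ledger that downstream tests reconcile against.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contingency import SUBGROUPS, SubgroupSpec
from .io import HCP_CODES, RawTables

#: age bands (years): [low, high) except the top band which is capped at 100
AGE_BANDS = [(0.0, 18.0), (18.0, 65.0), (65.0, 86.0), (86.0, 100.0)]
WEIGHT_BANDS = [(40.0, 50.0), (50.0, 100.0), (100.0, 140.0)]

#: variant spellings of the drug of interest the curation layer must fold
DRUG_VARIANTS = [
    "AMLODIPINE BESYLATE",
    "Norvasc",
    "NORVASC 5MG",
    "amlodipine  besilate",
    "AMLODIPINE 10 MG TABLET",
]

FILLER_TERM = "DRUG INEFFECTIVE"  # assigned when a case draws no event


@dataclass(frozen=True)
class PlantedSignal:
    """One drug-event association planted into the stream.

    ``multiplier`` acts on the reporting odds among exposed cases; an
    optional ``subgroup`` (name or SubgroupSpec) restricts the effect.
    """

    event_term: str
    multiplier: float
    subgroup: Optional[str | SubgroupSpec] = None
    base_rate: Optional[float] = None


@dataclass
class SyntheticConfig:
    n_cases: int = 20_000
    #: P(female, male, unknown)
    sex_probs: tuple = (0.45, 0.45, 0.10)
    #: P(<18, 18-64, 65-85, >=86, unknown)
    age_band_probs: tuple = (0.05, 0.40, 0.35, 0.05, 0.15)
    #: P(<50, 50-100, >100, unknown) kg
    weight_band_probs: tuple = (0.05, 0.30, 0.05, 0.60)
    #: P over HCP reporter codes (MD, PH, OT, RN)
    reporter_probs: tuple = (0.55, 0.20, 0.24, 0.01)
    country_probs: tuple = (
        ("US", 0.55),
        ("GB", 0.12),
        ("CA", 0.08),
        ("FR", 0.07),
        ("IT", 0.05),
        ("JP", 0.05),
        ("DE", 0.04),
        ("BR", 0.04),
    )
    n_background_events: int = 40
    background_event_rate_range: tuple = (0.01, 0.01)
    exposure_prob: float = 0.05
    n_background_drugs: int = 50
    planted_signals: Sequence[PlantedSignal] = ()
    duplicate_rate: float = 0.0
    variant_spelling_rate: float = 0.0
    non_hcp_rate: float = 0.0
    drug_of_interest: str = "AMLODIPINE"
    seed: int = 0

    def validate(self) -> None:
        for name in ("sex_probs", "age_band_probs", "weight_band_probs", "reporter_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a probability simplex, got {p}")
        lo, hi = self.background_event_rate_range
        if not (0 < lo <= hi < 1):
            raise ValueError("background_event_rate_range must satisfy 0 < lo <= hi < 1")
        for r in (self.exposure_prob, self.duplicate_rate, self.variant_spelling_rate, self.non_hcp_rate):
            if not (0 <= r < 1):
                raise ValueError(f"rate {r} outside [0, 1)")
        if not 0 < self.exposure_prob:
            raise ValueError("exposure_prob must be positive")
        for s in self.planted_signals:
            if s.multiplier <= 0:
                raise ValueError(f"multiplier must be > 0, got {s.multiplier}")


@dataclass
class GroundTruthLedger:
    """What the generator actually did, for reconciliation by tests."""

    seed: int
    planted: list = field(default_factory=list)  # dicts: term, multiplier, subgroup, a,b,c,d
    duplicate_pairs: list = field(default_factory=list)  # (original, duplicate) case ids
    variant_spellings: list = field(default_factory=list)  # (case_id, verbatim)
    event_terms: list = field(default_factory=list)
    base_rates: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _subgroup_mask(spec, sex: np.ndarray, age: np.ndarray) -> np.ndarray:
    if spec is None:
        return np.ones(len(sex), dtype=bool)
    if isinstance(spec, str):
        spec = SUBGROUPS[spec]
    m = np.ones(len(sex), dtype=bool)
    if spec.sex is not None:
        m &= sex == ("F" if spec.sex == "female" else "M")
    if spec.min_age is not None or spec.max_age is not None:
        m &= ~np.isnan(age)
        if spec.min_age is not None:
            m &= age >= spec.min_age
        if spec.max_age is not None:
            m &= age < spec.max_age
    return m


def generate(config: SyntheticConfig) -> tuple[RawTables, GroundTruthLedger]:
    """Draw one synthetic quarter; fully reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases

    case_ids = np.char.add("C", np.char.zfill((np.arange(n) + 1).astype(str), 8))

    sex = rng.choice(np.array(["F", "M", "UNK"]), size=n, p=np.asarray(config.sex_probs))
    band = rng.choice(5, size=n, p=np.asarray(config.age_band_probs))
    age = np.full(n, np.nan)
    for i, (lo, hi) in enumerate(AGE_BANDS):
        m = band == i
        age[m] = np.floor(rng.uniform(lo, hi, m.sum()))
    wband = rng.choice(4, size=n, p=np.asarray(config.weight_band_probs))
    weight = np.full(n, np.nan)
    for i, (lo, hi) in enumerate(WEIGHT_BANDS):
        m = wband == i
        weight[m] = np.round(rng.uniform(lo, hi, m.sum()), 1)
    countries, cp = zip(*config.country_probs)
    cp = np.asarray(cp, dtype=float)
    country = rng.choice(np.array(countries), size=n, p=cp / cp.sum())
    reporter = rng.choice(np.array(sorted(HCP_CODES, key="MD PH OT RN".split().index)),
                          size=n, p=np.asarray(config.reporter_probs))
    reporter = np.where(rng.random(n) < config.non_hcp_rate, "CN", reporter)

    year = rng.integers(2004, 2025, n)
    month = rng.integers(1, 13, n)
    day = rng.integers(1, 29, n)
    event_date = np.array([f"{y:04d}{m:02d}{d:02d}" for y, m, d in zip(year, month, day)])

    exposed = rng.random(n) < config.exposure_prob

    # event panel: background terms plus any planted terms not already present
    terms = [f"EVT {i + 1:04d}" for i in range(config.n_background_events)]
    lo, hi = config.background_event_rate_range
    rates = rng.uniform(lo, hi, config.n_background_events)
    rate_of = dict(zip(terms, rates))
    for s in config.planted_signals:
        if s.event_term not in rate_of:
            terms.append(s.event_term)
            rate_of[s.event_term] = s.base_rate if s.base_rate is not None else (lo + hi) / 2
    rates = np.array([rate_of[t] for t in terms])

    P = np.tile(rates, (n, 1))
    planted_meta = []
    for s in config.planted_signals:
        j = terms.index(s.event_term)
        m_sub = _subgroup_mask(s.subgroup, sex, age) & exposed
        p = rate_of[s.event_term]
        P[m_sub, j] = s.multiplier * p / (1 - p + s.multiplier * p)
        planted_meta.append((s, j, s.subgroup))

    occurs = rng.random(P.shape) < P

    # drug rows: one primary suspect per case
    bg_idx = rng.integers(0, config.n_background_drugs, n)
    verbatim = np.array([f"DRUG {i + 1:02d}" for i in bg_idx], dtype=object)
    verbatim[exposed] = config.drug_of_interest
    variant_ids = []
    if config.variant_spelling_rate > 0:
        vmask = exposed & (rng.random(n) < config.variant_spelling_rate)
        choices = rng.integers(0, len(DRUG_VARIANTS), int(vmask.sum()))
        verbatim[vmask] = [DRUG_VARIANTS[k] for k in choices]
        variant_ids = list(zip(case_ids[vmask], verbatim[vmask]))

    demo = pd.DataFrame(
        {
            "case_id": case_ids,
            "version_id": 1,
            "event_date": event_date,
            "sex": sex,
            "age_value": age,
            "age_unit": np.where(np.isnan(age), "", "YR"),
            "weight_kg": weight,
            "country": country,
            "reporter_qualification": reporter,
        }
    )
    drug = pd.DataFrame(
        {
            "case_id": case_ids,
            "drug_seq": 1,
            "verbatim_drug_name": verbatim,
            "role_code": "PS",
        }
    )
    rows_ix, cols_ix = np.nonzero(occurs)
    term_arr = np.array(terms, dtype=object)
    reac = pd.DataFrame(
        {"case_id": case_ids[rows_ix], "preferred_term": term_arr[cols_ix]}
    )
    empty = ~occurs.any(axis=1)
    if empty.any():
        reac = pd.concat(
            [reac, pd.DataFrame({"case_id": case_ids[empty], "preferred_term": FILLER_TERM})],
            ignore_index=True,
        )
    reac = reac.sort_values(["case_id", "preferred_term"], kind="stable").reset_index(drop=True)

    # realized per-signal 2x2 counts among the cases that survive default
    # curation (HCP reporters; every case has >= 1 event by construction)
    hcp = np.isin(reporter, list(HCP_CODES))
    ledger = GroundTruthLedger(seed=config.seed, event_terms=terms,
                               base_rates={t: float(rate_of[t]) for t in terms})
    for s, j, sub in planted_meta:
        insub = _subgroup_mask(sub, sex, age) & hcp
        ev = occurs[:, j]
        ledger.planted.append(
            {
                "term": s.event_term,
                "multiplier": s.multiplier,
                "subgroup": sub if (sub is None or isinstance(sub, str)) else sub.name,
                "a": int((insub & exposed & ev).sum()),
                "b": int((insub & exposed & ~ev).sum()),
                "c": int((insub & ~exposed & ev).sum()),
                "d": int((insub & ~exposed & ~ev).sum()),
            }
        )

    # duplicates: exact key-tuple copies under fresh case ids
    if config.duplicate_rate > 0:
        k = int(round(config.duplicate_rate * n))
        dup_idx = np.sort(rng.choice(n, size=k, replace=False))
        dup_ids = np.char.add("D", case_ids[dup_idx])
        ddemo = demo.iloc[dup_idx].copy()
        ddemo["case_id"] = dup_ids
        demo = pd.concat([demo, ddemo], ignore_index=True)
        ddrug = drug.iloc[dup_idx].copy()
        ddrug["case_id"] = dup_ids
        drug = pd.concat([drug, ddrug], ignore_index=True)
        old_to_new = dict(zip(case_ids[dup_idx], dup_ids))
        dreac = reac[reac["case_id"].isin(old_to_new)].copy()
        dreac["case_id"] = dreac["case_id"].map(old_to_new)
        reac = pd.concat([reac, dreac], ignore_index=True)
        ledger.duplicate_pairs = [(str(o), str(d)) for o, d in old_to_new.items()]

    ledger.variant_spellings = [(str(c), str(v)) for c, v in variant_ids]

    raw = RawTables(demo=demo, drug=drug, reac=reac,
                    report={"generator": {"n_cases": n, "seed": config.seed}})
    return raw, ledger


# ---------------------------------------------------------------------------
# printed reference marginals (amlodipine cohort general-characteristics table)

_T2_N = 18_886
_T2_SEX = {"female": 9_182, "male": 7_846, "unknown": 1_858}
_T2_AGE = {"<18": 695, "18-64": 7_170, "65-85": 6_737, ">=86": 1_217, "unknown": 3_067}
_T2_WEIGHT = {"<50": 398, "50-100": 4_143, ">100": 702, "unknown": 13_643}
_T2_REPORTER = {"MD": 10_038, "PH": 3_549, "OT": 5_291, "RN": 8}
_T2_COUNTRIES = ["US", "GB", "CA", "FR", "IT"]


def table2_like_config(n_cases: int = 100_000, seed: int = 0, **overrides) -> SyntheticConfig:
    """A config whose demographic marginals match the published amlodipine
    cohort summary (sex, age-band, weight-band and reporter proportions)."""
    sex = np.array([_T2_SEX["female"], _T2_SEX["male"], _T2_SEX["unknown"]], float) / _T2_N
    agec = np.array([_T2_AGE[k] for k in ("<18", "18-64", "65-85", ">=86", "unknown")], float)
    wc = np.array([_T2_WEIGHT[k] for k in ("<50", "50-100", ">100", "unknown")], float)
    rep = np.array([_T2_REPORTER[k] for k in ("MD", "PH", "OT", "RN")], float)
    cfg = SyntheticConfig(
        n_cases=n_cases,
        sex_probs=tuple(sex / sex.sum()),
        age_band_probs=tuple(agec / agec.sum()),
        weight_band_probs=tuple(wc / wc.sum()),
        reporter_probs=tuple(rep / rep.sum()),
        seed=seed,
        **overrides,
    )
    return cfg


def table2_fixture_cohort():
    """An AnalysisCohort whose marginal counts equal the printed summary
    table exactly (N = 18,886) — deterministic, no sampling.

    The joint distribution across blocks is arbitrary (only marginals are
    printed); each report carries one generic event term and is exposed.
    """
    from .io import AnalysisCohort

    def expand(counts: dict, reps: dict) -> np.ndarray:
        return np.concatenate([np.full(c, reps[k], dtype=object) for k, c in counts.items()])

    sex = expand(_T2_SEX, {k: k for k in _T2_SEX})
    age_rep = {"<18": 10.0, "18-64": 40.0, "65-85": 75.0, ">=86": 90.0, "unknown": np.nan}
    age = expand(_T2_AGE, age_rep).astype(float)
    weight_rep = {"<50": 45.0, "50-100": 75.0, ">100": 120.0, "unknown": np.nan}
    weight = expand(_T2_WEIGHT, weight_rep).astype(float)
    reporter = expand(_T2_REPORTER, {k: k for k in _T2_REPORTER})
    country_counts = {"US": 9_000, "GB": 3_500, "CA": 2_500, "FR": 2_000, "IT": 1_500, "JP": 386}
    country = expand(country_counts, {k: k for k in country_counts})

    ids = [f"T{i + 1:06d}" for i in range(_T2_N)]
    reports = pd.DataFrame(
        {
            "sex": sex,
            "age_years": age,
            "weight_kg": weight,
            "country": country,
            "reporter": reporter,
            "exposed": True,
            "primary_suspect": "amlodipine",
        },
        index=pd.Index(ids, name="case_id"),
    )
    events = pd.DataFrame({"case_id": ids, "term": "adverse event"})
    return AnalysisCohort(
        reports=reports,
        events=events,
        drug_of_interest="amlodipine",
        provenance={"fixture": "printed general-characteristics marginals", "stage_counts": {}},
    )


def toy_soc_mapping(terms) -> pd.DataFrame:
    """A deterministic toy PT -> SOC table for synthetic vocabularies."""
    socs = [
        "Investigations",
        "Cardiac disorders",
        "Nervous system disorders",
        "Gastrointestinal disorders",
        "Respiratory, thoracic and mediastinal disorders",
    ]
    terms = sorted({str(t) for t in terms})
    return pd.DataFrame(
        {
            "preferred_term": terms,
            "system_organ_class": [socs[i % len(socs)] for i in range(len(terms))],
        }
    )
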