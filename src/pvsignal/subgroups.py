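"""Signal sets across cohorts: intersection, SOC composition, characteristics.

Signal detection is run once per analysis cohort (entire population, male,
female, elderly, younger); the resulting consensus-term sets are intersected
to find the adverse events flagged in *every* cohort, and the full
exact-membership partition (the blocks of an upset plot) is emitted so the
overlap structure is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from ._util import normalize_term, pct_half_up
from .contingency import SUBGROUPS, stratify
from .stats import detect_signals, signal_table


@dataclass
class SignalSet:
    """The consensus signal terms of one cohort."""

    subgroup: str
    terms: frozenset
    results: Optional[pd.DataFrame] = None

    @classmethod
    def from_cohort(cls, cohort, subgroup) -> "SignalSet":
        name = subgroup if isinstance(subgroup, str) else subgroup.name
        sig = detect_signals(cohort, subgroup)
        return cls(subgroup=name, terms=frozenset(sig.index), results=sig)


def detect_all_subgroups(cohort, subgroups: Iterable = SUBGROUPS.values()) -> list[SignalSet]:
    return [SignalSet.from_cohort(cohort, sg) for sg in subgroups]


def intersect_signal_sets(sets: list[SignalSet]) -> tuple[frozenset, dict]:
    """Full intersection plus the exact-membership partition.

    The partition maps each non-empty combination of subgroup names (a
    frozenset) to the terms belonging to exactly those sets; blocks are
    disjoint and their union is the union of all sets.
    """
    if len(sets) < 2:
        raise ValueError("need at least two signal sets to intersect")
    common = frozenset.intersection(*(s.terms for s in sets))
    membership: dict[str, frozenset] = {}
    for term in frozenset.union(*(s.terms for s in sets)):
        membership[term] = frozenset(s.subgroup for s in sets if term in s.terms)
    partition: dict[frozenset, set] = {}
    for term, combo in membership.items():
        partition.setdefault(combo, set()).add(term)
    return common, partition


def upset_matrix(sets: list[SignalSet]) -> pd.DataFrame:
    """Term x subgroup boolean membership matrix (upset-plot input)."""
    union = sorted(frozenset.union(*(s.terms for s in sets)))
    return pd.DataFrame(
        {s.subgroup: [t in s.terms for t in union] for s in sets},
        index=pd.Index(union, name="event_term"),
    )


def soc_composition(signal_set: SignalSet, mapping: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Proportion of signal terms per system organ class.

    ``mapping`` has columns (preferred_term, system_organ_class); a PT maps
    to exactly one primary SOC.  Terms absent from the mapping are returned
    separately, never silently dropped.  Proportions are over mapped terms
    and sum to 1.
    """
    m = mapping.copy()
    m["preferred_term"] = m["preferred_term"].map(normalize_term)
    if m["preferred_term"].duplicated().any():
        dup = m.loc[m["preferred_term"].duplicated(), "preferred_term"].iloc[0]
        raise ValueError(f"preferred term {dup!r} maps to more than one SOC")
    lut = m.set_index("preferred_term")["system_organ_class"]
    terms = sorted(signal_set.terms)
    mapped = [t for t in terms if t in lut.index]
    unmapped = [t for t in terms if t not in lut.index]
    if not mapped:
        return pd.DataFrame(columns=["system_organ_class", "n_terms", "proportion"]), unmapped
    counts = lut.loc[mapped].value_counts()
    out = counts.rename("n_terms").reset_index()
    out["proportion"] = out["n_terms"] / len(mapped)
    return out, unmapped


# ---------------------------------------------------------------------------
# descriptive cohort characteristics

_AGE_BANDS = [("<18", 0, 18), ("18-64", 18, 65), ("65-85", 65, 86), (">=86", 86, None)]
_WEIGHT_BANDS = [("<50 kg", None, 50), ("50-100 kg", 50, 100.000001), (">100 kg", 100.000001, None)]


def _band(v, bands):
    if pd.isna(v):
        return "unknown"
    for name, lo, hi in bands:
        if (lo is None or v >= lo) and (hi is None or v < hi):
            return name
    return "unknown"


def cohort_characteristics(cohort, top_countries: int = 5) -> pd.DataFrame:
    """Counts and percentages per demographic block, publication style.

    Percentages are of the cohort total, rounded half-up to one decimal.
    Countries are ranked by count, ties broken by name.
    """
    rep = cohort.reports
    total = len(rep)
    rows = []

    def block(name, series):
        for cat, cnt in series.items():
            rows.append((name, cat, int(cnt), pct_half_up(cnt, total)))

    block("sex", rep["sex"].value_counts())
    block("age", rep["age_years"].map(lambda v: _band(v, _AGE_BANDS)).value_counts())
    block("weight", rep["weight_kg"].map(lambda v: _band(v, _WEIGHT_BANDS)).value_counts())
    block("reporter", rep["reporter"].value_counts())

    cc = rep["country"].value_counts().sort_index().sort_values(
        ascending=False, kind="stable"
    )
    block("country_top", cc.head(top_countries))

    return pd.DataFrame(rows, columns=["block", "category", "count", "pct"])


def characteristic_pct(table: pd.DataFrame, block: str, category: str) -> float:
    row = table[(table["block"] == block) & (table["category"] == category)]
    if row.empty:
        return 0.0
    return float(row["pct"].iloc[0])


def write_intersection(common, partition, sets, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.Series(sorted(common), name="event_term").to_csv(
        outdir / "common.tsv", sep="\t", index=False
    )
    upset_matrix(sets).to_csv(outdir / "upset_matrix.tsv", sep="\t")
    rows = [
        ("+".join(sorted(combo)), len(terms), ";".join(sorted(terms)))
        for combo, terms in sorted(partition.items(), key=lambda kv: -len(kv[1]))
    ]
    pd.DataFrame(rows, columns=["subgroups", "n_terms", "terms"]).to_csv(
        outdir / "upset_partition.tsv", sep="\t", index=False
    )
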