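"""2x2 contingency tables for (drug, event) pairs and cohort stratification.

The unit of counting is the *report*: a report either lists a preferred term
(at least once) or it does not, and it is either exposed to the drug of
interest (primary-suspect role) or it is not.  For one event term in one
cohort this gives the classic table

    =============  ==========  ==============
    .              target drug  all other drugs
    target event        a             c
    other events        b             d
    =============  ==========  ==============

with N = a + b + c + d equal to the cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

from ._util import normalize_term


@dataclass(frozen=True)
class ContingencyTable:
    """Report counts for one (drug, event) pair in one cohort."""

    a: int  # exposed reports listing the event
    b: int  # exposed reports without it
    c: int  # non-exposed reports listing the event
    d: int  # non-exposed reports without it

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int,)) or (hasattr(v, "is_integer") and float(v).is_integer())):
                raise ValueError(f"cell {name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"cell {name} must be >= 0, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SubgroupSpec:
    """A named demographic filter defining an analysis cohort.

    ``sex`` restricts to a known sex; ``min_age``/``max_age`` restrict to a
    half-open age interval [min_age, max_age) in years with age known.
    Reports with unknown sex (age) are excluded from sex (age) subgroups.
    """

    name: str
    sex: Optional[str] = None
    min_age: Optional[float] = None
    max_age: Optional[float] = None

    def mask(self, reports: pd.DataFrame) -> pd.Series:
        m = pd.Series(True, index=reports.index)
        if self.sex is not None:
            m &= reports["sex"] == self.sex
        if self.min_age is not None or self.max_age is not None:
            age = reports["age_years"]
            m &= age.notna()
            if self.min_age is not None:
                m &= age >= self.min_age
            if self.max_age is not None:
                m &= age < self.max_age
        return m


#: The five standard analysis cohorts.  The elderly/younger cut is 65 years:
#: the printed subgroup denominators equal the sums of the 65-85 and >=86
#: (resp. <18 and 18-64) age bands, which fixes the cut.
SUBGROUPS: dict[str, SubgroupSpec] = {
    "entire": SubgroupSpec("entire"),
    "male": SubgroupSpec("male", sex="male"),
    "female": SubgroupSpec("female", sex="female"),
    "elderly": SubgroupSpec("elderly", min_age=65),
    "younger": SubgroupSpec("younger", max_age=65),
}


def stratify(cohort, spec: SubgroupSpec | str):
    """Restrict a cohort to the reports satisfying a subgroup predicate.

    Raises ``ValueError`` if the subgroup would be empty.
    """
    if isinstance(spec, str):
        spec = SUBGROUPS[spec]
    m = spec.mask(cohort.reports)
    if spec.sex is None and spec.min_age is None and spec.max_age is None:
        return cohort
    reports = cohort.reports[m]
    if reports.empty:
        raise ValueError(f"subgroup {spec.name!r} selects no reports")
    events = cohort.events[cohort.events["case_id"].isin(reports.index)]
    prov = dict(cohort.provenance)
    prov["subgroup"] = spec.name
    prov.setdefault("stage_counts", {})
    return replace(cohort, reports=reports, events=events, provenance=prov)


def event_tables(cohort) -> pd.DataFrame:
    """Per-event report counts a/b/c/d for every candidate term.

    Candidates are all distinct terms with exposed count a >= 1.  A report
    contributes once per distinct term it lists.  Returns a DataFrame indexed
    by term with integer columns a, b, c, d.
    """
    rep = cohort.reports
    n_total = len(rep)
    n_exposed = int(rep["exposed"].sum())
    ev = cohort.events.drop_duplicates(["case_id", "term"])
    ev = ev.merge(
        rep["exposed"].rename("exposed"), left_on="case_id", right_index=True, how="inner"
    )
    g = ev.groupby("term")["exposed"]
    counts = pd.DataFrame({"a": g.sum().astype(int), "n_event": g.size().astype(int)})
    counts["c"] = counts["n_event"] - counts["a"]
    counts["b"] = n_exposed - counts["a"]
    counts["d"] = n_total - n_exposed - counts["c"]
    counts = counts[counts["a"] >= 1]
    return counts[["a", "b", "c", "d"]].sort_index()


def build_table(cohort, event: str) -> ContingencyTable:
    """The 2x2 table of one event term in the cohort.

    Raises ``KeyError`` naming the term if it occurs in no report.
    """
    term = normalize_term(event)
    rep = cohort.reports
    ev = cohort.events
    cases = ev.loc[ev["term"] == term, "case_id"].unique()
    if len(cases) == 0:
        raise KeyError(f"event term {event!r} absent from cohort")
    has_event = rep.index.isin(cases)
    exposed = rep["exposed"].to_numpy()
    a = int((exposed & has_event).sum())
    c = int((~exposed & has_event).sum())
    b = int(exposed.sum()) - a
    d = len(rep) - a - b - c
    return ContingencyTable(a, b, c, d)


def enumerate_candidate_events(cohort) -> pd.DataFrame:
    """All event terms with exposed count a >= 1, with their 2x2 tables."""
    return event_tables(cohort)
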