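"""Case/non-case logistic validation of candidate signals.

Each candidate adverse event is re-tested as a binary outcome in a
multivariable logistic regression on drug exposure adjusted for sex and age
band.  The unadjusted exposure odds ratio is algebraically identical to the
ROR of the collapsed 2x2 table; adjustment guards against demographic
confounding of the disproportionality estimate.  Wald inference is reported
per term, with no multiple-testing adjustment (recorded in the run
manifest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import normalize_term

#: age bands used as covariate levels; 18-64 is the reference
AGE_LEVELS = ["<18", "18-64", "65-85", ">=86"]


@dataclass(frozen=True)
class RegressionResult:
    event_term: str
    odds_ratio: float
    ci: tuple
    p_value: float
    coefficients: dict
    n_used: int
    n_dropped: int
    converged: bool
    separation: bool = False

    @property
    def confirmed(self) -> bool:
        return bool(self.converged and self.odds_ratio > 1 and self.p_value < 0.05)


def _age_band(v: float) -> str:
    if pd.isna(v):
        return "unknown"
    if v < 18:
        return "<18"
    if v < 65:
        return "18-64"
    if v < 86:
        return "65-85"
    return ">=86"


def _design(cohort, covariates: Sequence[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    rep = cohort.reports
    keep = pd.Series(True, index=rep.index)
    X = pd.DataFrame(index=rep.index)
    X["const"] = 1.0
    X["exposed"] = rep["exposed"].astype(float)
    if "sex" in covariates:
        keep &= rep["sex"].isin(["female", "male"])
        X["sex_male"] = (rep["sex"] == "male").astype(float)
    if "age_group" in covariates:
        band = rep["age_years"].map(_age_band)
        keep &= band != "unknown"
        for lvl in AGE_LEVELS:
            if lvl == "18-64":  # reference level
                continue
            X[f"age_{lvl}"] = (band == lvl).astype(float)
    return X[keep], rep[keep]


def fit_adr_logistic(
    cohort,
    event: str,
    covariates: Sequence[str] = ("sex", "age_group"),
) -> RegressionResult:
    """Logistic fit of one event on exposure plus demographic covariates.

    Raises ``ValueError`` when the outcome has prevalence 0 or 1 among the
    usable reports; non-convergence and separation are flagged on the
    result, never silently returned as estimates.
    """
    term = normalize_term(event)
    X, rep = _design(cohort, covariates)
    cases = set(cohort.events.loc[cohort.events["term"] == term, "case_id"])
    y = pd.Series(rep.index.isin(cases).astype(float), index=rep.index)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"outcome prevalence for {event!r} is 0 or 1; cannot fit")

    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        res = model.fit(maxiter=100, tol=1e-8)
    beta = res.params["exposed"]
    separation = bool(np.abs(res.params).max() > 15 or not np.isfinite(res.bse).all())
    converged = bool(getattr(res, "converged", True)) and not separation
    if separation:
        ci = (np.nan, np.nan)
        p = np.nan
    else:
        se = res.bse["exposed"]
        ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
        p = float(res.pvalues["exposed"])
    return RegressionResult(
        event_term=term,
        odds_ratio=float(np.exp(beta)),
        ci=ci,
        p_value=p,
        coefficients={k: float(v) for k, v in res.params.items()},
        n_used=int(len(y)),
        n_dropped=int(len(cohort.reports) - len(y)),
        converged=converged,
        separation=separation,
    )


def validate_intersection(
    cohort,
    common_terms: Iterable[str],
    covariates: Sequence[str] = ("sex", "age_group"),
) -> pd.DataFrame:
    """Fit every intersected term; verdict = (OR > 1 and p < 0.05).

    Per-term fit errors become flagged rows (converged = False), so one
    degenerate outcome never aborts the report.
    """
    rows = []
    for term in sorted({normalize_term(t) for t in common_terms}):
        try:
            r = fit_adr_logistic(cohort, term, covariates)
            rows.append(
                (term, r.odds_ratio, r.ci[0], r.ci[1], r.p_value, r.n_used,
                 r.converged, r.separation, r.confirmed)
            )
        except (ValueError, KeyError) as exc:
            rows.append((term, np.nan, np.nan, np.nan, np.nan, 0, False, False, False))
    return pd.DataFrame(
        rows,
        columns=["event_term", "odds_ratio", "ci_low", "ci_high", "p_value",
                 "n_used", "converged", "separation", "confirmed"],
    ).set_index("event_term")


def write_report(
    report: pd.DataFrame,
    crude: Optional[pd.DataFrame],
    outdir,
    manifest: Optional[dict] = None,
) -> None:
    """Final report TSV (with crude ROR merged in when given) + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = report.copy()
    if crude is not None and "ror" in crude.columns:
        out = out.join(crude["ror"].rename("crude_ror"), how="left")
    out.to_csv(outdir / "validated_signals.tsv", sep="\t")
    meta = {
        "inference": "Wald",
        "multiple_testing_adjustment": "none",
        "covariate_coding": {"sex": "male indicator (unknown dropped)",
                             "age": f"bands {AGE_LEVELS}, reference 18-64"},
    }
    meta.update(manifest or {})
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
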