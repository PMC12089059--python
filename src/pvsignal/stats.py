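"""Disproportionality statistics and signal criteria.

Four classical measures are computed per (drug, event) 2x2 table
(a, b, c, d; N = a+b+c+d):

* ROR  = ad/bc, with the log-Wald 95% CI
  exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d));
* PRR  = a(c+d) / (c(a+b)), with the Pearson chi-square
  N(ad−bc)² / [(a+b)(c+d)(a+c)(b+d)];
* BCPNN information component IC = log₂[aN / ((a+b)(a+c))], with the
  closed-form posterior moment approximation of Bate et al. for E(IC) and
  V(IC) under the canonical priors, and IC025 = E(IC) − 2·sqrt(V(IC));
* EBGM  = aN / ((a+b)(a+c)) — the observed-to-expected reporting ratio —
  with EBGM05 = exp(ln EBGM − 1.96·sqrt(1/a + 1/b + 1/c + 1/d)).

A pair is a *positive signal* under each method when

* ROR: 95% CI lower bound > 1 and a ≥ 3;
* PRR: PRR ≥ 2, chi² ≥ 4 and a ≥ 3;
* BCPNN: IC025 > 0;
* EBGM: EBGM05 > 2;

and a *consensus* signal when all four agree.  Zero cells leave ROR/PRR/EBGM
undefined (NaN, never a positive flag); the BCPNN posterior is finite for
every table thanks to its prior.

An optional multi-item gamma-Poisson shrinker (``mgps_ebgm``) is provided
for users who want the empirical-Bayes shrinkage estimator rather than the
plain O/E ratio; the plain ratio is the default throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

from .contingency import ContingencyTable, SubgroupSpec, event_tables, stratify

Z95 = 1.96

# canonical BCPNN priors (joint cell gamma11 = 1; marginals Beta(1, 1)-like
# with alpha = beta = 2)
_ALPHA1 = _BETA1 = _GAMMA11 = 1.0
_ALPHA = _BETA = 2.0


# ---------------------------------------------------------------------------
# vectorized kernels (arrays of cells) -- the scalar API wraps these


def _cells(a, b, c, d):
    return (np.asarray(a, float), np.asarray(b, float),
            np.asarray(c, float), np.asarray(d, float))


def ror_arrays(a, b, c, d):
    """(estimate, lo, hi); NaN where any cell is zero."""
    a, b, c, d = _cells(a, b, c, d)
    ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = np.where(ok, (a * d) / (b * c), np.nan)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = np.exp(np.log(est) - Z95 * se)
        hi = np.exp(np.log(est) + Z95 * se)
    return est, np.where(ok, lo, np.nan), np.where(ok, hi, np.nan)


def prr_arrays(a, b, c, d):
    """(estimate, chi2); NaN where a denominator vanishes."""
    a, b, c, d = _cells(a, b, c, d)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        den = c * (a + b)
        est = np.where(den > 0, a * (c + d) / den, np.nan)
        chi_den = (a + b) * (c + d) * (a + c) * (b + d)
        chi2 = np.where(chi_den > 0, n * (a * d - b * c) ** 2 / chi_den, np.nan)
    return est, chi2


def ic_arrays(a, b, c, d):
    """(raw IC, E(IC), IC025) in bits.  Raw IC is NaN at a = 0; the
    posterior expectation and bound are finite for every table."""
    a, b, c, d = _cells(a, b, c, d)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(a > 0, np.log2(a * n / ((a + b) * (a + c))), np.nan)
    gamma = _GAMMA11 * (n + _ALPHA) * (n + _BETA) / ((a + b + _ALPHA1) * (a + c + _BETA1))
    eic = np.log2(
        (a + _GAMMA11) * (n + _ALPHA) * (n + _BETA)
        / ((n + gamma) * (a + b + _ALPHA1) * (a + c + _BETA1))
    )
    vic = (
        (n - a + gamma - _GAMMA11) / ((a + _GAMMA11) * (1 + n + gamma))
        + (n - a - b + _ALPHA - _ALPHA1) / ((a + b + _ALPHA1) * (1 + n + _ALPHA))
        + (n - a - c + _BETA - _BETA1) / ((a + c + _BETA1) * (1 + n + _BETA))
    ) / np.log(2) ** 2
    ic025 = eic - 2.0 * np.sqrt(vic)
    return raw, eic, ic025


def ebgm_arrays(a, b, c, d):
    """(estimate, ebgm05): observed/expected ratio with log-normal CI."""
    a, b, c, d = _cells(a, b, c, d)
    n = a + b + c + d
    ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = np.where(a > 0, a * n / ((a + b) * (a + c)), np.nan)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = np.exp(np.log(est) - Z95 * se)
    return np.where(ok | (a > 0), est, np.nan), np.where(ok, lo, np.nan)


def criteria_arrays(a, ror_lo, prr_est, chi2, ic025, ebgm05):
    """Per-method positive-signal flags and the four-way consensus."""
    a = np.asarray(a, float)
    with np.errstate(invalid="ignore"):
        ror_pos = np.nan_to_num(ror_lo, nan=-np.inf) > 1.0
        ror_pos &= a >= 3
        prr_pos = (np.nan_to_num(prr_est, nan=-np.inf) >= 2.0) & (
            np.nan_to_num(chi2, nan=-np.inf) >= 4.0
        ) & (a >= 3)
        bcpnn_pos = np.asarray(ic025, float) > 0.0
        ebgm_pos = np.nan_to_num(ebgm05, nan=-np.inf) > 2.0
    consensus = ror_pos & prr_pos & bcpnn_pos & ebgm_pos
    return ror_pos, prr_pos, bcpnn_pos, ebgm_pos, consensus


# ---------------------------------------------------------------------------
# scalar API


@dataclass(frozen=True)
class SignalResult:
    """All four statistics, interval bounds and flags for one pair."""

    event_term: str
    table: ContingencyTable
    ror: float
    ror_ci: tuple
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    ror_pos: bool
    prr_pos: bool
    bcpnn_pos: bool
    ebgm_pos: bool
    consensus: bool


def ror(table: ContingencyTable):
    est, lo, hi = ror_arrays(table.a, table.b, table.c, table.d)
    return float(est), float(lo), float(hi)


def prr(table: ContingencyTable):
    est, chi2 = prr_arrays(table.a, table.b, table.c, table.d)
    return float(est), float(chi2)


def bcpnn_ic(table: ContingencyTable):
    raw, eic, ic025 = ic_arrays(table.a, table.b, table.c, table.d)
    return float(raw), float(ic025)


def ebgm(table: ContingencyTable):
    est, lo = ebgm_arrays(table.a, table.b, table.c, table.d)
    return float(est), float(lo)


def evaluate_criteria(a, ror_ci_lower, prr_est, chi2, ic025, ebgm05) -> dict:
    """Apply the four positive-signal criteria to already-computed bounds."""
    r, p, bc, e, cons = criteria_arrays(
        np.atleast_1d(a), np.atleast_1d(ror_ci_lower), np.atleast_1d(prr_est),
        np.atleast_1d(chi2), np.atleast_1d(ic025), np.atleast_1d(ebgm05),
    )
    return {
        "ror_pos": bool(r[0]),
        "prr_pos": bool(p[0]),
        "bcpnn_pos": bool(bc[0]),
        "ebgm_pos": bool(e[0]),
        "consensus": bool(cons[0]),
    }


def compute_signal(event_term: str, table: ContingencyTable) -> SignalResult:
    est, lo, hi = ror(table)
    prr_est, chi2 = prr(table)
    raw_ic, ic025 = bcpnn_ic(table)
    ebgm_est, ebgm05 = ebgm(table)
    flags = evaluate_criteria(table.a, lo, prr_est, chi2, ic025, ebgm05)
    return SignalResult(
        event_term=event_term, table=table, ror=est, ror_ci=(lo, hi),
        prr=prr_est, chi2=chi2, ic=raw_ic, ic025=ic025,
        ebgm=ebgm_est, ebgm05=ebgm05, **flags,
    )


# ---------------------------------------------------------------------------
# cohort-level detection


def signal_table(cohort, subgroup: Optional[SubgroupSpec | str] = None) -> pd.DataFrame:
    """Statistics + flags for every candidate event of a (stratified) cohort.

    Returns a DataFrame indexed by term with columns a, b, c, d, ror,
    ror_low, ror_high, prr, chi2, ic, ic025, ebgm, ebgm05, the four
    per-method flags and consensus.
    """
    if subgroup is not None:
        cohort = stratify(cohort, subgroup)
    t = event_tables(cohort)
    a, b, c, d = (t[k].to_numpy() for k in "abcd")
    out = t.copy()
    out["ror"], out["ror_low"], out["ror_high"] = ror_arrays(a, b, c, d)
    out["prr"], out["chi2"] = prr_arrays(a, b, c, d)
    out["ic"], _, out["ic025"] = ic_arrays(a, b, c, d)
    out["ebgm"], out["ebgm05"] = ebgm_arrays(a, b, c, d)
    flags = criteria_arrays(a, out["ror_low"], out["prr"], out["chi2"],
                            out["ic025"], out["ebgm05"])
    for name, col in zip(("ror_pos", "prr_pos", "bcpnn_pos", "ebgm_pos", "consensus"), flags):
        out[name] = col
    return out


def detect_signals(
    cohort,
    subgroup: Optional[SubgroupSpec | str] = None,
    top: Optional[int] = None,
) -> pd.DataFrame:
    """Consensus signals of a cohort, ranked by descending ROR.

    Ties in ROR break lexicographically on the event term.
    """
    table = signal_table(cohort, subgroup)
    sig = table[table["consensus"]].copy()
    sig["_term"] = sig.index
    sig = sig.sort_values(["ror", "_term"], ascending=[False, True]).drop(columns="_term")
    if top is not None:
        sig = sig.head(top)
    return sig


def write_signals(table: pd.DataFrame, path, subgroup: str = "entire") -> None:
    out = table.reset_index(names="event_term")
    out.insert(0, "subgroup", subgroup)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# optional multi-item gamma-Poisson shrinker (empirical-Bayes EBGM)


def mgps_ebgm(tables: pd.DataFrame, min_count: int = 0) -> pd.DataFrame:
    """Empirical-Bayes geometric mean by gamma-Poisson shrinkage.

    Fits a two-component gamma mixture prior on the relative reporting rate
    by maximizing the marginal negative-binomial likelihood over all pairs,
    then reports the posterior geometric mean (ebgm_shrunk) and the posterior
    5th percentile (ebgm05_shrunk) per pair.

    ``tables`` needs integer columns a, b, c, d (as from ``event_tables``).
    """
    a = tables["a"].to_numpy(float)
    n = tables[["a", "b", "c", "d"]].sum(axis=1).to_numpy(float)
    e = (tables["a"] + tables["b"]).to_numpy(float) * (
        tables["a"] + tables["c"]
    ).to_numpy(float) / n
    use = a >= min_count

    def nll(theta):
        a1, b1, a2, b2 = np.exp(theta[:4])
        w = special.expit(theta[4])
        l1 = sps.nbinom.logpmf(a[use], a1, b1 / (b1 + e[use]))
        l2 = sps.nbinom.logpmf(a[use], a2, b2 / (b2 + e[use]))
        m = np.maximum(l1, l2)
        return -np.sum(m + np.log(w * np.exp(l1 - m) + (1 - w) * np.exp(l2 - m)))

    x0 = np.array([np.log(0.2), np.log(0.1), np.log(2.0), np.log(4.0), 0.0])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8})
    a1, b1, a2, b2 = np.exp(res.x[:4])
    w = float(special.expit(res.x[4]))

    l1 = sps.nbinom.logpmf(a, a1, b1 / (b1 + e))
    l2 = sps.nbinom.logpmf(a, a2, b2 / (b2 + e))
    m = np.maximum(l1, l2)
    q1 = w * np.exp(l1 - m)
    q1 = q1 / (q1 + (1 - w) * np.exp(l2 - m))

    elog = q1 * (special.digamma(a1 + a) - np.log(b1 + e)) + (1 - q1) * (
        special.digamma(a2 + a) - np.log(b2 + e)
    )
    ebgm_point = np.exp(elog)

    def q05(i):
        g1 = sps.gamma(a1 + a[i], scale=1 / (b1 + e[i]))
        g2 = sps.gamma(a2 + a[i], scale=1 / (b2 + e[i]))
        f = lambda x: q1[i] * g1.cdf(x) + (1 - q1[i]) * g2.cdf(x) - 0.05
        hi = max(g1.ppf(0.05), g2.ppf(0.05), 1e-8)
        lo = min(g1.ppf(0.05), g2.ppf(0.05), hi / 2)
        while f(lo) > 0:
            lo /= 2
        while f(hi) < 0:
            hi *= 2
        return optimize.brentq(f, lo, hi)

    out = tables.copy()
    out["ebgm_shrunk"] = ebgm_point
    out["ebgm05_shrunk"] = [q05(i) for i in range(len(a))]
    out.attrs["mgps_prior"] = {"alpha1": a1, "beta1": b1, "alpha2": a2,
                               "beta2": b2, "weight": w, "converged": bool(res.success)}
    return out
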