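"""Disproportionality formulas vs independent oracles; criteria gating."""

import numpy as np
import pytest
from scipy import stats as sps

import pvsignal as pv
from pvsignal.stats import (
    Z95,
    criteria_arrays,
    ebgm_arrays,
    ic_arrays,
    prr_arrays,
    ror_arrays,
)

from conftest import random_tables


def oracle_stats(a, b, c, d):
    """Brute-force re-derivation of every statistic, coded from the printed
    formulas independently of the implementation."""
    n = a + b + c + d
    ror = (a / b) / (c / d)
    se = np.sqrt(sum(1.0 / x for x in (a, b, c, d)))
    prr = (a / (a + b)) / (c / (c + d))
    exp_a = (a + b) * (a + c) / n
    exp_b = (a + b) * (b + d) / n
    exp_c = (c + d) * (a + c) / n
    exp_d = (c + d) * (b + d) / n
    chi2 = sum(
        (obs - exp) ** 2 / exp
        for obs, exp in [(a, exp_a), (b, exp_b), (c, exp_c), (d, exp_d)]
    )
    rrr = a / exp_a
    return {
        "ror": ror,
        "ror_low": np.exp(np.log(ror) - Z95 * se),
        "ror_high": np.exp(np.log(ror) + Z95 * se),
        "prr": prr,
        "chi2": chi2,
        "ic": np.log2(rrr),
        "ebgm": rrr,
        "ebgm05": np.exp(np.log(rrr) - Z95 * se),
    }


HAND_TABLE = (5, 5, 10, 80)
# frozen values computed with oracle_stats and cross-checked against
# statsmodels Table2x2 / scipy chi2_contingency
HAND_EXPECTED = {
    "ror": 8.0,
    "ror_low": 1.9665781986190776,
    "prr": 4.5,
    "chi2": 10.675381263616558,
    "ic": 1.7369655941662063,
    "ebgm": 10.0 / 3.0,
    "ebgm05": 0.8194075827579492,
}


class TestPointFormulas:
    def test_hand_table_frozen_values(self):
        t = pv.ContingencyTable(*HAND_TABLE)
        est, lo, hi = pv.ror(t)
        assert est == pytest.approx(HAND_EXPECTED["ror"], rel=1e-12)
        assert lo == pytest.approx(HAND_EXPECTED["ror_low"], rel=1e-12)
        p, chi2 = pv.prr(t)
        assert p == pytest.approx(HAND_EXPECTED["prr"], rel=1e-12)
        assert chi2 == pytest.approx(HAND_EXPECTED["chi2"], rel=1e-12)
        ic, _ = pv.bcpnn_ic(t)
        assert ic == pytest.approx(HAND_EXPECTED["ic"], rel=1e-12)
        e, e05 = pv.ebgm(t)
        assert e == pytest.approx(HAND_EXPECTED["ebgm"], rel=1e-12)
        assert e05 == pytest.approx(HAND_EXPECTED["ebgm05"], rel=1e-12)

    def test_independence_table(self):
        t = pv.ContingencyTable(10, 90, 100, 900)
        assert pv.ror(t)[0] == pytest.approx(1.0)
        assert pv.prr(t) == (pytest.approx(1.0), pytest.approx(0.0))
        ic, ic025 = pv.bcpnn_ic(t)
        assert ic == pytest.approx(0.0)
        assert ic025 < 0
        assert pv.ebgm(t)[0] == pytest.approx(1.0)

    def test_zero_cell_undefined_not_positive(self):
        t = pv.ContingencyTable(3, 0, 10, 80)
        est, lo, hi = pv.ror(t)
        assert np.isnan(est) and np.isnan(lo)
        r = pv.compute_signal("x", t)
        assert not r.ror_pos and not r.consensus

    def test_zero_a_prr_is_zero_never_positive(self):
        t = pv.ContingencyTable(0, 10, 10, 80)
        p, _ = pv.prr(t)
        assert p == 0.0
        assert not pv.compute_signal("x", t).prr_pos

    def test_matches_oracle_on_random_tables(self, rng):
        cells = random_tables(rng, 10_000)
        a, b, c, d = cells.T.astype(float)
        est, lo, hi = ror_arrays(a, b, c, d)
        p, chi2 = prr_arrays(a, b, c, d)
        raw, _, _ = ic_arrays(a, b, c, d)
        e, e05 = ebgm_arrays(a, b, c, d)
        for i in range(len(cells)):
            o = oracle_stats(*cells[i].astype(float))
            assert est[i] == pytest.approx(o["ror"], rel=1e-9)
            assert lo[i] == pytest.approx(o["ror_low"], rel=1e-9)
            assert hi[i] == pytest.approx(o["ror_high"], rel=1e-9)
            assert p[i] == pytest.approx(o["prr"], rel=1e-9)
            assert chi2[i] == pytest.approx(o["chi2"], rel=1e-9)
            assert raw[i] == pytest.approx(o["ic"], rel=1e-9)
            assert e[i] == pytest.approx(o["ebgm"], rel=1e-9)
            assert e05[i] == pytest.approx(o["ebgm05"], rel=1e-9)

    def test_library_cross_checks(self, rng):
        """Spot-check against scipy/statsmodels on a smaller batch."""
        import statsmodels.api as sm

        for cells in random_tables(rng, 200):
            a, b, c, d = (int(x) for x in cells)
            t22 = sm.stats.Table2x2(np.array([[a, b], [c, d]]))
            est, lo, hi = pv.ror(pv.ContingencyTable(a, b, c, d))
            assert est == pytest.approx(t22.oddsratio, rel=1e-9)
            # statsmodels uses the exact quantile 1.95996...; the published
            # formula prints 1.96, so agreement is to ~1e-4 relative
            ci = t22.oddsratio_confint(0.05)
            assert lo == pytest.approx(ci[0], rel=5e-4)
            assert hi == pytest.approx(ci[1], rel=5e-4)
            chi2_ref = sps.chi2_contingency([[a, b], [c, d]], correction=False)[0]
            assert pv.prr(pv.ContingencyTable(a, b, c, d))[1] == pytest.approx(
                chi2_ref, rel=1e-9
            )


class TestAlgebraicIdentities:
    def test_ebgm_is_two_to_raw_ic(self, rng):
        a, b, c, d = random_tables(rng, 2_000).T.astype(float)
        raw, _, _ = ic_arrays(a, b, c, d)
        e, _ = ebgm_arrays(a, b, c, d)
        np.testing.assert_allclose(e, 2.0 ** raw, rtol=1e-12)

    def test_prr_below_ror_when_ror_above_one(self, rng):
        a, b, c, d = random_tables(rng, 2_000).T.astype(float)
        ror_est, _, _ = ror_arrays(a, b, c, d)
        prr_est, _ = prr_arrays(a, b, c, d)
        m = ror_est > 1
        assert (prr_est[m] <= ror_est[m] + 1e-12).all()

    def test_transposition_symmetry(self, rng):
        a, b, c, d = random_tables(rng, 2_000).T.astype(float)
        fwd, _, _ = ror_arrays(a, b, c, d)
        rev, _, _ = ror_arrays(b, a, d, c)
        np.testing.assert_allclose(fwd, 1.0 / rev, rtol=1e-12)

    def test_monotone_in_a(self):
        b, c, d = 50.0, 40.0, 900.0
        ar = np.arange(1.0, 30.0)
        ror_est, _, _ = ror_arrays(ar, b, c, d)
        prr_est, _ = prr_arrays(ar, b, c, d)
        raw, _, _ = ic_arrays(ar, b, c, d)
        e, _ = ebgm_arrays(ar, b, c, d)
        for series in (ror_est, prr_est, raw, e):
            assert (np.diff(series) > 0).all()


class TestBcpnnPosterior:
    @staticmethod
    def mc_ic_quantile(a, b, c, d, n_draws=1_000_000, seed=0, q=2.5):
        """MC oracle: posterior of IC under the independent-Beta model with
        the same canonical priors the closed form uses."""
        n = a + b + c + d
        g11, a1, b1, al, be = 1.0, 1.0, 1.0, 2.0, 2.0
        gamma = g11 * (n + al) * (n + be) / ((a + b + a1) * (a + c + b1))
        r = np.random.default_rng(seed)
        p11 = r.beta(a + g11, n - a + gamma - g11, n_draws)
        p1 = r.beta(a + b + a1, n - a - b + al - a1, n_draws)
        p2 = r.beta(a + c + b1, n - a - c + be - b1, n_draws)
        return np.percentile(np.log2(p11 / (p1 * p2)), q)

    def test_closed_form_matches_mc_at_moderate_counts(self):
        _, _, ic025 = ic_arrays(50, 50, 100, 800)
        assert float(ic025) == pytest.approx(
            self.mc_ic_quantile(50, 50, 100, 800), abs=0.02
        )

    def test_closed_form_bounded_error_at_small_counts(self):
        """The moment (normal) approximation carries skew error when a is
        small; it stays within 0.15 bits of the exact posterior percentile."""
        _, _, ic025 = ic_arrays(5, 5, 10, 80)
        assert abs(float(ic025) - self.mc_ic_quantile(5, 5, 10, 80)) < 0.15


class TestCriteria:
    def test_strong_signal_quadruple_passes_all(self):
        # values of a published extreme signal (hypoinsulinaemia-style)
        flags = pv.evaluate_criteria(
            a=7, ror_ci_lower=85.321, prr_est=243.233, chi2=844.330,
            ic025=5.107, ebgm05=351.393,
        )
        assert all(flags.values())

    def test_a_below_three_fails_ror_gate(self):
        flags = pv.evaluate_criteria(
            a=2, ror_ci_lower=50.0, prr_est=100.0, chi2=500.0, ic025=3.0, ebgm05=40.0
        )
        assert not flags["ror_pos"] and not flags["consensus"]

    def test_independence_fails_all(self):
        r = pv.compute_signal("x", pv.ContingencyTable(10, 90, 100, 900))
        assert not (r.ror_pos or r.prr_pos or r.bcpnn_pos or r.ebgm_pos or r.consensus)

    def test_consensus_is_conjunction(self, rng):
        a, b, c, d = random_tables(rng, 500, low=1, high=200).T
        est, lo, hi = ror_arrays(a, b, c, d)
        p, chi2 = prr_arrays(a, b, c, d)
        _, _, ic025 = ic_arrays(a, b, c, d)
        e, e05 = ebgm_arrays(a, b, c, d)
        r, pr, bc, eb, cons = criteria_arrays(a, lo, p, chi2, ic025, e05)
        np.testing.assert_array_equal(cons, r & pr & bc & eb)


class TestDetectSignals:
    def test_planted_signal_flagged(self):
        cfg = pv.SyntheticConfig(
            n_cases=20_000, seed=17, exposure_prob=0.05,
            background_event_rate_range=(0.01, 0.01),
            planted_signals=[pv.PlantedSignal("EVT 0001", 8.0)],
        )
        raw, _ = pv.generate(cfg)
        raw = pv.normalize_drug_names(raw, pv.amlodipine_synonyms())
        cohort = pv.build_cohort(raw, "amlodipine")
        sig = pv.detect_signals(cohort)
        assert "evt 0001" in sig.index

    def test_tie_break_is_lexicographic(self):
        import pandas as pd

        n = 2_000
        reports = pd.DataFrame(
            {
                "sex": ["male"] * n,
                "age_years": [50.0] * n,
                "weight_kg": [70.0] * n,
                "country": ["US"] * n,
                "reporter": ["MD"] * n,
                "exposed": [True] * 100 + [False] * (n - 100),
                "primary_suspect": ["x"] * n,
            },
            index=pd.Index([f"r{i:04d}" for i in range(n)], name="case_id"),
        )
        ids = reports.index
        # identical tables for two terms -> identical ROR -> name order
        rows = []
        for term in ["zeta", "alpha"]:
            rows += [(i, term) for i in ids[:30]] + [(i, term) for i in ids[100:110]]
        rows += [(i, "filler") for i in ids]
        events = pd.DataFrame(rows, columns=["case_id", "term"])
        cohort = pv.AnalysisCohort(reports, events, "x")
        sig = pv.detect_signals(cohort)
        pair = [t for t in sig.index if t in ("alpha", "zeta")]
        assert pair == ["alpha", "zeta"]

    def test_empty_candidates_empty_result(self):
        import pandas as pd

        reports = pd.DataFrame(
            {
                "sex": ["male", "female"],
                "age_years": [50.0, 60.0],
                "weight_kg": [70.0, 60.0],
                "country": ["US", "US"],
                "reporter": ["MD", "MD"],
                "exposed": [True, False],
                "primary_suspect": ["x", "y"],
            },
            index=pd.Index(["r1", "r2"], name="case_id"),
        )
        events = pd.DataFrame({"case_id": ["r2"], "term": ["only nonexposed"]})
        cohort = pv.AnalysisCohort(reports, events, "x")
        assert len(pv.detect_signals(cohort)) == 0


class TestMgps:
    def test_shrinkage_pulls_small_counts_toward_prior(self):
        cfg = pv.SyntheticConfig(n_cases=10_000, seed=33, exposure_prob=0.1,
                                 background_event_rate_range=(0.005, 0.03))
        raw, _ = pv.generate(cfg)
        raw = pv.normalize_drug_names(raw, pv.amlodipine_synonyms())
        cohort = pv.build_cohort(raw, "amlodipine")
        tables = pv.event_tables(cohort)
        out = pv.mgps_ebgm(tables)
        assert np.isfinite(out["ebgm_shrunk"]).all()
        assert (out["ebgm05_shrunk"] <= out["ebgm_shrunk"] + 1e-9).all()
        raw_oe = pv.stats.ebgm_arrays(*(tables[k] for k in "abcd"))[0]
        small = tables["a"] <= 3
        # shrunk estimates sit closer to the null than the raw O/E ratio
        assert (
            np.abs(np.log(out.loc[small, "ebgm_shrunk"]))
            <= np.abs(np.log(raw_oe[small.to_numpy()])) + 1e-6
        ).mean() > 0.8
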