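"""Calibration studies run on the synthetic generator.

Two standing experiments exercise the full detection pipeline under known
truth:

* ``run_null_calibration`` — no signal planted anywhere (every multiplier
  1): measures the per-(replicate, event) false-positive rate of each
  method's criterion and of the four-method consensus.  The consensus rate
  is necessarily bounded by the strictest single method and should be well
  below 1% under these criteria.
* ``run_recovery`` — one event planted with reporting-odds multiplier 8
  (5% exposure, 1% background rate, 20,000 reports per replicate): measures
  how often the consensus flags the planted pair, how often the ROR interval
  covers the true multiplier, and how often the sex/age-adjusted logistic
  interval covers it.

Replicate seeds are drawn from one base seed, so both studies are exactly
reproducible.
"""

from __future__ import annotations

import numpy as np

from .io import amlodipine_synonyms, build_cohort, normalize_drug_names
from .regression import fit_adr_logistic
from .stats import signal_table
from .synth import FILLER_TERM, PlantedSignal, SyntheticConfig, generate, table2_like_config

TRUE_MULTIPLIER = 8.0
PLANTED_TERM = "EVT 0001"


def _analysis_cohort(cfg: SyntheticConfig):
    raw, ledger = generate(cfg)
    raw = normalize_drug_names(raw, amlodipine_synonyms())
    return build_cohort(raw, "amlodipine"), ledger


def _study_config(seed: int, planted=()) -> SyntheticConfig:
    return table2_like_config(
        n_cases=20_000,
        seed=seed,
        n_background_events=40,
        background_event_rate_range=(0.01, 0.01),
        exposure_prob=0.05,
        planted_signals=list(planted),
    )


def run_null_calibration(seed: int = 0, n_replicates: int = 200) -> dict:
    """False-positive rates per method under the global null (m = 1)."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, n_replicates)
    flags = {k: 0 for k in ("ror_pos", "prr_pos", "bcpnn_pos", "ebgm_pos", "consensus")}
    n_pairs = 0
    filler = FILLER_TERM.casefold()
    for s in rep_seeds:
        cohort, _ = _analysis_cohort(_study_config(int(s)))
        table = signal_table(cohort)
        table = table[table.index != filler]
        n_pairs += len(table)
        for k in flags:
            flags[k] += int(table[k].sum())
    rates = {k: v / n_pairs for k, v in flags.items()}
    rates["n_pairs"] = n_pairs
    rates["n_replicates"] = n_replicates
    return rates


def run_recovery(seed: int = 0, n_replicates: int = 100) -> dict:
    """Detection and interval coverage for a planted multiplier of 8."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, n_replicates)
    term = PLANTED_TERM.casefold()
    detected = ror_covered = logit_covered = logit_done = 0
    rors = []
    for s in rep_seeds:
        cfg = _study_config(int(s), planted=[PlantedSignal(PLANTED_TERM, TRUE_MULTIPLIER)])
        cohort, _ = _analysis_cohort(cfg)
        table = signal_table(cohort)
        row = table.loc[term]
        detected += int(row["consensus"])
        rors.append(float(row["ror"]))
        if np.isfinite(row["ror_low"]) and row["ror_low"] <= TRUE_MULTIPLIER <= row["ror_high"]:
            ror_covered += 1
        r = fit_adr_logistic(cohort, term)
        if r.converged:
            logit_done += 1
            if r.ci[0] <= TRUE_MULTIPLIER <= r.ci[1]:
                logit_covered += 1
    return {
        "n_replicates": n_replicates,
        "consensus_detected": detected,
        "ror_ci_covered": ror_covered,
        "adjusted_or_ci_covered": logit_covered,
        "adjusted_fits_converged": logit_done,
        "mean_ror": float(np.mean(rors)),
    }
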