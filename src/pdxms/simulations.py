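"""Calibration simulations: do the implemented intervals and searches
deliver what they promise?

These are the package's own operating-characteristic checks: Wald CI
coverage under the synthetic cohort generator, backward-AIC agreement with
exhaustive subset search, and BCa bootstrap coverage for the AUC of a
fixed score.  Each returns plain numbers so tests and reproduction scripts
can assert on them.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from pdxms.evaluate import bootstrap_auc
from pdxms.models import WALD_Z, fit_logistic, stepwise_backward_aic
from pdxms.synthdata import CohortGenSpec, generate_cohort


def wald_coverage_sim(n_sims: int = 500, n: int = 1000,
                      seed: int = 0) -> float:
    """Fraction of simulations whose 95% Wald CI covers the true Ki-67
    slope (log OR 1.05 per percentage point) in cohorts from the
    synthetic generator."""
    true_slope = math.log(1.05)
    beta = {"intercept": -2.0, "ki67": true_slope, "nac:yes": 1.0}
    seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2 ** 31)
    hits = 0
    for rep in range(n_sims):
        cohort = generate_cohort(CohortGenSpec(
            n=n, beta=beta, seed=int(seeds[rep])))
        fit = fit_logistic(cohort.table, "engrafted", ["ki67", "nac"])
        b, se = fit.coef_for("ki67")
        hits += b - WALD_Z * se <= true_slope <= b + WALD_Z * se
    return hits / n_sims


def stepwise_agreement_sim(n_sims: int = 100, n: int = 1000,
                           seed: int = 0) -> tuple[float, bool]:
    """Backward-AIC vs exhaustive-subset minimum-AIC model.

    Six standard-normal covariates, three with real effects (0.5, 0.4,
    0.3) and three pure noise.  Returns (fraction of simulations where the
    stepwise model equals the global AIC minimiser, whether
    AIC(final) <= AIC(full) held in every simulation).
    """
    variables = [f"x{i}" for i in range(1, 7)]
    effects = np.array([0.5, 0.4, 0.3, 0.0, 0.0, 0.0])
    rng_master = np.random.SeedSequence(seed)
    matches = 0
    aic_ok = True
    for child in rng_master.spawn(n_sims):
        rng = np.random.default_rng(child)
        X = rng.standard_normal((n, 6))
        p = 1.0 / (1.0 + np.exp(-(-1.0 + X @ effects)))
        frame = pd.DataFrame(X, columns=variables)
        frame["y"] = (rng.uniform(size=n) < p).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final, _ = stepwise_backward_aic(frame, "y", variables)
            full = fit_logistic(frame, "y", variables)
            best_aic, best_terms = np.inf, None
            for k in range(len(variables) + 1):
                for subset in itertools.combinations(variables, k):
                    cand = fit_logistic(frame, "y", list(subset))
                    if cand.aic < best_aic - 1e-10:
                        best_aic, best_terms = cand.aic, set(subset)
        matches += set(final.terms) == best_terms
        aic_ok &= final.aic <= full.aic + 1e-10
    return matches / n_sims, aic_ok


def bca_coverage_sim(n_sims: int = 200, n: int = 300,
                     prevalence: float = 0.17, shift: float = 1.0,
                     B: int = 1000, seed: int = 0) -> float:
    """Empirical coverage (in percent) of the 95% BCa interval for the AUC
    of a fixed score.

    Each simulated cohort draws labels Bernoulli(prevalence) and scores
    Normal(0,1) for failures, Normal(shift,1) for successes; the true AUC
    is Phi(shift/sqrt(2)).  The interval is the BCa bootstrap of the fixed
    (never refitted) score.
    """
    true_auc = stats.norm.cdf(shift / math.sqrt(2.0))
    hits = 0
    for k, child in enumerate(np.random.SeedSequence(seed).spawn(n_sims)):
        rng = np.random.default_rng(child)
        while True:
            y = (rng.uniform(size=n) < prevalence).astype(int)
            if 0 < y.sum() < n:
                break
        scores = rng.normal(loc=shift * y, scale=1.0)
        boot_seed = int(rng.integers(0, 2 ** 31))
        res = bootstrap_auc(scores, y, B=B, seed=boot_seed)
        hits += res.bca_low <= true_auc <= res.bca_high
    return 100.0 * hits / n_sims
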