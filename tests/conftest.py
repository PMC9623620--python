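"""Shared fixtures and independent analytic oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from scipy import integrate
from scipy import stats as sps

import ftpi_dta as fd

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")

BIG_N = 10_000
BIG_SEED = 1


@pytest.fixture(scope="session")
def big_cohort() -> fd.Dataset:
    """Large calibrated synthetic cohort used by recovery checks."""
    return fd.generate(fd.default_config(n_calves=BIG_N, seed=BIG_SEED))


@pytest.fixture(scope="session")
def big_derived(big_cohort) -> fd.Dataset:
    return fd.derive_fields(big_cohort)


@pytest.fixture(scope="session")
def study_cohort() -> fd.Dataset:
    """Study-sized cohort (258 calves before the age filter)."""
    return fd.generate(fd.default_config(n_calves=258, seed=BIG_SEED))


# ---------------------------------------------------------------------------
# independent oracles


def pairwise_auc_oracle(values, labels, orientation="lower_is_positive") -> float:
    """AUC as the exhaustive pairwise-comparison probability.

    Over every (positive, negative) pair, counts a concordant ordering as
    1 and a tie as 1/2, averaged -- independent of the trapezoid route.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos, neg = v[y], v[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p == q:
                total += 0.5
            elif (p < q) == (orientation == "lower_is_positive"):
                total += 1.0
    return total / (pos.size * neg.size)


def clopper_pearson_bisection_oracle(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial interval by bisection on the binomial tail probabilities."""
    from scipy.optimize import brentq

    alpha = 1 - conf
    lower = (
        0.0
        if k == 0
        else brentq(lambda p: sps.binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12)
    )
    upper = (
        1.0
        if k == n
        else brentq(lambda p: sps.binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12)
    )
    return lower, upper


def mcnemar_enumeration_oracle(b: int, c: int) -> float:
    """Two-sided exact McNemar p by exhaustive enumeration of Binomial(b+c, 1/2)."""
    n = b + c
    if n == 0:
        return 1.0
    pmf = [sps.binom.pmf(i, n, 0.5) for i in range(n + 1)]
    lower_tail = sum(pmf[: min(b, c) + 1])
    return min(1.0, 2.0 * lower_tail)


def glob_generating_model(cfg) -> tuple[float, float, float]:
    """(slope, intercept, noise_sd) of derived globulin vs IgG under the generator."""
    cal = cfg.calibrations["stp_ba"]
    slope = cal.slope - cfg.alb_igg_slope
    intercept = cal.intercept - cfg.alb_intercept
    noise_sd = np.sqrt(
        (1 - cfg.alb_shared_load) ** 2 * cal.noise_sd**2 + cfg.alb_noise_sd**2
    )
    return slope, intercept, float(noise_sd)


def analytic_operating_point(
    cfg, slope: float, intercept: float, noise_sd: float, cutoff: float, threshold: float = 10.0
) -> tuple[float, float]:
    """True (Se, Sp) of a linear-Gaussian test at a fixed cutoff.

    Integrates P(test <= cutoff | IgG = x) over the log-normal IgG density
    on either side of the FTPI threshold. Independent of the empirical
    ROC machinery.
    """
    mu, sigma = cfg.igg_log_mean, cfg.igg_log_sd

    def integrand(x):
        return sps.norm.cdf((cutoff - intercept - slope * x) / noise_sd) * sps.lognorm.pdf(
            x, s=sigma, scale=np.exp(mu)
        )

    p_pos = sps.lognorm.cdf(threshold, s=sigma, scale=np.exp(mu))
    call_pos_low, _ = integrate.quad(integrand, 0, threshold, limit=200)
    call_pos_high, _ = integrate.quad(integrand, threshold, np.inf, limit=200)
    se = call_pos_low / p_pos
    sp = 1.0 - call_pos_high / (1.0 - p_pos)
    return float(se), float(sp)


def analytic_youden_max(cfg, slope, intercept, noise_sd, threshold=10.0, grid=None):
    """(best cutoff, best J) of the generating model over a fine cutoff grid."""
    if grid is None:
        center = intercept + slope * threshold
        grid = np.linspace(center - 3 * noise_sd, center + 3 * noise_sd, 121)
    best_c, best_j = None, -np.inf
    for c in grid:
        se, sp = analytic_operating_point(cfg, slope, intercept, noise_sd, c, threshold)
        j = se + sp - 1
        if j > best_j:
            best_c, best_j = c, j
    return float(best_c), float(best_j)
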