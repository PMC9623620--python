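"""Inferential statistics used in diagnostic-test-accuracy studies.

Exact binomial (Clopper-Pearson) intervals, Cohen's unweighted kappa,
McNemar's exact paired test, Pearson correlation, two-group rank
comparison, sample-size planning for Se/Sp estimation, and intra-assay
coefficient of variation from replicate measurements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionTable",
    "SampleSizeSpec",
    "ReplicateSummary",
    "clopper_pearson",
    "cohen_kappa",
    "mcnemar",
    "pearson_r",
    "rank_sum_test",
    "sample_size_se_sp",
    "total_sample_size",
    "intra_assay_cv",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-classification of an index-test call against the reference.

    ``a``: index+ / reference+, ``b``: index+ / reference-,
    ``c``: index- / reference+, ``d``: index- / reference-.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("confusion table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_calls(cls, index_pos, ref_pos) -> "ConfusionTable":
        """Build from aligned boolean arrays of index-test and reference calls."""
        ip = np.asarray(index_pos, dtype=bool)
        rp = np.asarray(ref_pos, dtype=bool)
        if ip.shape != rp.shape:
            raise ValueError("index and reference call arrays must be aligned")
        return cls(
            a=int(np.sum(ip & rp)),
            b=int(np.sum(ip & ~rp)),
            c=int(np.sum(~ip & rp)),
            d=int(np.sum(~ip & ~rp)),
        )

    def transpose(self) -> "ConfusionTable":
        """Swap the roles of the two raters (b and c exchange)."""
        return ConfusionTable(a=self.a, b=self.c, c=self.b, d=self.d)


def clopper_pearson(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval.

    Inverts the binomial tail probabilities via beta quantiles. The lower
    bound is exactly 0 when ``successes == 0`` and the upper bound exactly 1
    when ``successes == n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must lie in [0, {n}], got {successes}")
    if not 0 < conf < 1:
        raise ValueError("conf must lie in (0, 1)")
    alpha = 1.0 - conf
    k = successes
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def cohen_kappa(table: ConfusionTable) -> float:
    """Cohen's unweighted kappa for a 2x2 agreement table.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement
    p_o = (a + d)/N and chance agreement
    p_e = [(a+b)(a+c) + (c+d)(b+d)] / N^2.
    """
    n = table.total
    p_o = (table.a + table.d) / n
    p_e = (
        (table.a + table.b) * (table.a + table.c)
        + (table.c + table.d) * (table.b + table.d)
    ) / (n * n)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("kappa undefined: chance agreement is 1 with imperfect observed agreement")
    return (p_o - p_e) / (1.0 - p_e)


def mcnemar(discordant_b: int, discordant_c: int) -> float:
    """Exact two-sided McNemar test on the discordant-pair counts.

    Tests b against Binomial(b + c, 1/2); the two-sided p-value doubles the
    smaller tail and is capped at 1. Returns 1 when there is no discordance.
    """
    b, c = int(discordant_b), int(discordant_c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        logger.info("McNemar: no discordant pairs, p = 1 by convention")
        return 1.0
    tail = float(sps.binom.cdf(min(b, c), n, 0.5))
    return min(1.0, 2.0 * tail)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-based p-value.

    Pairs with a missing value in either vector are dropped (complete-case).
    Requires at least 3 complete pairs and non-degenerate variance.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must be aligned")
    mask = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[mask], ya[mask]
    if xa.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {xa.size}")
    if np.ptp(xa) == 0:
        raise ValueError("x has zero variance")
    if np.ptp(ya) == 0:
        raise ValueError("y has zero variance")
    res = sps.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


def rank_sum_test(group1, group2) -> float:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum comparison of two groups.

    Uses the exact null distribution when both groups have <= 10
    observations and the pooled sample is tie-free; otherwise the normal
    approximation with midranks and tie correction.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    g1 = g1[np.isfinite(g1)]
    g2 = g2[np.isfinite(g2)]
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    tie_free = np.unique(pooled).size == pooled.size
    if g1.size <= 10 and g2.size <= 10 and tie_free:
        res = sps.mannwhitneyu(g1, g2, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            g1, g2, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.pvalue)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs for precision-based Se/Sp sample-size planning.

    ``expected_p``: anticipated sensitivity or specificity;
    ``precision``: absolute half-width of the confidence interval;
    ``conf``: confidence level; ``prevalence``: anticipated proportion of
    reference-positive subjects, used to scale the per-class size to a total.
    """

    expected_p: float = 0.80
    precision: float = 0.10
    conf: float = 0.95
    prevalence: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.expected_p < 1:
            raise ValueError("expected_p must lie in (0, 1)")
        if not 0 < self.precision < 1:
            raise ValueError("precision must lie in (0, 1)")
        if not 0.5 < self.conf < 1:
            raise ValueError("conf must lie in (0.5, 1)")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


def sample_size_se_sp(spec: SampleSizeSpec) -> int:
    """Minimum per-class sample size for estimating a proportion.

    n = ceil( z^2 p (1 - p) / d^2 ) with z the two-sided standard-normal
    quantile at the requested confidence level.
    """
    z = float(sps.norm.ppf(0.5 + spec.conf / 2))
    n = z * z * spec.expected_p * (1 - spec.expected_p) / (spec.precision**2)
    return int(math.ceil(n))


def total_sample_size(per_class_n: int, prevalence: float) -> int:
    """Total cohort size needed so the rarer class reaches ``per_class_n``."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if per_class_n < 1:
        raise ValueError("per_class_n must be >= 1")
    return int(math.ceil(per_class_n / prevalence))


@dataclass
class ReplicateSummary:
    """Per-sample replicate statistics and the overall CV summary."""

    per_sample: pd.DataFrame = field(repr=False)
    cv_min: float = float("nan")
    cv_max: float = float("nan")
    cv_mean: float = float("nan")


def intra_assay_cv(
    table: pd.DataFrame,
    sample_col: str = "sample_id",
    value_col: str = "value",
) -> ReplicateSummary:
    """Within-run coefficient of variation from replicate measurements.

    For each sample, CV = sample SD (n-1 denominator) / mean; the overall
    summary is the unweighted min, max and mean CV across samples. Each
    sample needs at least two replicates and a strictly positive mean.
    """
    if sample_col not in table.columns or value_col not in table.columns:
        raise ValueError(f"replicate table needs columns {sample_col!r} and {value_col!r}")
    rows = []
    for sid, grp in table.groupby(sample_col, sort=True):
        vals = pd.to_numeric(grp[value_col], errors="raise").to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise ValueError(f"sample {sid!r} has fewer than 2 replicates")
        mean = float(vals.mean())
        if mean <= 0:
            raise ValueError(f"sample {sid!r} has non-positive mean {mean}; CV undefined")
        sd = float(vals.std(ddof=1))
        rows.append({"sample_id": sid, "n_rep": vals.size, "mean": mean, "sd": sd, "cv": sd / mean})
    per_sample = pd.DataFrame(rows)
    cvs = per_sample["cv"].to_numpy()
    return ReplicateSummary(
        per_sample=per_sample,
        cv_min=float(cvs.min()),
        cv_max=float(cvs.max()),
        cv_mean=float(cvs.mean()),
    )
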