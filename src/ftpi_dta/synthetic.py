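"""Synthetic calf-cohort generator with calibrated biomarker structure.

Emulates a field study of passive-immunity screening in neonatal calves:
a reference serum IgG concentration (log-normal, moment-matched to a mean
of 16.26 g/L and SD of 8.91 g/L), five indirect tests correlated with IgG
at the published strengths (Pearson r = 0.73 %Brix, 0.74 STP_OP, 0.87
STP_BA, 0.89 GLOB, 0.67 GGT), herd clustering with 1-6 calves per herd,
an age distribution concentrated on 2-6 days with a few out-of-window and
missing-age calves, a strong multiplicative age effect on GGT, and
per-test completely-at-random missingness.

Refractometer and analyzer protein measures are linear-Gaussian in IgG
(the Pearson targets are linear-scale quantities, and a linear
calibration hits them exactly in expectation). Albumin carries a small
IgG loading plus a loading on the STP_BA measurement noise, solved in
closed form so that both corr(ALB, STP_BA) = 0.60 and the derived-globulin
correlation corr(GLOB, IgG) = 0.89 hold simultaneously. GGT is modelled
jointly log-normal with IgG (log-linear link) because its marginal is
strongly right-skewed and strictly positive; the log-scale slope and
noise are solved in closed form from the target overall SD and Pearson
correlation using log-normal moment algebra.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .data import COLUMNS, Dataset

__all__ = [
    "LinearCalibration",
    "IgGMixture",
    "SyntheticConfig",
    "linear_calibration",
    "default_config",
    "generate",
    "generate_replicates",
    "STUDY_MARGINALS",
    "IGG_CORR_TARGETS",
]

#: target marginal (mean, SD) of each measured variable, in its own units
STUDY_MARGINALS: Dict[str, tuple[float, float]] = {
    "igg_rid": (16.26, 8.91),
    "stp_ba": (59.21, 8.91),
    "alb": (22.24, 3.21),
    "brix": (8.83, 1.11),
    "stp_op": (57.36, 10.11),
    "ggt": (561.38, 338.90),
}

#: target Pearson correlation of each index test with reference IgG
IGG_CORR_TARGETS: Dict[str, float] = {
    "brix": 0.73,
    "stp_op": 0.74,
    "stp_ba": 0.87,
    "glob": 0.89,
    "ggt": 0.67,
}

#: target correlation between albumin and analyzer total protein
ALB_STP_CORR_TARGET = 0.60

#: GGT group means (IU/L) by age group, and the stratum definitions
GGT_GROUP_MEANS = {"2-3": 640.46, "4-6": 456.56}

#: cohort age-group composition (shares of the sampled cohort)
AGE_GROUP_SHARES = {
    "0-1": 3 / 258,
    "2-3": 132 / 258,
    "4-6": 113 / 258,
    ">6": 3 / 258,
    "missing": 7 / 258,
}

#: herd-size distribution on {1,...,6} calves per herd (median 3)
HERD_SIZE_PROBS = (0.20, 0.25, 0.26, 0.14, 0.09, 0.06)

#: default per-test missing-data rates (fractions of the analyzed cohort)
MISSINGNESS_DEFAULT = {
    "igg_rid": 0.0,
    "stp_ba": 1 / 245,
    "alb": 1 / 245,
    "brix": 45 / 245,
    "stp_op": 4 / 245,
    "ggt": 45 / 245,
}


@dataclass(frozen=True)
class LinearCalibration:
    """Linear-Gaussian link of an index test to IgG: intercept + slope*IgG + noise."""

    slope: float
    intercept: float
    noise_sd: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.noise_sd) or self.noise_sd < 0:
            raise ValueError(f"noise_sd must be finite and >= 0, got {self.noise_sd}")


def linear_calibration(
    mean_test: float, sd_test: float, r: float, mean_igg: float, sd_igg: float
) -> LinearCalibration:
    """Solve slope/intercept/noise so the test hits its marginal moments and r.

    slope = r * SD_test / SD_IgG, intercept matches the means, and
    noise_sd = SD_test * sqrt(1 - r^2). Raises for infeasible |r| > 1.
    """
    if abs(r) > 1:
        raise ValueError(f"infeasible correlation target r={r}: |r| must be <= 1")
    slope = r * sd_test / sd_igg
    return LinearCalibration(
        slope=slope,
        intercept=mean_test - slope * mean_igg,
        noise_sd=sd_test * math.sqrt(1.0 - r * r),
    )


@dataclass(frozen=True)
class IgGMixture:
    """Optional two-component log-normal IgG marginal (low/high subpopulations)."""

    weight_low: float
    low_mean: float
    low_sd: float
    high_mean: float
    high_sd: float

    def __post_init__(self) -> None:
        if not 0 < self.weight_low < 1:
            raise ValueError("weight_low must lie in (0, 1)")
        for v in (self.low_mean, self.low_sd, self.high_mean, self.high_sd):
            if v <= 0:
                raise ValueError("mixture component moments must be positive")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a log-normal moment-matched to (mean, sd)."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass
class SyntheticConfig:
    """All generator parameters; :func:`default_config` fills the calibrated defaults.

    ``herd_sd`` is the SD of an additive herd effect on the log-IgG scale
    (0 disables clustering beyond shared herd labels). ``ggt_age_effect``
    is the multiplicative GGT factor applied to calves aged 3 days or
    younger. ``age_group_probs`` are probabilities over the groups
    {0-1, 2-3, 4-6, >6, missing}; "missing" calves have a true age in 2-6
    days but a missing age record.
    """

    n_calves: int = 258
    n_herds: int = 93
    herd_sd: float = 0.0
    igg_log_mean: float = 0.0
    igg_log_sd: float = 1.0
    igg_mixture: Optional[IgGMixture] = None
    calibrations: Dict[str, LinearCalibration] = field(default_factory=dict)
    alb_intercept: float = 0.0
    alb_igg_slope: float = 0.0
    alb_shared_load: float = 0.0
    alb_noise_sd: float = 1.0
    ggt_log_intercept: float = 0.0
    ggt_log_slope: float = 0.0
    ggt_log_noise_sd: float = 0.0
    ggt_age_effect: float = 1.0
    age_group_probs: Dict[str, float] = field(default_factory=lambda: dict(AGE_GROUP_SHARES))
    herd_size_probs: Sequence[float] = HERD_SIZE_PROBS
    missingness_rates: Dict[str, float] = field(default_factory=lambda: dict(MISSINGNESS_DEFAULT))
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_calves < 1:
            raise ValueError("n_calves must be >= 1")
        if not 1 <= self.n_herds <= self.n_calves:
            raise ValueError("need 1 <= n_herds <= n_calves")
        for name, sd in (
            ("herd_sd", self.herd_sd),
            ("igg_log_sd", self.igg_log_sd),
            ("alb_noise_sd", self.alb_noise_sd),
            ("ggt_log_noise_sd", self.ggt_log_noise_sd),
        ):
            if sd < 0 or not math.isfinite(sd):
                raise ValueError(f"{name} must be finite and >= 0")
        psum = sum(self.age_group_probs.values())
        if abs(psum - 1.0) > 1e-6:
            raise ValueError(f"age_group_probs must sum to 1, got {psum}")
        if abs(sum(self.herd_size_probs) - 1.0) > 1e-6:
            raise ValueError("herd_size_probs must sum to 1")
        for test, rate in self.missingness_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness rate for {test!r} must lie in [0, 1]")
        if self.ggt_age_effect <= 0:
            raise ValueError("ggt_age_effect must be positive")

    # -- flat-file (YAML) round-trip ------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["herd_size_probs"] = list(self.herd_size_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if d.get("igg_mixture") is not None:
            d["igg_mixture"] = IgGMixture(**d["igg_mixture"])
        d["calibrations"] = {
            k: LinearCalibration(**v) if isinstance(v, dict) else v
            for k, v in d.get("calibrations", {}).items()
        }
        d["herd_size_probs"] = tuple(d.get("herd_size_probs", HERD_SIZE_PROBS))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_config(n_calves: int = 258, seed: int = 0, mixture: bool = False) -> SyntheticConfig:
    """Generator configuration calibrated to the study cohort's structure.

    All derived parameters are solved in closed form from the marginal
    targets and correlation targets; nothing is fitted by simulation.
    """
    m_igg, sd_igg = STUDY_MARGINALS["igg_rid"]
    mu, sigma = _lognormal_params(m_igg, sd_igg)
    var_igg = sd_igg**2

    calibrations = {
        test: linear_calibration(*STUDY_MARGINALS[test], IGG_CORR_TARGETS[test], m_igg, sd_igg)
        for test in ("brix", "stp_op", "stp_ba")
    }

    # Albumin: ALB = intercept + lambda*IgG + gamma*e_stp + e_alb, with
    # (lambda, gamma) solved so corr(ALB, STP_BA) and corr(GLOB, IgG) hit
    # their targets given the STP_BA calibration above. Var(GLOB) is then
    # fully determined by the ALB/STP marginals and their correlation.
    m_alb, sd_alb = STUDY_MARGINALS["alb"]
    b_stp = calibrations["stp_ba"].slope
    var_e1 = calibrations["stp_ba"].noise_sd ** 2
    cov_as = ALB_STP_CORR_TARGET * sd_alb * sd_igg  # note SD(STP_BA) == SD(IgG) here
    var_glob = sd_igg**2 + sd_alb**2 - 2 * cov_as
    lam = b_stp - IGG_CORR_TARGETS["glob"] * math.sqrt(var_glob) / sd_igg
    gam = (cov_as - b_stp * lam * var_igg) / var_e1
    var_e_alb = sd_alb**2 - lam**2 * var_igg - gam**2 * var_e1
    if var_e_alb < 0:
        raise ValueError("infeasible albumin correlation targets (negative residual variance)")

    # GGT: log(GGT) = alpha_age + beta*log(IgG) + noise, with a
    # multiplicative factor f on the natural scale for the 2-3 d group.
    # beta and the log noise solve the overall SD and Pearson-r targets
    # through log-normal moment algebra; alpha anchors the 4-6 d group mean.
    m_ggt, sd_ggt = STUDY_MARGINALS["ggt"]
    r_ggt = IGG_CORR_TARGETS["ggt"]
    p23, p46 = AGE_GROUP_SHARES["2-3"], AGE_GROUP_SHARES["4-6"]
    p_young = p23 / (p23 + p46)
    f = GGT_GROUP_MEANS["2-3"] / GGT_GROUP_MEANS["4-6"]
    base_mean = GGT_GROUP_MEANS["4-6"]
    ef = p_young * f + (1 - p_young)
    ef2 = p_young * f**2 + (1 - p_young)
    exp_s2 = (sd_ggt**2 / base_mean**2 + ef**2) / ef2
    if exp_s2 <= 1:
        raise ValueError("infeasible GGT variance target")
    s2 = math.log(exp_s2)
    exp_bs = 1.0 + r_ggt * sd_ggt * sd_igg / (ef * base_mean * m_igg)
    beta = math.log(exp_bs) / sigma**2
    tau2 = s2 - beta**2 * sigma**2
    if tau2 < 0:
        raise ValueError("infeasible GGT correlation target (negative log-scale residual variance)")
    alpha = math.log(base_mean) - s2 / 2.0 - beta * mu

    igg_mixture = None
    if mixture:
        igg_mixture = _default_mixture(m_igg, sd_igg)

    return SyntheticConfig(
        n_calves=n_calves,
        igg_log_mean=mu,
        igg_log_sd=sigma,
        igg_mixture=igg_mixture,
        calibrations=calibrations,
        alb_intercept=m_alb - lam * m_igg,
        alb_igg_slope=lam,
        alb_shared_load=gam,
        alb_noise_sd=math.sqrt(var_e_alb),
        ggt_log_intercept=alpha,
        ggt_log_slope=beta,
        ggt_log_noise_sd=math.sqrt(tau2),
        ggt_age_effect=f,
        seed=seed,
    )


def _default_mixture(m_igg: float, sd_igg: float, weight_low: float = 0.31, low_mean: float = 7.0, low_sd: float = 2.0) -> IgGMixture:
    """Two-component IgG marginal preserving the overall mean and SD.

    The low (FTPI-prone) component is fixed; the high component's moments
    are solved so the mixture's overall mean and SD match the targets.
    Gives quartiles closer to the printed ones than the single log-normal.
    """
    w = weight_low
    high_mean = (m_igg - w * low_mean) / (1 - w)
    between = w * low_mean**2 + (1 - w) * high_mean**2 - m_igg**2
    high_var = (sd_igg**2 - between - w * low_sd**2) / (1 - w)
    if high_var <= 0:
        raise ValueError("infeasible IgG mixture targets")
    return IgGMixture(w, low_mean, low_sd, high_mean, math.sqrt(high_var))


def _draw_herds(rng: np.random.Generator, n: int, size_probs: Sequence[float]) -> np.ndarray:
    """Assign calves to herds with 1-6 calves per herd (iid categorical sizes)."""
    sizes = []
    total = 0
    while total < n:
        k = int(rng.choice(np.arange(1, 7), p=np.asarray(size_probs)))
        sizes.append(k)
        total += k
    sizes[-1] -= total - n  # trim the last herd to fit exactly
    labels = np.repeat(np.arange(len(sizes)), sizes)
    return labels


def _draw_ages(rng: np.random.Generator, n: int, probs: Dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    """Draw (true_age_days, recorded_missing_mask) from the group probabilities."""
    groups = list(probs.keys())
    p = np.asarray([probs[g] for g in groups], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(groups), size=n, p=p)
    group = np.asarray(groups, dtype=object)[idx]
    true_age = np.empty(n, dtype=int)
    for g, days in (("0-1", [0, 1]), ("2-3", [2, 3]), ("4-6", [4, 5, 6]), (">6", [7, 8]), ("missing", [2, 3, 4, 5, 6])):
        mask = group == g
        if mask.any():
            true_age[mask] = rng.choice(days, size=int(mask.sum()))
    return true_age, group == "missing"


def _draw_igg(rng: np.random.Generator, n: int, cfg: SyntheticConfig, herd_labels: np.ndarray) -> np.ndarray:
    if cfg.igg_mixture is None:
        log_igg = rng.normal(cfg.igg_log_mean, cfg.igg_log_sd, n)
    else:
        mx = cfg.igg_mixture
        low = rng.random(n) < mx.weight_low
        mu_l, s_l = _lognormal_params(mx.low_mean, mx.low_sd)
        mu_h, s_h = _lognormal_params(mx.high_mean, mx.high_sd)
        log_igg = np.where(low, rng.normal(mu_l, s_l, n), rng.normal(mu_h, s_h, n))
    if cfg.herd_sd > 0:
        effects = rng.normal(0.0, cfg.herd_sd, herd_labels.max() + 1)
        log_igg = log_igg + effects[herd_labels]
    return np.exp(log_igg)


def generate(cfg: SyntheticConfig) -> Dataset:
    """Generate a synthetic cohort; deterministic given ``cfg.seed``.

    Only STP_BA and ALB are emitted (globulin is a derived field); the
    albumin construction guarantees the derived GLOB-IgG correlation
    target. Measurements are floored at zero (a vanishing-probability
    guard for the Gaussian links).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_calves

    herd_labels = _draw_herds(rng, n, cfg.herd_size_probs)
    true_age, age_missing = _draw_ages(rng, n, cfg.age_group_probs)
    igg = _draw_igg(rng, n, cfg, herd_labels)

    cal_stp = cfg.calibrations["stp_ba"]
    e_stp = rng.normal(0.0, cal_stp.noise_sd, n)
    stp_ba = cal_stp.intercept + cal_stp.slope * igg + e_stp

    cal_brix = cfg.calibrations["brix"]
    brix = cal_brix.intercept + cal_brix.slope * igg + rng.normal(0.0, cal_brix.noise_sd, n)
    cal_op = cfg.calibrations["stp_op"]
    stp_op = cal_op.intercept + cal_op.slope * igg + rng.normal(0.0, cal_op.noise_sd, n)

    alb = (
        cfg.alb_intercept
        + cfg.alb_igg_slope * igg
        + cfg.alb_shared_load * e_stp
        + rng.normal(0.0, cfg.alb_noise_sd, n)
    )

    log_ggt = cfg.ggt_log_intercept + cfg.ggt_log_slope * np.log(igg) + rng.normal(
        0.0, cfg.ggt_log_noise_sd, n
    )
    ggt = np.exp(log_ggt) * np.where(true_age <= 3, cfg.ggt_age_effect, 1.0)

    df = pd.DataFrame(
        {
            "herd_id": [f"H{h + 1:03d}" for h in herd_labels],
            "calf_id": [f"C{i + 1:04d}" for i in range(n)],
            "age_days": pd.array(np.where(age_missing, -1, true_age), dtype="Int64"),
            "igg_rid": igg,
            "stp_ba": np.maximum(stp_ba, 0.0),
            "alb": np.maximum(alb, 0.0),
            "brix": np.clip(brix, 1e-6, 29.999),
            "stp_op": np.maximum(stp_op, 0.0),
            "ggt": ggt,
        }
    )
    df.loc[np.asarray(age_missing), "age_days"] = pd.NA

    for test, rate in cfg.missingness_rates.items():
        if rate > 0:
            drop = rng.random(n) < rate
            df.loc[drop, test] = np.nan

    return Dataset(
        df[list(COLUMNS)],
        provenance=f"synthetic cohort (n={n}, seed={cfg.seed})",
    )


def generate_replicates(
    true_values: Sequence[float], cv: float, n_rep: int, seed: int = 0
) -> pd.DataFrame:
    """Replicate measurements with multiplicative Gaussian noise of the given CV.

    Returns a long table with columns sample_id, true_value, replicate,
    value -- the input shape expected by the intra-assay CV estimator.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for i, tv in enumerate(true_values):
        noise = rng.normal(0.0, cv, n_rep)
        for j in range(n_rep):
            rows.append(
                {
                    "sample_id": f"S{i + 1}",
                    "true_value": float(tv),
                    "replicate": j + 1,
                    "value": float(tv * (1.0 + noise[j])),
                }
            )
    return pd.DataFrame(rows)
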