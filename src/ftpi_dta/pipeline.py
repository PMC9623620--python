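"""End-to-end FTPI diagnostic-accuracy analysis on a calf cohort.

Reproduces the shape of a parallel test-evaluation study on any
conforming dataset: age-window inclusion, derived fields, descriptive
statistics, test-vs-reference correlations, per-test ROC analysis with
Youden-optimal cutoffs and agreement (kappa), specificity/sensitivity
constrained decision thresholds with a grey zone, a borderline-exclusion
sensitivity analysis, and paired McNemar comparisons between tests.

GGT is additionally analysed within age strata (2-3 and 4-6 days)
because its serum activity declines steeply over the first week of life.
Every test uses its own complete cases.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    AGE_WINDOW_DEFAULT,
    FTPI_THRESHOLD_DEFAULT,
    INDEX_TESTS,
    Dataset,
    apply_age_filter,
    derive_fields,
    describe,
)
from .roc import build_roc, constrained_cutoffs, performance_at, select_cutoff_youden
from .stats import mcnemar, pearson_r

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis", "sensitivity_borderline", "compare_tests_paired", "analysis_units"]

#: default GGT age strata: (label, inclusive age range in days)
GGT_STRATA_DEFAULT = (("2-3", (2, 3)), ("4-6", (4, 6)))


@dataclass
class AnalysisConfig:
    """Analysis constants: thresholds, confidence level, strata and options."""

    ftpi_threshold: float = FTPI_THRESHOLD_DEFAULT
    conf_level: float = 0.95
    constrained_sp: float = 0.95
    constrained_se: float = 0.95
    age_window: Tuple[int, int] = AGE_WINDOW_DEFAULT
    ggt_strata: Sequence[Tuple[str, Tuple[int, int]]] = GGT_STRATA_DEFAULT
    borderline_exclusion: Optional[Tuple[float, float]] = None
    fixed_cutoffs: Optional[Dict[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ftpi_threshold <= 0:
            raise ValueError("ftpi_threshold must be positive")
        if not 0.5 < self.conf_level < 1:
            raise ValueError("conf_level must lie in (0.5, 1)")
        for name in ("constrained_sp", "constrained_se"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.borderline_exclusion is not None:
            lo, hi = self.borderline_exclusion
            if not lo <= self.ftpi_threshold <= hi:
                raise ValueError("borderline_exclusion interval must contain ftpi_threshold")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_window"] = list(self.age_window)
        d["ggt_strata"] = [[label, list(rng)] for label, rng in self.ggt_strata]
        if self.borderline_exclusion is not None:
            d["borderline_exclusion"] = list(self.borderline_exclusion)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "age_window" in d:
            d["age_window"] = tuple(d["age_window"])
        if "ggt_strata" in d:
            d["ggt_strata"] = tuple((label, tuple(rng)) for label, rng in d["ggt_strata"])
        if d.get("borderline_exclusion") is not None:
            d["borderline_exclusion"] = tuple(d["borderline_exclusion"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def analysis_units(cfg: AnalysisConfig) -> list[tuple[str, str, Optional[Tuple[int, int]]]]:
    """(unit label, test column, optional age restriction) for each report row."""
    units: list[tuple[str, str, Optional[Tuple[int, int]]]] = [
        (t, t, None) for t in INDEX_TESTS
    ]
    for label, rng in cfg.ggt_strata:
        units.append((f"ggt[{label}]", "ggt", tuple(rng)))
    return units


def _unit_values(df: pd.DataFrame, test: str, age_range: Optional[Tuple[int, int]]):
    """Complete-case values and FTPI labels for one analysis unit."""
    sub = df
    if age_range is not None:
        age = sub["age_days"]
        sub = sub[age.notna() & (age >= age_range[0]) & (age <= age_range[1])]
    mask = sub[test].notna() & sub["ftpi_status"].notna()
    sub = sub[mask]
    return sub[test].to_numpy(dtype=float), sub["ftpi_status"].to_numpy(dtype=bool)


@dataclass
class AnalysisReport:
    """All result blocks of one analysis run; serializable to JSON/CSV."""

    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    performance: pd.DataFrame
    constrained: pd.DataFrame
    prevalence: float
    n_pos: int
    n_neg: int
    sensitivity: Optional[dict] = None
    fixed_cutoff_performance: Optional[pd.DataFrame] = None
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "descriptives": self.descriptives.reset_index().to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "performance": self.performance.to_dict(orient="records"),
            "constrained": self.constrained.to_dict(orient="records"),
            "prevalence": self.prevalence,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "sensitivity": self.sensitivity,
            "fixed_cutoff_performance": (
                None
                if self.fixed_cutoff_performance is None
                else self.fixed_cutoff_performance.to_dict(orient="records")
            ),
            "metadata": self.metadata,
        }
        return d

    def save(self, outdir: str | Path) -> Path:
        """Write report.json plus CSV analogues of the result tables."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True))
        self.descriptives.to_csv(outdir / "descriptives.csv")
        self.correlations.to_csv(outdir / "correlations.csv", index=False)
        self.performance.to_csv(outdir / "performance.csv", index=False)
        self.constrained.to_csv(outdir / "constrained_cutoffs.csv", index=False)
        return report_path


def _prepare(ds: Dataset, cfg: AnalysisConfig) -> Dataset:
    ds = apply_age_filter(ds, *cfg.age_window)
    ds = derive_fields(ds, cfg.ftpi_threshold)
    labels = ds.df["ftpi_status"]
    n_pos = int((labels == True).sum())  # noqa: E712 (nullable boolean)
    n_neg = int((labels == False).sum())  # noqa: E712
    if n_pos < 1 or n_neg < 1:
        raise ValueError(
            f"cannot analyse: reference classes after filtering are {n_pos} FTPI+ / "
            f"{n_neg} FTPI- (need at least one of each)"
        )
    return ds


def _performance_tables(df: pd.DataFrame, cfg: AnalysisConfig):
    perf_rows, constrained_rows = [], []
    cutoffs: Dict[str, float] = {}
    for label, test, age_range in analysis_units(cfg):
        values, labels = _unit_values(df, test, age_range)
        logger.info("unit %s: n=%d (%d FTPI+)", label, len(values), int(labels.sum()))
        roc = build_roc(values, labels, test_name=label)
        perf = select_cutoff_youden(roc, conf=cfg.conf_level)
        cutoffs[label] = perf.cutoff
        perf_rows.append(perf.to_dict())
        rule_in, rule_out = constrained_cutoffs(
            roc, min_sp=cfg.constrained_sp, min_se=cfg.constrained_se, conf=cfg.conf_level
        )
        constrained_rows.append(
            {
                "test": label,
                "rule_in_cutoff": None if rule_in is None else rule_in.cutoff,
                "rule_in_se": None if rule_in is None else rule_in.se,
                "rule_in_sp": None if rule_in is None else rule_in.sp,
                "rule_out_cutoff": None if rule_out is None else rule_out.cutoff,
                "rule_out_se": None if rule_out is None else rule_out.se,
                "rule_out_sp": None if rule_out is None else rule_out.sp,
            }
        )
    return pd.DataFrame(perf_rows), pd.DataFrame(constrained_rows), cutoffs


def _evaluate_at_cutoffs(df: pd.DataFrame, cutoffs: Dict[str, float], cfg: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for label, test, age_range in analysis_units(cfg):
        if label not in cutoffs:
            continue
        values, labels = _unit_values(df, test, age_range)
        perf = performance_at(values, labels, cutoffs[label], test_name=label, conf=cfg.conf_level)
        rows.append(perf.to_dict())
    return pd.DataFrame(rows)


def run_analysis(ds: Dataset, cfg: Optional[AnalysisConfig] = None) -> AnalysisReport:
    """Run the full analysis and return the assembled report.

    The report is reproducible bit-for-bit from the same dataset and
    configuration (no resampling is involved).
    """
    cfg = cfg or AnalysisConfig()
    ds = _prepare(ds, cfg)
    df = ds.df

    desc_vars = ["igg_rid", "stp_ba", "alb", "brix", "stp_op", "glob", "ggt"]
    descriptives = describe(ds, desc_vars)
    strata_rows = []
    for label, rng in cfg.ggt_strata:
        age = df["age_days"]
        sub = Dataset(df[age.notna() & (age >= rng[0]) & (age <= rng[1])], provenance="stratum")
        row = describe(sub, ["ggt"]).iloc[0]
        strata_rows.append(row.rename(f"ggt[{label}]"))
    descriptives = pd.concat([descriptives, pd.DataFrame(strata_rows)])
    descriptives.index.name = "variable"

    corr_rows = []
    for test in INDEX_TESTS:
        mask = df[test].notna() & df["igg_rid"].notna()
        r, p = pearson_r(df.loc[mask, test], df.loc[mask, "igg_rid"])
        corr_rows.append({"test": test, "n": int(mask.sum()), "r": r, "p_value": p})
    correlations = pd.DataFrame(corr_rows)

    performance, constrained, cutoffs = _performance_tables(df, cfg)

    labels = df["ftpi_status"]
    n_pos = int((labels == True).sum())  # noqa: E712
    n_neg = int((labels == False).sum())  # noqa: E712

    sensitivity = None
    if cfg.borderline_exclusion is not None:
        sensitivity = _sensitivity_block(df, cfg, cfg.borderline_exclusion, cutoffs, performance)

    fixed = None
    if cfg.fixed_cutoffs:
        fixed = _evaluate_at_cutoffs(df, dict(cfg.fixed_cutoffs), cfg)

    report = AnalysisReport(
        descriptives=descriptives,
        correlations=correlations,
        performance=performance,
        constrained=constrained,
        prevalence=n_pos / (n_pos + n_neg),
        n_pos=n_pos,
        n_neg=n_neg,
        sensitivity=sensitivity,
        fixed_cutoff_performance=fixed,
        metadata={
            "config": cfg.to_dict(),
            "provenance": ds.provenance,
            "n_records": len(df),
            "software_version": __version__,
        },
    )
    return report


def _sensitivity_block(
    df: pd.DataFrame,
    cfg: AnalysisConfig,
    interval: Tuple[float, float],
    frozen_cutoffs: Dict[str, float],
    main_performance: pd.DataFrame,
) -> dict:
    """Re-evaluate the frozen optimal cutoffs after excluding borderline calves.

    Calves with reference IgG inside the closed interval are discarded;
    the main run's cutoffs are kept fixed (not re-optimized) and the
    Se/Sp deltas against the main run are reported.
    """
    lo, hi = interval
    igg = df["igg_rid"]
    excluded = igg.notna() & (igg >= lo) & (igg <= hi)
    reduced = df[~excluded]
    labels = reduced["ftpi_status"]
    n_pos = int((labels == True).sum())  # noqa: E712
    n_neg = int((labels == False).sum())  # noqa: E712
    if n_pos < 1 or n_neg < 1:
        raise ValueError(
            f"borderline exclusion [{lo}, {hi}] empties a reference class "
            f"({n_pos} FTPI+ / {n_neg} FTPI- remain)"
        )
    perf = _evaluate_at_cutoffs(reduced, frozen_cutoffs, cfg)
    main = main_performance.set_index("test")
    perf = perf.set_index("test")
    deltas = {
        test: {
            "delta_se": float(perf.loc[test, "se"] - main.loc[test, "se"]),
            "delta_sp": float(perf.loc[test, "sp"] - main.loc[test, "sp"]),
        }
        for test in perf.index
    }
    return {
        "interval": [lo, hi],
        "n_excluded": int(excluded.sum()),
        "performance": perf.reset_index().to_dict(orient="records"),
        "deltas": deltas,
    }


def sensitivity_borderline(
    ds: Dataset, cfg: AnalysisConfig, interval: Tuple[float, float]
) -> dict:
    """Standalone borderline-exclusion sensitivity analysis.

    Runs the main analysis to obtain the Youden-optimal cutoffs, then
    re-evaluates those frozen cutoffs on the cohort with borderline-IgG
    calves (reference value inside the closed interval) removed.
    """
    lo, hi = interval
    if not lo <= cfg.ftpi_threshold <= hi:
        raise ValueError("interval must straddle the FTPI threshold")
    ds = _prepare(ds, cfg)
    performance, _, cutoffs = _performance_tables(ds.df, cfg)
    return _sensitivity_block(ds.df, cfg, interval, cutoffs, performance)


def compare_tests_paired(
    ds: Dataset,
    cfg: AnalysisConfig,
    test_a: str,
    test_b: str,
    cutoffs: Optional[Dict[str, float]] = None,
) -> dict:
    """McNemar comparison of two tests on their overlapping complete cases.

    Each test dichotomizes at its own Youden-optimal cutoff from the main
    analysis unless explicit ``cutoffs`` are given. Within FTPI+ calves
    the discordant call counts test the sensitivity difference; within
    FTPI- calves, the specificity difference.
    """
    for t in (test_a, test_b):
        if t not in INDEX_TESTS:
            raise ValueError(f"unknown test {t!r}; choose from {INDEX_TESTS}")
    ds = _prepare(ds, cfg)
    df = ds.df
    if cutoffs is None:
        _, _, youden = _performance_tables(df, cfg)
        cutoffs = {test_a: youden[test_a], test_b: youden[test_b]}

    mask = df[test_a].notna() & df[test_b].notna() & df["ftpi_status"].notna()
    overlap = df[mask]
    if overlap.empty:
        raise ValueError(f"no calves have both {test_a!r} and {test_b!r} measured")
    call_a = overlap[test_a].to_numpy(dtype=float) <= cutoffs[test_a]
    call_b = overlap[test_b].to_numpy(dtype=float) <= cutoffs[test_b]
    ref = overlap["ftpi_status"].to_numpy(dtype=bool)

    result = {"test_a": test_a, "test_b": test_b, "cutoffs": {k: float(v) for k, v in cutoffs.items()}, "n_overlap": int(mask.sum())}
    for side, in_class in (("se", ref), ("sp", ~ref)):
        b = int(np.sum(call_a[in_class] & ~call_b[in_class]))
        c = int(np.sum(~call_a[in_class] & call_b[in_class]))
        result[f"{side}_discordant"] = [b, c]
        result[f"{side}_p_value"] = mcnemar(b, c)
        logger.info(
            "%s comparison %s vs %s: discordant %d/%d, p=%.4f",
            side, test_a, test_b, b, c, result[f"{side}_p_value"],
        )
    return result
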