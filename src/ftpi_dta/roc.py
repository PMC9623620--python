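"""Empirical ROC curves, AUC, and cutoff selection for FTPI screening tests.

All index tests considered here correlate positively with serum IgG, so a
*low* test value indicates FTPI: with the ``lower_is_positive``
orientation a calf is called positive iff its value is at or below the
cutoff. Candidate cutoffs are the distinct observed values plus an
all-negative sentinel, so the curve sweeps from (0, 0) to (1, 1).

Cutoff selection follows the classical criteria: maximal Youden index
J = Se + Sp - 1 (ties broken by minimal distance to the ROC corner
(0, 1), then by higher sensitivity), and the specificity/sensitivity
constrained rule-in / rule-out pair bounding a diagnostic grey zone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .stats import ConfusionTable, clopper_pearson, cohen_kappa

logger = logging.getLogger(__name__)

__all__ = [
    "ROCCurve",
    "DiagnosticPerformance",
    "build_roc",
    "auc",
    "select_cutoff_youden",
    "constrained_cutoffs",
    "performance_at",
    "plot_roc",
]

ORIENTATIONS = ("lower_is_positive", "higher_is_positive")


@dataclass
class ROCCurve:
    """Empirical operating points of one test on one labelled dataset.

    ``cutoffs[i]`` yields ``tp[i]`` true positives (of ``n_pos``) and
    ``fp[i]`` false positives (of ``n_neg``). Points are ordered so that
    tpr and fpr are non-decreasing.
    """

    test_name: str
    orientation: str
    cutoffs: np.ndarray = field(repr=False)
    tp: np.ndarray = field(repr=False)
    fp: np.ndarray = field(repr=False)
    n_pos: int = 0
    n_neg: int = 0

    @property
    def tpr(self) -> np.ndarray:
        return self.tp / self.n_pos

    @property
    def fpr(self) -> np.ndarray:
        return self.fp / self.n_neg


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Operating characteristics of one test at one cutoff.

    ``j`` is Youden's index Se + Sp - 1; ``dist`` the Euclidean distance
    of (fpr, tpr) from the ideal corner (0, 1) and ``dist_sq`` its square;
    ``kappa`` the chance-corrected agreement with the reference calls.
    """

    test_name: str
    cutoff: float
    se: float
    sp: float
    se_ci: tuple[float, float]
    sp_ci: tuple[float, float]
    j: float
    dist: float
    dist_sq: float
    auc: float
    kappa: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        assert abs(self.j - (self.se + self.sp - 1.0)) < 1e-12
        assert abs(self.dist_sq - ((1 - self.se) ** 2 + (1 - self.sp) ** 2)) < 1e-12
        assert self.se_ci[0] - 1e-12 <= self.se <= self.se_ci[1] + 1e-12
        assert self.sp_ci[0] - 1e-12 <= self.sp <= self.sp_ci[1] + 1e-12

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "cutoff": self.cutoff,
            "se": self.se,
            "sp": self.sp,
            "se_ci_low": self.se_ci[0],
            "se_ci_high": self.se_ci[1],
            "sp_ci_low": self.sp_ci[0],
            "sp_ci_high": self.sp_ci[1],
            "j": self.j,
            "dist": self.dist,
            "dist_sq": self.dist_sq,
            "auc": self.auc,
            "kappa": self.kappa,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


def _clean(values, labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape:
        raise ValueError("values and labels must be aligned")
    mask = np.isfinite(v)
    v, y = v[mask], y[mask]
    n_pos = int(y.sum())
    n_neg = int(v.size - n_pos)
    if n_pos < 1 or n_neg < 1:
        raise ValueError(
            f"ROC undefined: need both classes, got {n_pos} positive / {n_neg} negative"
        )
    return v, y


def build_roc(
    values,
    labels,
    orientation: str = "lower_is_positive",
    test_name: str = "",
    allow_inverted: bool = False,
) -> ROCCurve:
    """Empirical ROC curve over the distinct observed values.

    Pairs with a missing value are dropped (complete-case per test).
    Unless ``allow_inverted`` is set, an AUC below 0.5 raises -- a likely
    sign that the orientation is wrong for this test.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    v, y = _clean(values, labels)
    pos = np.sort(v[y])
    neg = np.sort(v[~y])
    uniq = np.unique(v)
    if orientation == "lower_is_positive":
        cutoffs = np.concatenate(([-np.inf], uniq))
        tp = np.searchsorted(pos, cutoffs, side="right")
        fp = np.searchsorted(neg, cutoffs, side="right")
    else:
        cutoffs = np.concatenate(([np.inf], uniq[::-1]))
        tp = pos.size - np.searchsorted(pos, cutoffs, side="left")
        fp = neg.size - np.searchsorted(neg, cutoffs, side="left")
    roc = ROCCurve(
        test_name=test_name,
        orientation=orientation,
        cutoffs=cutoffs,
        tp=tp.astype(int),
        fp=fp.astype(int),
        n_pos=pos.size,
        n_neg=neg.size,
    )
    if not allow_inverted:
        a = auc(roc)
        if a < 0.5:
            raise ValueError(
                f"AUC {a:.3f} < 0.5 for test {test_name!r} under orientation "
                f"{orientation!r}; flip the orientation or pass allow_inverted=True"
            )
    return roc


def auc(roc: ROCCurve) -> float:
    """Trapezoidal area under the empirical ROC polyline.

    Equals the pairwise-comparison probability P(positive ranks before
    negative) + 0.5 P(tie) under the curve's orientation.
    """
    return float(np.trapezoid(roc.tpr, roc.fpr))


def _performance_from_counts(
    test_name: str,
    cutoff: float,
    tp: int,
    fp: int,
    n_pos: int,
    n_neg: int,
    auc_value: float,
    conf: float,
) -> DiagnosticPerformance:
    se = tp / n_pos
    sp = 1.0 - fp / n_neg
    table = ConfusionTable(a=tp, b=fp, c=n_pos - tp, d=n_neg - fp)
    dist_sq = (1 - se) ** 2 + (1 - sp) ** 2
    return DiagnosticPerformance(
        test_name=test_name,
        cutoff=float(cutoff),
        se=se,
        sp=sp,
        se_ci=clopper_pearson(tp, n_pos, conf),
        sp_ci=clopper_pearson(n_neg - fp, n_neg, conf),
        j=se + sp - 1.0,
        dist=math.sqrt(dist_sq),
        dist_sq=dist_sq,
        auc=auc_value,
        kappa=cohen_kappa(table),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def _finite_candidates(roc: ROCCurve) -> np.ndarray:
    return np.flatnonzero(np.isfinite(roc.cutoffs))


def select_cutoff_youden(roc: ROCCurve, conf: float = 0.95) -> DiagnosticPerformance:
    """Cutoff maximizing Youden's J among the observed candidate cutoffs.

    Ties in J are broken by minimal corner distance, then by higher
    sensitivity; the rule is deterministic.
    """
    idx = _finite_candidates(roc)
    se = roc.tpr[idx]
    sp = 1.0 - roc.fpr[idx]
    j = se + sp - 1.0
    best = j >= j.max() - 1e-12
    dist = np.sqrt((1 - se) ** 2 + (1 - sp) ** 2)
    dist_masked = np.where(best, dist, np.inf)
    best &= dist_masked <= dist_masked.min() + 1e-12
    se_masked = np.where(best, se, -np.inf)
    pick = int(np.flatnonzero(se_masked >= se_masked.max() - 1e-12)[0])
    i = idx[pick]
    return _performance_from_counts(
        roc.test_name, roc.cutoffs[i], int(roc.tp[i]), int(roc.fp[i]),
        roc.n_pos, roc.n_neg, auc(roc), conf,
    )


def constrained_cutoffs(
    roc: ROCCurve,
    min_sp: float = 0.95,
    min_se: float = 0.95,
    conf: float = 0.95,
) -> tuple[Optional[DiagnosticPerformance], Optional[DiagnosticPerformance]]:
    """Rule-in / rule-out cutoff pair bounding a diagnostic grey zone.

    Rule-in: the cutoff with the best sensitivity among those with
    specificity >= ``min_sp`` (a confident positive call). Rule-out: the
    cutoff with the best specificity among those with sensitivity >=
    ``min_se`` (a confident negative call). A side with no feasible
    cutoff is returned as ``None`` with a logged explanation.
    """
    if not (0 <= min_sp < 1) or not (0 <= min_se < 1):
        raise ValueError("min_sp and min_se must lie in [0, 1)")
    idx = _finite_candidates(roc)
    se = roc.tpr[idx]
    sp = 1.0 - roc.fpr[idx]

    def _pick(eligible: np.ndarray, primary: np.ndarray, secondary: np.ndarray) -> Optional[int]:
        if not eligible.any():
            return None
        p = np.where(eligible, primary, -np.inf)
        best = p >= p.max() - 1e-12
        s = np.where(best, secondary, -np.inf)
        return int(np.flatnonzero(s >= s.max() - 1e-12)[0])

    out = []
    for side, pick in (
        ("rule-in", _pick(sp >= min_sp, se, sp)),
        ("rule-out", _pick(se >= min_se, sp, se)),
    ):
        if pick is None:
            logger.warning(
                "%s cutoff undefined for test %r: no cutoff meets the constraint "
                "(min_sp=%.3f, min_se=%.3f)", side, roc.test_name, min_sp, min_se,
            )
            out.append(None)
        else:
            i = idx[pick]
            out.append(
                _performance_from_counts(
                    roc.test_name, roc.cutoffs[i], int(roc.tp[i]), int(roc.fp[i]),
                    roc.n_pos, roc.n_neg, auc(roc), conf,
                )
            )
    return out[0], out[1]


def performance_at(
    values,
    labels,
    cutoff: float,
    orientation: str = "lower_is_positive",
    test_name: str = "",
    conf: float = 0.95,
) -> DiagnosticPerformance:
    """Operating characteristics at a pre-specified cutoff.

    Under ``lower_is_positive`` a calf is called positive iff its value is
    at or below the cutoff. The attached AUC is that of the full
    empirical curve on the same data.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    v, y = _clean(values, labels)
    called = v <= cutoff if orientation == "lower_is_positive" else v >= cutoff
    tp = int(np.sum(called & y))
    fp = int(np.sum(called & ~y))
    roc = build_roc(v, y, orientation=orientation, test_name=test_name, allow_inverted=True)
    return _performance_from_counts(
        test_name, cutoff, tp, fp, int(y.sum()), int((~y).sum()), auc(roc), conf
    )


def plot_roc(rocs, path) -> None:
    """Plot one or more ROC polylines to an image file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for roc in np.atleast_1d(rocs):
        ax.plot(roc.fpr, roc.tpr, label=f"{roc.test_name} (AUC {auc(roc):.2f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
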