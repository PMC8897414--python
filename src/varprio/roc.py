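"""ROC curves, DeLong AUC inference, and cutoff-selection strategies.

The AUC is the Mann–Whitney two-sample statistic with midrank tie handling;
its variance and confidence interval follow DeLong's structural-components
method, which also yields the paired z-test used to compare two predictors
evaluated on the same variants (with pairwise deletion of rows missing
either score).

Three cutoff strategies are provided: Youden's J, the threshold at which
sensitivity equals specificity, and the strictest threshold whose
sensitivity still reaches a floor (default 90%).  All thresholds are
reported on the predictor's native scale with its native direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .registry import Direction, PredictorSpec
from .scores import LabeledScores, harmonize_array, native_from_harmonized


class DegenerateInputError(ValueError):
    """Raised when data cannot support the requested statistic."""


@dataclass
class RocCurve:
    """A per-predictor ROC evaluated at every distinct observed score.

    ``thresholds`` are on the native scale, ordered from lenient to strict;
    passing is inclusive (>= for higher-is-risk, <= for lower-is-risk).
    Rows with a missing score are excluded before construction.
    """

    predictor: str
    direction: Direction
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_variance: float
    auc_ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    # harmonized positive/negative scores, kept for paired comparisons
    _pos: np.ndarray = None
    _neg: np.ndarray = None


@dataclass
class CutoffEstimate:
    """A selected operating point on a ROC curve (native scale/direction)."""

    predictor: str
    strategy: str
    cutoff: float
    direction: Direction
    sensitivity: float
    specificity: float
    fp_rate: float  # percent, = 100 * (1 - specificity)
    missing_rate: float = float("nan")  # percent of labeled rows lacking the score

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def as_dict(self) -> dict:
        op = ">=" if self.direction is Direction.HIGHER else "<="
        return {
            "predictor": self.predictor,
            "strategy": self.strategy,
            "cutoff": self.cutoff,
            "direction": op,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fp_rate": self.fp_rate,
            "missing_rate": self.missing_rate,
        }


# ---------------------------------------------------------------------------
# DeLong structural components


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_components(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Structural components (V10 per positive, V01 per negative) and AUC.

    Uses the midrank formulation, so ties contribute 1/2; the AUC equals the
    mean of either component vector.
    """
    m, n = len(pos), len(neg)
    if m < 1 or n < 1:
        raise DegenerateInputError("need at least one score in each class")
    allv = np.concatenate([pos, neg])
    r_all = _midrank(allv)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else np.nan
    s01 = v01.var(ddof=1) if n > 1 else np.nan
    return float(s10 / m + s01 / n)


def auc_delong(roc: RocCurve) -> tuple[float, float, tuple[float, float]]:
    """AUC, DeLong variance, and a 95% normal CI clipped to [0, 1]."""
    if roc.n_pos < 2 or roc.n_neg < 2:
        raise DegenerateInputError("DeLong variance needs >=2 scores per class")
    return roc.auc, roc.auc_variance, roc.auc_ci95


# ---------------------------------------------------------------------------
# Curve construction


def roc_curve(
    data: LabeledScores,
    predictor: str,
    spec: PredictorSpec,
    *,
    restrict_family: bool = True,
) -> RocCurve:
    """Build the ROC for one predictor under per-predictor deletion.

    Splicing-family tools are evaluated on the splicing subset only (when
    ``restrict_family``).  Thresholds are the distinct observed native
    scores; sensitivity/specificity are evaluated with the inclusive pass
    predicate.
    """
    sub = data.subset_for(spec) if restrict_family else data
    raw = sub.scores_for(predictor)
    y = sub.y
    keep = ~np.isnan(raw)
    raw, y = raw[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise DegenerateInputError(
            f"{predictor}: need both classes with non-missing scores"
        )
    h = harmonize_array(raw, spec)
    pos, neg = h[y == 1], h[y == 0]

    v10, v01, auc = delong_components(pos, neg)
    var = delong_variance(v10, v01) if len(pos) > 1 and len(neg) > 1 else 0.0
    if var and var > 0:
        half = stats.norm.ppf(0.975) * np.sqrt(var)
        ci = (max(0.0, auc - half), min(1.0, auc + half))
    else:
        var = 0.0
        ci = (auc, auc)

    # thresholds: distinct harmonized scores ascending = lenient -> strict
    th = np.unique(h)
    sens = np.array([(pos >= t).mean() for t in th])
    spe = np.array([(neg < t).mean() for t in th])
    native = np.array([native_from_harmonized(t, spec) for t in th])
    return RocCurve(
        predictor=predictor,
        direction=spec.direction,
        thresholds=native,
        sensitivity=sens,
        specificity=spe,
        auc=auc,
        auc_variance=var,
        auc_ci95=ci,
        n_pos=len(pos),
        n_neg=len(neg),
        _pos=pos,
        _neg=neg,
    )


def compare_auc_paired(
    data: LabeledScores,
    predictor_a: str,
    spec_a: PredictorSpec,
    predictor_b: str,
    spec_b: PredictorSpec,
) -> tuple[float, float]:
    """DeLong paired z-test for the AUC difference of two predictors.

    Restricted to rows scored by both tools (pairwise deletion); returns
    (AUC_a - AUC_b, two-sided p).
    """
    if spec_a.family is not spec_b.family:
        sub = data
    else:
        sub = data.subset_for(spec_a)
    ra = sub.scores_for(predictor_a)
    rb = sub.scores_for(predictor_b)
    y = sub.y
    keep = ~np.isnan(ra) & ~np.isnan(rb)
    ra, rb, y = ra[keep], rb[keep], y[keep]
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("no common rows with both classes present")
    ha = harmonize_array(ra, spec_a)
    hb = harmonize_array(rb, spec_b)
    mask_pos = y == 1
    va10, va01, auc_a = delong_components(ha[mask_pos], ha[~mask_pos])
    vb10, vb01, auc_b = delong_components(hb[mask_pos], hb[~mask_pos])
    m, n = int(mask_pos.sum()), int((~mask_pos).sum())
    if m < 2 or n < 2:
        raise DegenerateInputError("paired DeLong needs >=2 rows per class")
    s10 = np.cov(np.vstack([va10, vb10]))
    s01 = np.cov(np.vstack([va01, vb01]))
    cov = s10 / m + s01 / n
    delta = auc_a - auc_b
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        # identical (or rank-identical) predictors: no sampling variability
        p = 1.0 if abs(delta) < 1e-12 else 0.0
        return float(delta), p
    z = delta / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(delta), float(p)


# ---------------------------------------------------------------------------
# Cutoff strategies
#
# Tie-break convention (the strategies below share it): among thresholds with
# equal objective value, prefer the one with higher sensitivity, then the
# stricter cutoff.


def _strictness_order(roc: RocCurve) -> np.ndarray:
    """Indices of thresholds from lenient to strict (native direction aware)."""
    # thresholds are already stored lenient -> strict by construction
    return np.arange(len(roc.thresholds))


def _pick(roc: RocCurve, objective: np.ndarray, strategy: str) -> CutoffEstimate:
    best = objective.max()
    cand = np.flatnonzero(np.isclose(objective, best))
    # higher sensitivity first, then stricter (larger index = stricter)
    cand = sorted(cand, key=lambda i: (-roc.sensitivity[i], -i))
    i = cand[0]
    return CutoffEstimate(
        predictor=roc.predictor,
        strategy=strategy,
        cutoff=float(roc.thresholds[i]),
        direction=roc.direction,
        sensitivity=float(roc.sensitivity[i]),
        specificity=float(roc.specificity[i]),
        fp_rate=100.0 * (1.0 - float(roc.specificity[i])),
    )


def cutoff_youden(roc: RocCurve) -> CutoffEstimate:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1."""
    j = roc.sensitivity + roc.specificity - 1.0
    return _pick(roc, j, "youden")


def cutoff_sens_eq_spec(roc: RocCurve) -> CutoffEstimate:
    """Threshold minimizing |sensitivity - specificity|."""
    gap = -np.abs(roc.sensitivity - roc.specificity)
    return _pick(roc, gap, "sens-eq-spec")


def cutoff_at_sensitivity(roc: RocCurve, target: float = 0.90) -> CutoffEstimate:
    """Strictest threshold whose sensitivity still reaches ``target``.

    This maximizes specificity subject to the sensitivity floor; the
    reported fp_rate (percent) is the benign pass rate at that threshold.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target sensitivity must be in (0, 1]")
    ok = np.flatnonzero(roc.sensitivity >= target)
    if len(ok) == 0:
        raise DegenerateInputError(
            f"{roc.predictor}: no threshold reaches sensitivity {target}"
        )
    i = ok[-1]  # thresholds ordered lenient -> strict
    return CutoffEstimate(
        predictor=roc.predictor,
        strategy="sens-90" if target == 0.90 else f"sens-{target:g}",
        cutoff=float(roc.thresholds[i]),
        direction=roc.direction,
        sensitivity=float(roc.sensitivity[i]),
        specificity=float(roc.specificity[i]),
        fp_rate=100.0 * (1.0 - float(roc.specificity[i])),
    )


STRATEGIES = {
    "youden": lambda roc, target: cutoff_youden(roc),
    "senspec": lambda roc, target: cutoff_sens_eq_spec(roc),
    "sens90": cutoff_at_sensitivity,
}


def missing_rate(data: LabeledScores, predictor: str, spec: Optional[PredictorSpec] = None) -> float:
    """Percent of labeled rows (of the predictor's relevant subset) lacking a score."""
    sub = data.subset_for(spec) if spec is not None else data
    raw = sub.scores_for(predictor)
    if len(raw) == 0:
        raise DegenerateInputError("empty table")
    return 100.0 * float(np.isnan(raw).mean())
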