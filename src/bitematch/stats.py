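"""Statistical evaluation of the bite-to-teeth matching statistic.

Every (teeth, bite) cell of a proportion matrix becomes a labeled pair
(outcome 1 iff the two samples come from the same participant). A
single-predictor logistic model tests whether the shared-read proportion
carries matching information; a ROC sweep over the observed proportions
selects the optimum proportion (OP) by Youden's J; and the confusion
table at the OP yields sensitivity, specificity, PPV and NPV with both
asymptotic-normal (Wald) and exact (Clopper-Pearson) binomial intervals.

The threshold comparison is inclusive (proportion >= threshold): pairs
printed exactly at the OP count as predicted matches, which is the
reading under which the published diagnostic table reproduces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .seq_io import ProportionMatrix
from .matching import participant_from_label


class UndefinedAUCError(ValueError):
    """ROC analysis needs at least one positive and one negative pair."""


@dataclass(frozen=True)
class LabeledPair:
    bite_id: str
    teeth_id: str
    proportion: float
    outcome: int  # 1 iff same participant

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError("outcome must be 0 or 1")
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"proportion {self.proportion} outside [0, 1]")


def label_pairs(
    matrix: ProportionMatrix,
    participant_of: Optional[Mapping[str, int]] = None,
    subset: Optional[Sequence[int]] = None,
) -> list[LabeledPair]:
    """One labeled pair per (teeth, bite) cell.

    ``participant_of`` maps sample ids to participants; by default it is
    parsed from the trailing digits of the printed labels. ``subset``
    restricts both axes to the given participant ids (e.g. the
    pooled-library participants 1 and 3-10). A bite whose corresponding
    teeth sample is absent is retained with all-zero outcomes, with a
    warning.
    """
    if participant_of is None:
        participant_of = {
            label: participant_from_label(label)
            for label in matrix.teeth_ids + matrix.bite_ids
        }
    teeth = matrix.teeth_ids
    bites = matrix.bite_ids
    if subset is not None:
        chosen = set(subset)
        teeth = [t for t in teeth if participant_of[t] in chosen]
        bites = [b for b in bites if participant_of[b] in chosen]
    teeth_participants = {participant_of[t] for t in teeth}
    pairs = []
    for bite in bites:
        if participant_of[bite] not in teeth_participants:
            warnings.warn(
                f"bite {bite!r} has no corresponding teeth sample; all its "
                "outcomes are 0",
                stacklevel=2,
            )
        for t in teeth:
            pairs.append(
                LabeledPair(
                    bite,
                    t,
                    float(matrix.values.at[t, bite]),
                    int(participant_of[t] == participant_of[bite]),
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# Binomial confidence intervals

Z_95 = float(sps.norm.ppf(0.975))


def binomial_ci(successes: int, n: int, method: str = "wald") -> tuple[float, float]:
    """95% CI for a binomial proportion, as percentages in [0, 100].

    ``wald``: asymptotic normal p +/- z*sqrt(p(1-p)/n), clipped to the
    unit interval (degenerate at p in {0, 1}). ``exact``: Clopper-Pearson.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    if method == "wald":
        lo, hi = proportion_confint(successes, n, alpha=0.05, method="normal")
    elif method == "exact":
        lo, hi = proportion_confint(successes, n, alpha=0.05, method="beta")
    else:
        raise ValueError(f"unknown method {method!r}")
    return 100 * max(0.0, float(lo)), 100 * min(1.0, float(hi))


# ---------------------------------------------------------------------------
# Threshold evaluation


def _metric(numer: int, denom: int) -> Optional[float]:
    return 100 * numer / denom if denom else None


def _cis(numer: int, denom: int) -> dict[str, Optional[tuple[float, float]]]:
    if not denom:
        return {"wald": None, "exact": None}
    return {
        "wald": binomial_ci(numer, denom, "wald"),
        "exact": binomial_ci(numer, denom, "exact"),
    }


@dataclass
class ConfusionSummary:
    """Counts and diagnostic metrics at one decision threshold.

    Metrics are percentages; each has a Wald and an exact
    (Clopper-Pearson) 95% interval, or None when its denominator is zero.
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float] = field(init=False)
    specificity: Optional[float] = field(init=False)
    ppv: Optional[float] = field(init=False)
    npv: Optional[float] = field(init=False)
    ci_sensitivity: dict = field(init=False)
    ci_specificity: dict = field(init=False)
    ci_ppv: dict = field(init=False)
    ci_npv: dict = field(init=False)

    def __post_init__(self) -> None:
        self.sensitivity = _metric(self.tp, self.tp + self.fn)
        self.specificity = _metric(self.tn, self.tn + self.fp)
        self.ppv = _metric(self.tp, self.tp + self.fp)
        self.npv = _metric(self.tn, self.tn + self.fn)
        self.ci_sensitivity = _cis(self.tp, self.tp + self.fn)
        self.ci_specificity = _cis(self.tn, self.tn + self.fp)
        self.ci_ppv = _cis(self.tp, self.tp + self.fp)
        self.ci_npv = _cis(self.tn, self.tn + self.fn)

    @property
    def youden_j(self) -> float:
        sens = self.sensitivity if self.sensitivity is not None else 0.0
        spec = self.specificity if self.specificity is not None else 0.0
        return (sens + spec) / 100 - 1


def evaluate_threshold(pairs: Sequence[LabeledPair], threshold: float) -> ConfusionSummary:
    """Confusion summary when a pair is called a match iff its proportion
    is at least the threshold."""
    if not pairs:
        raise ValueError("no pairs to evaluate")
    tp = sum(1 for p in pairs if p.outcome == 1 and p.proportion >= threshold)
    fn = sum(1 for p in pairs if p.outcome == 1 and p.proportion < threshold)
    fp = sum(1 for p in pairs if p.outcome == 0 and p.proportion >= threshold)
    tn = sum(1 for p in pairs if p.outcome == 0 and p.proportion < threshold)
    return ConfusionSummary(threshold, tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# ROC analysis


@dataclass
class RocAnalysis:
    candidate_thresholds: list[float]
    points: list[tuple[float, float, float]]  # (threshold, sens %, spec %)
    auc: float
    optimal_threshold: float


def empirical_auc(pairs: Sequence[LabeledPair]) -> float:
    """AUC as the rank-sum probability that a random corresponding pair
    scores above a random non-corresponding one (ties count one half)."""
    scores = np.array([p.proportion for p in pairs])
    outcomes = np.array([p.outcome for p in pairs])
    n1 = int(outcomes.sum())
    n0 = len(pairs) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedAUCError("need at least one positive and one negative pair")
    ranks = sps.rankdata(scores)
    rank_sum = ranks[outcomes == 1].sum()
    return float((rank_sum - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_analysis(pairs: Sequence[LabeledPair]) -> RocAnalysis:
    """Sweep the observed proportions as thresholds and pick the optimum.

    Candidate thresholds are the distinct observed proportions (lowest to
    highest); the optimum maximizes Youden's J, with ties broken toward
    the largest threshold (most stringent among equally good cutoffs).
    """
    auc = empirical_auc(pairs)  # also validates class balance
    candidates = sorted({p.proportion for p in pairs})
    points = []
    best_j, best_threshold = -math.inf, None
    for threshold in candidates:
        summary = evaluate_threshold(pairs, threshold)
        points.append((threshold, summary.sensitivity, summary.specificity))
        if summary.youden_j >= best_j:  # >= : ties go to the larger threshold
            best_j, best_threshold = summary.youden_j, threshold
    return RocAnalysis(candidates, points, auc, best_threshold)


# ---------------------------------------------------------------------------
# Logistic matching model


@dataclass
class ModelReport:
    """Per-locus evaluation of the logistic matching model."""

    locus: str
    n_pairs: int
    n_positive: int
    slope: Optional[float]
    intercept: Optional[float]
    p_value: Optional[float]  # likelihood-ratio test vs intercept-only
    p_value_wald: Optional[float]
    pseudo_r2: Optional[float]  # McFadden
    gof_p: Optional[float]  # Hosmer-Lemeshow, decile-grouped
    separation_flag: bool
    model_note: Optional[str]
    roc: RocAnalysis
    confusion_at_op: ConfusionSummary


def _null_loglik(y: np.ndarray) -> float:
    n1 = y.sum()
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return 0.0
    p = n1 / len(y)
    return float(n1 * math.log(p) + n0 * math.log(1 - p))


def hosmer_lemeshow(y: np.ndarray, fitted: np.ndarray, groups: int = 10) -> float:
    """Decile-grouped observed-vs-expected goodness-of-fit p-value."""
    import pandas as pd

    frame = pd.DataFrame({"y": y, "p": fitted})
    try:
        frame["g"] = pd.qcut(frame["p"].rank(method="first"), groups, labels=False)
    except ValueError:
        frame["g"] = 0
    statistic, used = 0.0, 0
    for _, grp in frame.groupby("g"):
        expected1 = grp["p"].sum()
        expected0 = (1 - grp["p"]).sum()
        observed1 = grp["y"].sum()
        observed0 = len(grp) - observed1
        if expected1 > 1e-12:
            statistic += (observed1 - expected1) ** 2 / expected1
        if expected0 > 1e-12:
            statistic += (observed0 - expected0) ** 2 / expected0
        used += 1
    df = max(used - 2, 1)
    return float(sps.chi2.sf(statistic, df))


def fit_matching_model(
    pairs: Sequence[LabeledPair], locus: str = ""
) -> ModelReport:
    """Fit outcome ~ proportion by logistic regression and evaluate it.

    The model p-value is a likelihood-ratio test against the
    intercept-only model, which stays well defined near perfect
    separation (where the Wald test collapses). Under perfect separation
    the maximum-likelihood slope diverges; the fit is flagged and the
    coefficient estimates should not be interpreted, but every diagnostic
    metric comes from the threshold analysis and is unaffected.
    """
    import statsmodels.api as sm

    y = np.array([p.outcome for p in pairs], dtype=float)
    x = np.array([p.proportion for p in pairs], dtype=float)
    roc = roc_analysis(pairs)  # validates both classes present
    confusion = evaluate_threshold(pairs, roc.optimal_threshold)

    positives = x[y == 1]
    negatives = x[y == 0]
    separation = positives.min() > negatives.max()

    slope = intercept = p_lr = p_wald = pseudo_r2 = gof_p = None
    note = None
    if np.ptp(x) == 0:
        note = "constant predictor: logistic model skipped"
    else:
        design = sm.add_constant(x)
        llnull = _null_loglik(y)
        llf = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = sm.Logit(y, design).fit(disp=0, maxiter=200)
                intercept, slope = (float(v) for v in result.params)
                llf = float(result.llf)
                p_wald = float(result.pvalues[1])
                fitted = np.asarray(result.predict(design))
            gof_p = hosmer_lemeshow(y, fitted)
        except Exception as exc:  # e.g. PerfectSeparationError
            note = f"maximum-likelihood fit failed ({type(exc).__name__})"
            if separation:
                # separated data: the model log-likelihood supremum is 0
                llf = 0.0
        if llf is not None:
            lr = 2 * (llf - llnull)
            p_lr = float(sps.chi2.sf(max(lr, 0.0), 1))
            pseudo_r2 = float(1 - llf / llnull) if llnull != 0 else None
        if separation and note is None:
            note = "perfect separation: coefficient estimates diverge"

    return ModelReport(
        locus=locus,
        n_pairs=len(pairs),
        n_positive=int(y.sum()),
        slope=slope,
        intercept=intercept,
        p_value=p_lr,
        p_value_wald=p_wald,
        pseudo_r2=pseudo_r2,
        gof_p=gof_p,
        separation_flag=bool(separation),
        model_note=note,
        roc=roc,
        confusion_at_op=confusion,
    )
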