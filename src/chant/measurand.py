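"""Accuracy deconstruction of candidate measurands (development phase).

For each oriented measurand this module provides the empirical ROC curve and
area under it, sensitivity/specificity at any cutoff, the effect size
(partial eta-squared), four cutoff-selection criteria, and their
geometric-mean consensus:

1. the cutoff where the sensitivity and specificity curves cross;
2. the cutoff where the positive and negative predictive value curves cross;
3. the cutoff where the positive likelihood ratio and the reciprocal of the
   negative likelihood ratio cross on the log scale (both ratios are
   "better" away from 1 in opposite directions, so they are compared through
   log LR+ = -log LR-; the search is restricted to cutoffs with a positive
   Youden index, where the crossing is unique);
4. the cutoff minimising a weighted misdiagnosis cost,
   cost(c) = (c_fp*FP + c_fn*FN) / (c_fp*N_neg + c_fn*N_pos),
   normalised to [0, 1] with 0 meaning perfect classification.

All curves are step functions of the cutoff.  They are evaluated at every
unique measurand value, treated as piecewise-linear between adjacent values
for root finding, and a crossing that holds over an interval resolves to the
interval midpoint.  Comparison is inclusive on the abnormal side of a cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .exceptions import ConfigurationError, DegenerateDataError
from .items import ITEMS, ITEM_LABELS, ITEM_ORIENTATION, Orientation

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class OrientedMeasurand:
    """One value per patient plus the direction of abnormality."""

    values: np.ndarray
    orientation: Orientation
    name: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ConfigurationError("measurand values must be 1-dimensional")
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("measurand values must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def abnormality_scores(self) -> np.ndarray:
        """Values on a scale where *higher always means more abnormal*."""
        sign = 1.0 if self.orientation is Orientation.HIGHER_ABNORMAL else -1.0
        return sign * self.values

    def to_native_cutoff(self, score_cutoff: float) -> float:
        sign = 1.0 if self.orientation is Orientation.HIGHER_ABNORMAL else -1.0
        return sign * score_cutoff

    def to_score_cutoff(self, native_cutoff: float) -> float:
        return self.to_native_cutoff(native_cutoff)


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class CostWeights:
    """Relative misdiagnosis costs.  The default false-positive to
    false-negative cost ratio is 1:2 (ratio 0.50): missing a case is twice as
    costly as a false alarm.  ``c_tp`` and ``c_tn`` are carried for fidelity
    with the published weighting but do not enter the normalised cost."""

    c_tp: float = 1.0
    c_tn: float = 1.0
    c_fp: float = 1.0
    c_fn: float = 2.0

    def __post_init__(self) -> None:
        for name in ("c_tp", "c_tn", "c_fp", "c_fn"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.c_fp + self.c_fn <= 0:
            raise ConfigurationError("c_fp + c_fn must be > 0")


@dataclass(frozen=True)
class EffectSize:
    partial_eta_squared: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class CutoffDecision:
    cutoff_sens_spec: float
    cutoff_ppv_npv: float
    cutoff_lr: float
    cutoff_min_cost: float
    geometric_mean: float
    cost_curve: tuple[tuple[float, float], ...]
    direction: Orientation


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class MeasurandReport:
    """One development-phase summary row for a measurand."""

    name: str
    auc: float
    crossover_sens_spec: float  # common sens = spec value at the crossover
    partial_eta_squared: float
    decision: CutoffDecision
    min_cost: float

    def to_row(self) -> dict:
        d = self.decision
        return {
            "measurand": self.name,
            "auc": self.auc,
            "crossover_sens_spec": self.crossover_sens_spec,
            "partial_eta_squared": self.partial_eta_squared,
            "cutoff_sens_spec": d.cutoff_sens_spec,
            "cutoff_ppv_npv": d.cutoff_ppv_npv,
            "cutoff_lr": d.cutoff_lr,
            "cutoff_min_cost": d.cutoff_min_cost,
            "geometric_mean_cutoff": d.geometric_mean,
            "direction": d.direction.value,
            "min_cost": self.min_cost,
        }


def _as_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels, dtype=bool)
    if arr.ndim != 1:
        raise ConfigurationError("labels must be 1-dimensional")
    return arr


def confusion_at_cutoff(
    measurand: OrientedMeasurand, labels: Sequence, cutoff: float
) -> ConfusionTable:
    """2x2 table at a cutoff; a value counts positive when it lies on the
    abnormal side of the cutoff (inclusive)."""
    labels = _as_labels(labels)
    if labels.size != measurand.values.size:
        raise ConfigurationError("values and labels must have the same length")
    scores = measurand.abnormality_scores
    positive = scores >= measurand.to_score_cutoff(cutoff)
    return ConfusionTable(
        tp=int(np.sum(positive & labels)),
        fp=int(np.sum(positive & ~labels)),
        fn=int(np.sum(~positive & labels)),
        tn=int(np.sum(~positive & ~labels)),
    )


def _check_both_classes(labels: np.ndarray, what: str) -> None:
    if labels.all() or not labels.any():
        raise DegenerateDataError(
            f"{what} undefined: labels contain a single class"
        )


def empirical_roc(measurand: OrientedMeasurand, labels: Sequence) -> RocCurve:
    """Empirical ROC over all unique cutoffs with endpoints (0,0) and (1,1);
    the area equals the concordance probability with ties counted 1/2."""
    labels = _as_labels(labels)
    _check_both_classes(labels, "ROC")
    scores = measurand.abnormality_scores
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos

    ranks = stats.rankdata(scores)  # midranks
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    # collapse ties: curve points only where the score changes
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(~sorted_labels)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(auc))


def _candidate_stats(
    measurand: OrientedMeasurand, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stats of the cutoff step-curves on the abnormality-score scale.

    Returns (score_cutoffs, sens, spec, ppv, npv) at each unique score plus a
    virtual all-negative cutoff above the largest score.  The step value on
    the half-open interval between adjacent candidates equals the value at
    the interval's upper candidate.
    """
    scores = measurand.abnormality_scores
    uniq = np.unique(scores)
    gap = np.mean(np.diff(uniq)) if uniq.size > 1 else 1.0
    cand = np.r_[uniq, uniq[-1] + gap]
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    tp = (n_pos - np.searchsorted(pos_sorted, cand, side="left")).astype(float)
    fp = (n_neg - np.searchsorted(neg_sorted, cand, side="left")).astype(float)
    fn = n_pos - tp
    tn = n_neg - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = tp / n_pos
        spec = tn / n_neg
        ppv = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        npv = np.where(tn + fn > 0, tn / (tn + fn), np.nan)
    return cand, sens, spec, ppv, npv


def _step_crossing(cand: np.ndarray, diff: np.ndarray, criterion: str) -> float:
    """Root of a step-function difference curve on the candidate grid.

    An exact-zero run over candidates i..j corresponds to the cutoff interval
    (cand[i-1], cand[j]] and resolves to its midpoint; otherwise the first
    sign change is interpolated linearly.
    """
    finite = np.isfinite(diff)
    zero = finite & (np.abs(diff) <= _ZERO_TOL)
    if zero.any():
        i = int(np.argmax(zero))
        j = i
        while j + 1 < zero.size and zero[j + 1]:
            j += 1
        lo = cand[i - 1] if i > 0 else cand[i]
        return float((lo + cand[j]) / 2.0)
    idx = np.flatnonzero(finite)
    for a, b in zip(idx[:-1], idx[1:]):
        if np.sign(diff[a]) != np.sign(diff[b]):
            da, db = diff[a], diff[b]
            # clamp infinities so interpolation lands at the finite end
            da = np.clip(da, -1e9, 1e9)
            db = np.clip(db, -1e9, 1e9)
            return float(cand[a] + (cand[b] - cand[a]) * da / (da - db))
    raise DegenerateDataError(
        f"{criterion} curves never cross; the data are degenerate for this "
        "criterion"
    )


def crossover_cutoff(
    measurand: OrientedMeasurand, labels: Sequence, criterion: str
) -> float:
    """Cutoff where the two criterion curves cross (native scale).

    ``criterion`` is 'sens_spec', 'ppv_npv' or 'lr' (see the module
    docstring for the likelihood-ratio construction).
    """
    labels = _as_labels(labels)
    _check_both_classes(labels, f"{criterion} crossover")
    cand, sens, spec, ppv, npv = _candidate_stats(measurand, labels)
    if criterion == "sens_spec":
        diff = sens - spec
    elif criterion == "ppv_npv":
        # PPV - NPV vanishes both where sens = spec and on the uninformative
        # locus sens + spec = 1; restrict to cutoffs with a positive Youden
        # index so only the meaningful crossing remains
        diff = ppv - npv
        diff = np.where(sens + spec - 1 > _ZERO_TOL, diff, np.nan)
    elif criterion == "lr":
        # log LR+ + log LR- = log[sens(1-sens)] - log[spec(1-spec)];
        # restricted to the informative region (Youden index > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            diff = np.log(sens * (1 - sens)) - np.log(spec * (1 - spec))
        # a perfectly separating cutoff has LR+ = inf and LR- = 0 at once:
        # the curves touch there (indeterminate ratio), so the difference is 0
        diff = np.where((sens == 1.0) & (spec == 1.0), 0.0, diff)
        informative = sens + spec - 1 > _ZERO_TOL
        if not informative.any():
            raise DegenerateDataError(
                "lr crossover undefined: no cutoff has a positive Youden index"
            )
        diff = np.where(informative, diff, np.nan)
        # the boundary of the informative region behaves like a sign change
        # toward +inf (the test degenerates to all-negative there)
        last = np.flatnonzero(informative)[-1]
        if last + 1 < diff.size:
            diff[last + 1] = np.inf
    else:
        raise ConfigurationError(f"unknown crossover criterion {criterion!r}")
    score_cut = _step_crossing(cand, diff, criterion)
    return measurand.to_native_cutoff(score_cut)


def misdiagnosis_cost(table: ConfusionTable, weights: CostWeights) -> float:
    """Normalised weighted misclassification cost in [0, 1]."""
    n_neg = table.fp + table.tn
    n_pos = table.tp + table.fn
    denom = weights.c_fp * n_neg + weights.c_fn * n_pos
    if denom <= 0:
        raise DegenerateDataError("cost undefined: no weighted observations")
    return (weights.c_fp * table.fp + weights.c_fn * table.fn) / denom


def min_cost_cutoff(
    measurand: OrientedMeasurand,
    labels: Sequence,
    weights: CostWeights = CostWeights(),
) -> tuple[float, tuple[tuple[float, float], ...]]:
    """Cutoff minimising the weighted misdiagnosis cost, with the full cost
    curve.  Cost ties resolve to the candidate nearest the
    sensitivity/specificity crossover."""
    labels = _as_labels(labels)
    _check_both_classes(labels, "min-cost cutoff")
    cand, sens, spec, _, _ = _candidate_stats(measurand, labels)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    fp = (1 - spec) * n_neg
    fn = (1 - sens) * n_pos
    cost = (weights.c_fp * fp + weights.c_fn * fn) / (
        weights.c_fp * n_neg + weights.c_fn * n_pos
    )
    best = cost.min()
    ties = np.flatnonzero(np.abs(cost - best) <= _ZERO_TOL)
    if ties.size > 1:
        anchor = measurand.to_score_cutoff(
            crossover_cutoff(measurand, labels, "sens_spec")
        )
        pick = ties[np.argmin(np.abs(cand[ties] - anchor))]
    else:
        pick = ties[0]
    curve = tuple(
        (float(measurand.to_native_cutoff(c)), float(v)) for c, v in zip(cand, cost)
    )
    return float(measurand.to_native_cutoff(cand[pick])), curve


def geometric_mean_cutoff(
    c1: float, c2: float, c3: float, c4: float, offset: float = 0.0
) -> float:
    """Geometric mean of the four criterion cutoffs.

    Requires a positive scale; for scales containing zero or negative
    cutoffs, pass a documented ``offset`` which is added before and removed
    after averaging.
    """
    cuts = np.array([c1, c2, c3, c4], dtype=float) + offset
    if np.any(cuts <= 0):
        raise ConfigurationError(
            "geometric mean requires strictly positive cutoffs; apply a "
            "positive `offset` to shift the scale (removed after averaging)"
        )
    return float(np.exp(np.mean(np.log(cuts))) - offset)


def partial_eta_squared(
    dependent: Sequence,
    factor: Sequence,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> EffectSize:
    """Partial eta-squared of ``factor`` on ``dependent``:
    SS_effect / (SS_effect + SS_error) from the linear-model decomposition,
    with covariates partialled out (type-II sums of squares).  Without
    covariates this is the classical eta-squared."""
    y = np.asarray(dependent, dtype=float)
    g = np.asarray(factor)
    if y.size != g.size:
        raise ConfigurationError("dependent and factor must have equal length")
    groups, counts = np.unique(g, return_counts=True)
    if groups.size < 2:
        raise ConfigurationError("need at least 2 groups")
    if counts.min() < 1:
        raise ConfigurationError("every group needs at least 1 observation")

    df = pd.DataFrame({"y": y, "g": g})
    terms = ["C(g)"]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        for j in range(cov.shape[1]):
            df[f"x{j}"] = cov[:, j]
            terms.append(f"x{j}")
    model = smf.ols("y ~ " + " + ".join(terms), data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    ss_effect = float(anova.loc["C(g)", "sum_sq"])
    ss_error = float(anova.loc["Residual", "sum_sq"])
    denom = ss_effect + ss_error
    eta = ss_effect / denom if denom > 0 else 0.0
    return EffectSize(partial_eta_squared=eta, ss_effect=ss_effect, ss_error=ss_error)


def sens_spec_at(measurand: OrientedMeasurand, labels: Sequence, cutoff: float) -> tuple[float, float]:
    """(sensitivity, specificity) at a native-scale cutoff."""
    t = confusion_at_cutoff(measurand, labels, cutoff)
    if t.tp + t.fn == 0 or t.fp + t.tn == 0:
        raise DegenerateDataError("sens/spec undefined: single-class labels")
    return t.tp / (t.tp + t.fn), t.tn / (t.fp + t.tn)


def evaluate_measurand(
    measurand: OrientedMeasurand,
    labels: Sequence,
    weights: CostWeights = CostWeights(),
    gm_offset: float = 0.0,
) -> MeasurandReport:
    """Assemble the full development-phase summary for one measurand."""
    labels = _as_labels(labels)
    roc = empirical_roc(measurand, labels)
    c_ss = crossover_cutoff(measurand, labels, "sens_spec")
    c_pn = crossover_cutoff(measurand, labels, "ppv_npv")
    c_lr = crossover_cutoff(measurand, labels, "lr")
    c_mc, curve = min_cost_cutoff(measurand, labels, weights)
    gm = geometric_mean_cutoff(c_ss, c_pn, c_lr, c_mc, offset=gm_offset)
    sens_at_cross, spec_at_cross = sens_spec_at(measurand, labels, c_ss)
    effect = partial_eta_squared(measurand.values, labels)
    min_cost = min(v for _, v in curve)
    decision = CutoffDecision(
        cutoff_sens_spec=c_ss,
        cutoff_ppv_npv=c_pn,
        cutoff_lr=c_lr,
        cutoff_min_cost=c_mc,
        geometric_mean=gm,
        cost_curve=curve,
        direction=measurand.orientation,
    )
    return MeasurandReport(
        name=measurand.name,
        auc=roc.auc,
        crossover_sens_spec=(sens_at_cross + spec_at_cross) / 2.0,
        partial_eta_squared=effect.partial_eta_squared,
        decision=decision,
        min_cost=min_cost,
    )


def bilateral_values(cohort: pd.DataFrame, item: str) -> OrientedMeasurand:
    """Per-patient bilateral summary of a screening item: the *less abnormal*
    side, so that dichotomising it at the item cutoff is exactly the
    'abnormal on both sides' indicator."""
    if item not in ITEMS:
        raise ConfigurationError(f"unknown item {item!r}")
    r = cohort[f"{item}_right"].to_numpy(dtype=float)
    l = cohort[f"{item}_left"].to_numpy(dtype=float)
    orientation = ITEM_ORIENTATION[item]
    vals = np.minimum(r, l) if orientation is Orientation.HIGHER_ABNORMAL else np.maximum(r, l)
    return OrientedMeasurand(values=vals, orientation=orientation,
                             name=ITEM_LABELS[item])


def evaluate_cohort(
    cohort: pd.DataFrame,
    labels: Sequence,
    weights: CostWeights = CostWeights(),
) -> pd.DataFrame:
    """Development-phase summary table: one row per screening item, using the
    bilateral (less-abnormal-side) value of each item.

    The reflex item is a three-level ordinal scale, so its cutoffs are grid
    artifacts; on coarse grids or small samples a criterion's curves may
    never cross, in which case that item's cutoff columns are NaN and a
    warning is logged rather than the whole table failing.
    """
    import logging

    rows = []
    for item in ITEMS:
        m = bilateral_values(cohort, item)
        # the reflex and numbness scales contain 0; shift before averaging
        offset = 1.0 if np.any(m.values <= 0) else 0.0
        try:
            rows.append(
                evaluate_measurand(m, labels, weights, gm_offset=offset).to_row()
            )
        except DegenerateDataError as exc:
            logging.getLogger(__name__).warning(
                "measurand %s: %s; reporting partial row", m.name, exc
            )
            roc = empirical_roc(m, labels)
            effect = partial_eta_squared(m.values, labels)
            _, curve = min_cost_cutoff(m, labels, weights)
            row = {col: np.nan for col in (
                "crossover_sens_spec", "cutoff_sens_spec", "cutoff_ppv_npv",
                "cutoff_lr", "cutoff_min_cost", "geometric_mean_cutoff",
            )}
            row.update({
                "measurand": m.name,
                "auc": roc.auc,
                "partial_eta_squared": effect.partial_eta_squared,
                "direction": m.orientation.value,
                "min_cost": min(v for _, v in curve),
            })
            rows.append(row)
    columns = [
        "measurand", "auc", "crossover_sens_spec", "partial_eta_squared",
        "cutoff_sens_spec", "cutoff_ppv_npv", "cutoff_lr", "cutoff_min_cost",
        "geometric_mean_cutoff", "direction", "min_cost",
    ]
    return pd.DataFrame(rows)[columns]
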