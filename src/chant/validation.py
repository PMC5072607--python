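"""Validation-phase statistics: 2x2 accuracy with likelihood ratios, pre- to
post-test probability, internal consistency, item-total and inter-tester
rank correlations, and the content validity ratio.

Likelihood ratios follow the standard definitions LR+ = sens/(1-spec) and
LR- = (1-sens)/spec; a perfect specificity yields LR+ = +inf (no continuity
correction).  Post-test probability is exact odds arithmetic:
post-odds = pre-odds x LR.

Internal consistency is Cronbach's alpha.  Item-total correlations are
*corrected* (each item against the total minus that item) Spearman
correlations with midranks; the uncorrected variant, which inflates the
correlation by the item's self-correlation, is available via
``corrected=False``.

The content validity ratio for an item rated essential by ``n_e`` of ``N``
expert panelists is CVR = (n_e - N/2) / (N/2), ranging from -1 to +1 with
positive values meaning more than half the panel rated the item essential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DegenerateDataError, UndefinedMetricError
from .measurand import ConfusionTable


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float

    def rounded(self, digits: int = 0) -> dict:
        """Percentages at reporting precision (full precision is kept
        internally)."""
        pct = lambda v: round(100 * v, digits) if digits else int(round(100 * v))
        return {
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "ppv_pct": pct(self.ppv),
            "npv_pct": pct(self.npv),
            "lr_pos": round(self.lr_pos, 2) if math.isfinite(self.lr_pos) else self.lr_pos,
            "lr_neg": round(self.lr_neg, 2),
        }


@dataclass(frozen=True)
class ReliabilityReport:
    cronbach_alpha: float
    item_total: dict[str, float]
    item_total_mean: float
    inter_tester: dict[str, float] | None = None


@dataclass(frozen=True)
class PanelResponse:
    n_panelists: int
    essential_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_panelists < 1:
            raise ConfigurationError("n_panelists must be >= 1")
        counts = tuple(int(c) for c in self.essential_counts)
        for c in counts:
            if c < 0 or c > self.n_panelists:
                raise ConfigurationError(
                    f"essential count {c} outside 0..{self.n_panelists}"
                )
        object.__setattr__(self, "essential_counts", counts)


def diagnostic_metrics(table: ConfusionTable) -> DiagnosticMetrics:
    """Standard 2x2 accuracy statistics.  Zero denominators raise a named
    error rather than silently returning zero."""
    if table.tp + table.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no reference positives")
    if table.fp + table.tn == 0:
        raise UndefinedMetricError("specificity undefined: no reference negatives")
    sens = table.tp / (table.tp + table.fn)
    spec = table.tn / (table.fp + table.tn)
    if table.tp + table.fp == 0:
        raise UndefinedMetricError("PPV undefined: no test positives")
    if table.tn + table.fn == 0:
        raise UndefinedMetricError("NPV undefined: no test negatives")
    ppv = table.tp / (table.tp + table.fp)
    npv = table.tn / (table.tn + table.fn)
    lr_pos = sens / (1.0 - spec) if spec < 1.0 else math.inf
    if spec == 0.0:
        raise UndefinedMetricError("LR- undefined: specificity is zero")
    lr_neg = (1.0 - sens) / spec
    return DiagnosticMetrics(sensitivity=sens, specificity=spec, ppv=ppv,
                             npv=npv, lr_pos=lr_pos, lr_neg=lr_neg)


def fagan_posttest(pretest: float, lr: float) -> float:
    """Post-test probability from pre-test probability and a likelihood
    ratio, by exact odds arithmetic."""
    if not 0.0 < pretest < 1.0:
        raise ConfigurationError(
            f"pretest probability must be strictly between 0 and 1: {pretest}"
        )
    if lr <= 0:
        raise ConfigurationError(f"likelihood ratio must be > 0: {lr}")
    post_odds = pretest / (1.0 - pretest) * lr
    return post_odds / (1.0 + post_odds)


def _item_matrix(item_matrix) -> pd.DataFrame:
    df = pd.DataFrame(item_matrix)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ConfigurationError("need at least 2 patients and 2 items")
    return df.astype(float)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha of a patients x items score matrix
    (sample variances, denominator n-1)."""
    df = _item_matrix(item_matrix)
    k = df.shape[1]
    total_var = df.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DegenerateDataError("total-score variance is zero")
    item_vars = df.var(ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))


def item_total_correlation(item_matrix, corrected: bool = True) -> tuple[dict[str, float], float]:
    """Per-item Spearman correlation with the (rest-)score, plus the mean.

    A constant item or rest-score yields NaN for that item (flagged by the
    caller); NaNs are excluded from the mean.
    """
    df = _item_matrix(item_matrix)
    total = df.sum(axis=1)
    out: dict[str, float] = {}
    for col in df.columns:
        other = (total - df[col]) if corrected else total
        if df[col].nunique() < 2 or other.nunique() < 2:
            out[str(col)] = float("nan")
            continue
        rho = stats.spearmanr(df[col], other).statistic
        out[str(col)] = float(rho)
    values = [v for v in out.values() if not math.isnan(v)]
    if not values:
        raise DegenerateDataError("all item-total correlations are undefined")
    return out, float(np.mean(values))


def inter_tester(rater1_matrix: pd.DataFrame, rater2_matrix: pd.DataFrame) -> dict[str, float]:
    """Per-item Spearman correlation between two raters (matched ids)."""
    r1, r2 = pd.DataFrame(rater1_matrix), pd.DataFrame(rater2_matrix)
    if "id" in r1.columns and "id" in r2.columns:
        if not r1["id"].reset_index(drop=True).equals(r2["id"].reset_index(drop=True)):
            raise ConfigurationError("rater matrices have mismatched ids")
        r1 = r1.drop(columns="id")
        r2 = r2.drop(columns="id")
    if list(r1.columns) != list(r2.columns) or len(r1) != len(r2):
        raise ConfigurationError("rater matrices must share items and patients")
    out = {}
    for col in r1.columns:
        out[str(col)] = float(stats.spearmanr(r1[col], r2[col]).statistic)
    return out


def reliability_report(
    item_matrix,
    rater2_matrix: pd.DataFrame | None = None,
    corrected: bool = True,
) -> ReliabilityReport:
    """Bundle internal consistency, item-total correlations and (optionally)
    inter-tester concordance."""
    per_item, mean = item_total_correlation(item_matrix, corrected=corrected)
    report = ReliabilityReport(
        cronbach_alpha=cronbach_alpha(item_matrix),
        item_total=per_item,
        item_total_mean=mean,
        inter_tester=(
            inter_tester(item_matrix, rater2_matrix)
            if rater2_matrix is not None else None
        ),
    )
    return report


def cvr(panel: PanelResponse) -> tuple[tuple[float, ...], float]:
    """Content validity ratio per item, with the across-item mean."""
    half = panel.n_panelists / 2.0
    values = tuple((n_e - half) / half for n_e in panel.essential_counts)
    return values, float(np.mean(values))


def panel_response_from_matrix(panel_matrix: pd.DataFrame,
                               essential_label: str = "essential") -> PanelResponse:
    """Condense a panelists x items rating matrix into essential counts."""
    df = pd.DataFrame(panel_matrix)
    counts = tuple(int((df[col] == essential_label).sum()) for col in df.columns)
    return PanelResponse(n_panelists=len(df), essential_counts=counts)
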