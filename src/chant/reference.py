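"""Reference standards: the 2-of-3 composite case definition used during
development, and the symmetric-cutoff examination-score proxy used during
validation.

The composite definition calls a participant a case when at least two of
three components are abnormal: clinical signs of distal sensory neuropathy,
two or more abnormal quantitative-sensory-testing parameters (of the
13-parameter protocol), and an intraepidermal nerve fiber density at or below
7.63 fibers/mm.

The examination-score proxy applies a total cutoff of 8 across both feet, and
flags -- rather than classifies -- participants whose score is concentrated
on one side, since a high unilateral score suggests a focal lesion instead of
a symmetric polyneuropathy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .synthetic import N_QST_PARAMETERS

IENFD_CUT_DEFAULT = 7.63  # fibers/mm, inclusive
QST_MIN_ABNORMAL_DEFAULT = 2
QST_Z_THRESHOLD_DEFAULT = 1.96  # two-sided normative band
UENS_TOTAL_CUTOFF_DEFAULT = 8
UENS_ASYMMETRY_FRACTION_DEFAULT = 0.25


@dataclass(frozen=True)
class CaseDefinitionResult:
    is_case: bool
    criteria_met: int
    signs: bool
    qst_abnormal: bool
    ienfd_low: bool


@dataclass(frozen=True)
class UensVerdict:
    """``positive`` is None when the participant is excluded for asymmetry:
    an excluded record is flagged, never silently counted as negative."""

    positive: bool | None
    total: int
    asymmetric_excluded: bool


def qst_abnormal_count(qst_z: Sequence[float], z_threshold: float = QST_Z_THRESHOLD_DEFAULT) -> int:
    """Count sensory-testing parameters with |z| strictly above the threshold."""
    z = np.asarray(qst_z, dtype=float)
    if z.shape != (N_QST_PARAMETERS,):
        raise ConfigurationError(
            f"expected {N_QST_PARAMETERS} z-scores, got shape {z.shape}"
        )
    if z_threshold <= 0:
        raise ConfigurationError(f"z_threshold must be > 0: {z_threshold}")
    return int(np.sum(np.abs(z) > z_threshold))


def hiv_pins_case(
    signs: bool,
    qst_count: int,
    ienfd: float,
    ienfd_cut: float = IENFD_CUT_DEFAULT,
    qst_min: int = QST_MIN_ABNORMAL_DEFAULT,
) -> CaseDefinitionResult:
    """Apply the 2-of-3 composite case definition."""
    if ienfd < 0:
        raise ConfigurationError(f"ienfd must be >= 0: {ienfd}")
    if qst_count < 0:
        raise ConfigurationError(f"qst_count must be >= 0: {qst_count}")
    components = (bool(signs), qst_count >= qst_min, ienfd <= ienfd_cut)
    met = sum(components)
    return CaseDefinitionResult(
        is_case=met >= 2,
        criteria_met=met,
        signs=components[0],
        qst_abnormal=components[1],
        ienfd_low=components[2],
    )


def uens_classify(
    right: int,
    left: int,
    total_cutoff: int = UENS_TOTAL_CUTOFF_DEFAULT,
    asymmetry_fraction: float = UENS_ASYMMETRY_FRACTION_DEFAULT,
) -> UensVerdict:
    """Classify on the examination-score total with a symmetry requirement.

    A participant scoring at or above ``total_cutoff`` is positive unless the
    smaller side carries less than ``asymmetry_fraction`` of the total, in
    which case the record is excluded (flagged) rather than classified.
    """
    if right < 0 or left < 0:
        raise ConfigurationError(f"side scores must be >= 0: ({right}, {left})")
    if right + left > 42:
        raise ConfigurationError("total examination score exceeds 42")
    if not 0 <= asymmetry_fraction <= 0.5:
        raise ConfigurationError(
            f"asymmetry_fraction must be in [0, 0.5]: {asymmetry_fraction}"
        )
    total = int(right) + int(left)
    if total >= total_cutoff and min(right, left) / total < asymmetry_fraction:
        return UensVerdict(positive=None, total=total, asymmetric_excluded=True)
    return UensVerdict(positive=total >= total_cutoff, total=total,
                       asymmetric_excluded=False)


def reference_verdicts(
    cohort: pd.DataFrame,
    standard: str = "hiv_pins",
    **kwargs,
) -> pd.DataFrame:
    """Per-patient verdicts for a cohort table.

    ``standard`` is 'hiv_pins' (composite 2-of-3) or 'uens' (examination-score
    proxy); extra keyword arguments are forwarded to the chosen classifier.
    Returns columns id, positive (nullable boolean) and, for the proxy,
    asymmetric_excluded.
    """
    rows = []
    if standard == "hiv_pins":
        z_threshold = kwargs.pop("z_threshold", QST_Z_THRESHOLD_DEFAULT)
        qst_cols = [f"qst_z_{i}" for i in range(1, N_QST_PARAMETERS + 1)]
        for _, row in cohort.iterrows():
            count = qst_abnormal_count(row[qst_cols].to_numpy(dtype=float), z_threshold)
            res = hiv_pins_case(bool(row["clinical_signs"]), count,
                                float(row["ienfd"]), **kwargs)
            rows.append({"id": row["id"], "positive": res.is_case,
                         "criteria_met": res.criteria_met})
    elif standard == "uens":
        for _, row in cohort.iterrows():
            v = uens_classify(int(row["uens_right"]), int(row["uens_left"]), **kwargs)
            rows.append({"id": row["id"], "positive": v.positive,
                         "asymmetric_excluded": v.asymmetric_excluded})
    else:
        raise ConfigurationError(f"unknown reference standard {standard!r}")
    return pd.DataFrame(rows)
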