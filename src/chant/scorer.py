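"""Scoring of the 4-item screen and the in-silico combination-rule search.

Each item is scored per side against its threshold and *tallied* as the
number of abnormal sides (0, 1 or 2).  The positivity rule combines the four
bilateral-abnormality indicators (tally == 2):

* ``verbal`` (canonical): positive when (bilateral feet pain OR bilaterally
  reduced vibration) AND (bilateral feet numbness OR bilaterally reduced
  ankle reflex).
* ``table2_strict``: positive only for the 21 tally quadruples enumerated in
  the published scoring rubric.  The verbal rule admits 4 additional
  quadruples (bilateral pain with bilaterally reduced reflex but neither
  bilateral numbness nor reduced vibration); the discrepancy is surfaced via
  :func:`rubric_discrepancy` and a log message, never silently resolved.

The rule search enumerates every non-constant *monotone* Boolean function of
the four bilateral indicators -- abnormal findings can only add evidence for
neuropathy -- and ranks them by Youden index against a reference standard.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DegenerateDataError
from .items import ITEMS, MeasurandThresholds
from .synthetic import PatientPhenotype

logger = logging.getLogger(__name__)

RULES = ("verbal", "table2_strict")

#: the 21 positive tally quadruples of the published rubric, in the printed
#: order (pain, numbness, vibration, reflex)
TABLE2_ROWS: frozenset[tuple[int, int, int, int]] = frozenset({
    (2, 2, 0, 0), (2, 2, 1, 0), (2, 2, 0, 1), (2, 2, 1, 1),
    (0, 2, 2, 0), (1, 2, 2, 0), (0, 2, 2, 1), (1, 2, 2, 1),
    (0, 0, 2, 2), (0, 1, 2, 2), (1, 0, 2, 2), (1, 1, 2, 2),
    (0, 2, 2, 2), (1, 2, 2, 2), (2, 0, 2, 2), (2, 1, 2, 2),
    (2, 2, 0, 2), (2, 2, 1, 2), (2, 2, 2, 0), (2, 2, 2, 1),
    (2, 2, 2, 2),
})


@dataclass(frozen=True)
class ChantScore:
    """The four bilateral tallies and the positivity verdict."""

    pain_tally: int
    numb_tally: int
    vib_tally: int
    reflex_tally: int
    positive: bool
    rule_used: str

    @property
    def tallies(self) -> tuple[int, int, int, int]:
        return (self.pain_tally, self.numb_tally, self.vib_tally,
                self.reflex_tally)


def _check_tallies(tallies: Sequence[int]) -> tuple[int, int, int, int]:
    t = tuple(int(v) for v in tallies)
    if len(t) != 4 or any(v not in (0, 1, 2) for v in t):
        raise ConfigurationError(f"tallies must be four values in {{0,1,2}}: {tallies}")
    return t


def score_items(
    patient: PatientPhenotype | Mapping,
    thresholds: MeasurandThresholds = MeasurandThresholds(),
) -> tuple[int, int, int, int]:
    """Tally abnormal sides per item for one participant.

    Accepts a :class:`~chant.synthetic.PatientPhenotype` or any mapping with
    the eight side columns (``pain_right`` ... ``reflex_left``).
    """
    get = (lambda k: getattr(patient, k)) if isinstance(patient, PatientPhenotype) \
        else (lambda k: patient[k])
    tallies = []
    for item in ITEMS:
        count = 0
        for side in ("right", "left"):
            key = f"{item}_{side}"
            try:
                value = get(key)
            except (AttributeError, KeyError) as exc:
                raise ConfigurationError(
                    f"missing value for item {item!r}, side {side!r}"
                ) from exc
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise ConfigurationError(
                    f"missing value for item {item!r}, side {side!r}"
                )
            count += thresholds.side_abnormal(item, value)
        tallies.append(count)
    return tuple(tallies)


def chant_positive(tallies: Sequence[int], rule: str = "verbal") -> bool:
    """Apply the positivity rule to a tally quadruple."""
    pain, numb, vib, reflex = _check_tallies(tallies)
    if rule == "verbal":
        return (pain == 2 or vib == 2) and (numb == 2 or reflex == 2)
    if rule == "table2_strict":
        return (pain, numb, vib, reflex) in TABLE2_ROWS
    raise ConfigurationError(f"unknown rule {rule!r}; expected one of {RULES}")


def score_patient(
    patient: PatientPhenotype | Mapping,
    thresholds: MeasurandThresholds = MeasurandThresholds(),
    rule: str = "verbal",
) -> ChantScore:
    """Score one participant end-to-end."""
    tallies = score_items(patient, thresholds)
    return ChantScore(*tallies, positive=chant_positive(tallies, rule),
                      rule_used=rule)


def score_cohort(
    cohort: pd.DataFrame,
    thresholds: MeasurandThresholds = MeasurandThresholds(),
    rule: str = "verbal",
) -> pd.DataFrame:
    """Score a cohort table; returns id, the four tallies, and the verdict."""
    rows = []
    for _, row in cohort.iterrows():
        tallies = score_items(row, thresholds)
        rows.append({
            "id": row["id"],
            "pain_tally": tallies[0],
            "numb_tally": tallies[1],
            "vib_tally": tallies[2],
            "reflex_tally": tallies[3],
            "chant_positive": chant_positive(tallies, rule),
            "rule_used": rule,
        })
    return pd.DataFrame(rows)


def enumerate_rubric(rule: str = "verbal") -> frozenset[tuple[int, int, int, int]]:
    """All positive tally quadruples under a rule (exhaustive scan of the
    3^4 = 81 possibilities)."""
    positives = frozenset(
        q for q in itertools.product((0, 1, 2), repeat=4) if chant_positive(q, rule)
    )
    if rule == "verbal":
        extra = positives - TABLE2_ROWS
        if extra:
            logger.info(
                "verbal rule admits %d quadruples absent from the printed "
                "rubric: %s", len(extra), sorted(extra),
            )
    return positives


def rubric_discrepancy() -> frozenset[tuple[int, int, int, int]]:
    """Quadruples positive under the verbal rule but absent from the printed
    21-row rubric."""
    return enumerate_rubric("verbal") - enumerate_rubric("table2_strict")


# ---------------------------------------------------------------------------
# in-silico rule search
# ---------------------------------------------------------------------------

def monotone_boolean_functions(n_vars: int = 4) -> list[tuple[int, ...]]:
    """All non-constant monotone Boolean functions of ``n_vars`` variables,
    each as a truth table indexed by the variable bitmask (bit i = variable
    i).  For 4 variables there are 166 (the 168 monotone functions minus the
    two constants)."""
    size = 1 << n_vars
    # precompute the comparable pairs (x subset-of y)
    pairs = [
        (x, y)
        for x in range(size)
        for y in range(size)
        if x != y and (x & y) == x
    ]
    out = []
    for bits in range(1 << size):
        table = tuple((bits >> i) & 1 for i in range(size))
        if all(v == table[0] for v in table):
            continue  # constant
        if all(table[x] <= table[y] for x, y in pairs):
            out.append(table)
    return out


def rule_to_expression(table: tuple[int, ...], names: Sequence[str] = ITEMS) -> str:
    """Minimal OR-of-ANDs expression of a monotone rule (its minimal true
    points)."""
    n = len(names)
    true_points = [x for x in range(1 << n) if table[x]]
    minimal = [
        x for x in true_points
        if not any((y & x) == y and y != x for y in true_points)
    ]
    clauses = []
    for x in sorted(minimal):
        vars_ = [names[i] for i in range(n) if (x >> i) & 1]
        clauses.append(" & ".join(vars_) if vars_ else "TRUE")
    return " | ".join(f"({c})" for c in clauses)


def alpha_test_rules(
    bilateral: pd.DataFrame | np.ndarray,
    reference_labels: Sequence,
) -> pd.DataFrame:
    """Rank every candidate combination rule against a reference standard.

    ``bilateral`` holds the four bilateral-abnormality indicators per patient
    (columns in the canonical item order: pain, numbness, vibration, reflex;
    a tallies table from :func:`score_cohort` is also accepted).  Returns one
    row per candidate rule with sensitivity, specificity and Youden index,
    sorted by Youden (descending), ties broken by the lexicographic truth
    table encoding.
    """
    labels = np.asarray(reference_labels, dtype=bool)
    if labels.all() or not labels.any():
        raise DegenerateDataError("rule search needs both classes in the reference")
    if isinstance(bilateral, pd.DataFrame):
        if all(f"{item}_tally" in bilateral.columns for item in ITEMS):
            ind = np.column_stack([
                bilateral[f"{item}_tally"].to_numpy() == 2 for item in ITEMS
            ])
        else:
            ind = bilateral[list(ITEMS)].to_numpy(dtype=bool)
    else:
        ind = np.asarray(bilateral, dtype=bool)
    if ind.shape != (labels.size, 4):
        raise ConfigurationError("need a patients x 4 indicator matrix")

    mask = (ind * (1 << np.arange(4))).sum(axis=1)  # bitmask per patient
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    rows = []
    for table in monotone_boolean_functions(4):
        predicted = np.asarray(table)[mask].astype(bool)
        sens = (predicted & labels).sum() / n_pos
        spec = (~predicted & ~labels).sum() / n_neg
        encoding = sum(v << i for i, v in enumerate(table))
        rows.append({
            "rule": rule_to_expression(table),
            "encoding": encoding,
            "sensitivity": sens,
            "specificity": spec,
            "youden": sens + spec - 1.0,
        })
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["youden", "encoding"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
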