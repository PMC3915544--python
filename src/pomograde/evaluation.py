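"""Confusion accounting for graded batches.

A prediction is correct when its (color group, size class) pair matches the
ground truth.  Rates are reported per group and globally; the global rate
is the graded-count-weighted mean of the per-group rates, i.e.
(sum graded - sum incorrect) / sum graded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import pandas as pd

from .grading import GradeRecord

__all__ = ["ConfusionTable", "summarize"]


@dataclass
class ConfusionTable:
    """Per-group graded/incorrect counts and correct-classification rates.

    Only groups that were actually graded appear in the dictionaries;
    an absent group is absent, not zero.  Rates are kept at full precision
    internally; the ``*_rounded`` accessors round to 3 decimals for
    reporting.
    """

    graded: Dict[str, int]
    incorrect: Dict[str, int]

    def __post_init__(self) -> None:
        if set(self.incorrect) - set(self.graded):
            raise ValueError("incorrect counts for ungraded groups")
        for g, n in self.graded.items():
            bad = self.incorrect.get(g, 0)
            if not 0 <= bad <= n:
                raise ValueError(f"group {g!r}: incorrect={bad} outside [0, {n}]")

    @classmethod
    def from_counts(cls, groups: Sequence[str], graded: Sequence[int],
                    incorrect: Sequence[int]) -> "ConfusionTable":
        return cls(graded=dict(zip(groups, graded)),
                   incorrect=dict(zip(groups, incorrect)))

    @property
    def rates(self) -> Dict[str, float]:
        return {g: (n - self.incorrect.get(g, 0)) / n
                for g, n in self.graded.items()}

    @property
    def rates_rounded(self) -> Dict[str, float]:
        return {g: round(r, 3) for g, r in self.rates.items()}

    @property
    def total_graded(self) -> int:
        return sum(self.graded.values())

    @property
    def total_incorrect(self) -> int:
        return sum(self.incorrect.get(g, 0) for g in self.graded)

    @property
    def global_rate(self) -> float:
        return (self.total_graded - self.total_incorrect) / self.total_graded

    @property
    def global_rate_rounded(self) -> float:
        return round(self.global_rate, 3)

    def to_frame(self) -> pd.DataFrame:
        groups = list(self.graded)
        return pd.DataFrame({
            "group": groups,
            "graded": [self.graded[g] for g in groups],
            "incorrect": [self.incorrect.get(g, 0) for g in groups],
            "rate": [self.rates_rounded[g] for g in groups],
        })

    def to_dict(self) -> Dict:
        return {
            "graded": dict(self.graded),
            "incorrect": {g: self.incorrect.get(g, 0) for g in self.graded},
            "rates": self.rates_rounded,
            "global_rate": self.global_rate_rounded,
        }

    def __str__(self) -> str:
        frame = self.to_frame()
        lines = [frame.to_string(index=False)]
        lines.append(f"global correct classification rate: "
                     f"{self.global_rate_rounded:g} "
                     f"({self.total_graded - self.total_incorrect}/"
                     f"{self.total_graded})")
        return "\n".join(lines)


def summarize(predicted: Sequence[GradeRecord],
              truth: Sequence[GradeRecord]) -> ConfusionTable:
    """Confusion table of aligned predicted vs ground-truth records.

    Records are grouped by the *truth* (color, size) group; a prediction is
    incorrect when its group differs.
    """
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions, {len(truth)} truths")
    if not truth:
        raise ValueError("empty record lists")
    graded: Dict[str, int] = {}
    incorrect: Dict[str, int] = {}
    for pred, true in zip(predicted, truth):
        g = true.group
        graded[g] = graded.get(g, 0) + 1
        if pred.group != g:
            incorrect[g] = incorrect.get(g, 0) + 1
    return ConfusionTable(graded=graded, incorrect=incorrect)
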