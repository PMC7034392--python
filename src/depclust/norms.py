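"""Cutoff-based (norm) severity classification of total scores.

A norm criterion partitions the integer total-score range into ordered
closed intervals, e.g. the original BDI-13 norms 0-4 (None), 5-7 (Mild),
8-15 (Moderate), 16-39 (Severe). Cutoffs are stored as the inclusive
upper bounds of the first k-1 levels, which maps the conventional
"0-4 / 5-7 / ..." notation onto integers with no half-open ambiguity.

Shifted variants move every cutoff by a constant: one point lower
("criterion1": 0-3 / 4-6 / 7-14 / 15-39) or one point higher
("criterion2": 0-5 / 6-8 / 9-16 / 17-39), emulating plausible re-normed
cutoffs without an actual re-norming study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormCriterion",
    "classify_by_norm",
    "shift_criterion",
    "builtin_criteria",
    "BDI13_NORM",
]

_LEVELS4 = ("None", "Mild", "Moderate", "Severe")


@dataclass(frozen=True)
class NormCriterion:
    """Ordered total-score intervals mapping totals to severity levels."""

    name: str
    level_names: tuple[str, ...]
    upper_bounds: tuple[int, ...]  # inclusive upper bound of the first k-1 levels
    score_max: int

    def __post_init__(self):
        if len(self.upper_bounds) != len(self.level_names) - 1:
            raise ValueError("need one upper bound per level except the last")
        bounds = self.upper_bounds
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError(f"{self.name}: upper bounds must be strictly increasing")
        if bounds[0] < 0 or bounds[-1] >= self.score_max:
            raise ValueError(
                f"{self.name}: bounds must lie within [0, {self.score_max})"
            )

    @property
    def k(self) -> int:
        return len(self.level_names)

    def intervals(self) -> list[tuple[int, int]]:
        """Closed integer intervals, one per level, partitioning [0, score_max]."""
        lows = (0, *(b + 1 for b in self.upper_bounds))
        highs = (*self.upper_bounds, self.score_max)
        return list(zip(lows, highs))

    def describe(self) -> dict:
        return {
            "name": self.name,
            "levels": {
                name: f"{lo}-{hi}"
                for name, (lo, hi) in zip(self.level_names, self.intervals())
            },
        }


BDI13_NORM = NormCriterion(
    name="norm",
    level_names=_LEVELS4,
    upper_bounds=(4, 7, 15),
    score_max=39,
)


def classify_by_norm(totals, criterion: NormCriterion) -> np.ndarray:
    """Map each total score to the unique interval containing it.

    Returns severity levels 0..k-1. Totals outside [0, score_max] are an
    error rather than clipped.
    """
    totals = np.asarray(totals)
    if totals.size and (totals.min() < 0 or totals.max() > criterion.score_max):
        bad = totals[(totals < 0) | (totals > criterion.score_max)][0]
        raise ValueError(
            f"total score {bad} outside [0, {criterion.score_max}]"
        )
    return np.searchsorted(np.asarray(criterion.upper_bounds), totals, side="left")


def shift_criterion(criterion: NormCriterion, delta: int) -> NormCriterion:
    """Translate every cutoff by ``delta`` points (validated)."""
    bounds = tuple(b + int(delta) for b in criterion.upper_bounds)
    name = criterion.name if delta == 0 else f"{criterion.name}{delta:+d}"
    return NormCriterion(
        name=name,
        level_names=criterion.level_names,
        upper_bounds=bounds,
        score_max=criterion.score_max,
    )


def builtin_criteria() -> list[NormCriterion]:
    """The original BDI-13 norm plus the one-point-down/up variants."""
    import dataclasses

    crit1 = dataclasses.replace(shift_criterion(BDI13_NORM, -1), name="criterion1")
    crit2 = dataclasses.replace(shift_criterion(BDI13_NORM, +1), name="criterion2")
    return [BDI13_NORM, crit1, crit2]
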