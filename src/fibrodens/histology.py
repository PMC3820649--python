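"""Histologic fibrosis scoring.

Each animal contributes three trichrome-stained slides (middle section plus
50 µm above and below), each graded for fibrosis severity on a 0–4 scale
(0 normal; grades I–IV mapped to 1–4, grade 4 meaning no remaining
airspace).  The per-animal pulmonary-fibrosis (PF) score is the sum over
the three slides, giving a 12-point maximum (= 100%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

N_SLIDES = 3
MAX_GRADE = 4
MAX_SCORE = N_SLIDES * MAX_GRADE  # 12


@dataclass(frozen=True)
class SlideGrades:
    """Exactly three slide grades, each an integer in {0..4}."""

    grades: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.grades) != N_SLIDES:
            raise ValueError(f"expected {N_SLIDES} slide grades, got {len(self.grades)}")
        for g in self.grades:
            if int(g) != g or not 0 <= g <= MAX_GRADE:
                raise ValueError(f"slide grade must be an integer in 0..{MAX_GRADE}, got {g}")
        object.__setattr__(self, "grades", tuple(int(g) for g in self.grades))


@dataclass(frozen=True)
class AnimalHistologyScore:
    """Per-animal PF score: the slide-grade total (0–12) and its percent of
    the 12-point maximum."""

    total: int
    percent_of_max: float


def score_animal(grades: SlideGrades | Sequence[int]) -> AnimalHistologyScore:
    """Sum three slide grades into the 12-point per-animal PF score."""
    if not isinstance(grades, SlideGrades):
        grades = SlideGrades(tuple(grades))
    total = sum(grades.grades)
    return AnimalHistologyScore(total=total, percent_of_max=100.0 * total / MAX_SCORE)


def score_group(records: Iterable[SlideGrades | Sequence[int]]) -> tuple[float, float, int]:
    """Group summary of per-animal totals: (mean, SEM, n).

    SEM is the n-1 sample standard deviation over sqrt(n); reported as 0
    for a single animal.
    """
    totals = [score_animal(r).total for r in records]
    n = len(totals)
    if n == 0:
        raise ValueError("score_group requires at least one animal")
    mean = sum(totals) / n
    if n == 1:
        return mean, 0.0, n
    var = sum((t - mean) ** 2 for t in totals) / (n - 1)
    return mean, math.sqrt(var) / math.sqrt(n), n
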