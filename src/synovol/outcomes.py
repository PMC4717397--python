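"""KOOS pain scoring, eligibility screening and OARSI-OMERACT response rules.

The KOOS pain subscale is nine 0–4 Likert items transformed to a 0–100
score with 100 = no pain, so an *increase* is an improvement.  A treated
subject is an OARSI-OMERACT responder when either

  (ii) KOOS pain improves by >= 50% relative to baseline, or
  (i)  KOOS pain improves by >= 20% relative to baseline AND the subject
       reports global improvement on a 5-category transition question,

in both cases with an additional absolute-improvement requirement of at
least 3 points when the baseline score is 15 or less.  A responder whose
score later falls back to within 20% of baseline has relapsed; a responder
who does not relapse within 6 months (183 days) has persistently responded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Iterable, Optional, Sequence

RELAPSE_WINDOW_DAYS = 183  # "6 months"


class UnscorableError(ValueError):
    """Too many missing items (or required items absent) to produce a score."""


class GlobalChange(IntEnum):
    """5-category global change in knee pain since baseline."""

    MUCH_WORSE = 0
    SLIGHTLY_WORSE = 1
    UNCHANGED = 2
    SLIGHTLY_BETTER = 3
    MUCH_BETTER = 4


#: categories counting as "global improvement in pain" for criterion (i)
DEFAULT_IMPROVEMENT_CATEGORIES = frozenset(
    {GlobalChange.SLIGHTLY_BETTER, GlobalChange.MUCH_BETTER}
)


@dataclass(frozen=True)
class KoosPainItems:
    """The nine KOOS pain items P1..P9, each 0 (none) to 4 (extreme).

    ``None`` marks a missing item; missingness is explicit, never imputed
    silently.
    """

    items: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if len(self.items) != 9:
            raise ValueError("expected 9 items P1..P9")
        for i, v in enumerate(self.items, start=1):
            if v is not None and (not isinstance(v, (int,)) or not 0 <= v <= 4):
                raise ValueError(f"item P{i} must be an integer in 0..4 or None, got {v!r}")

    @property
    def n_missing(self) -> int:
        return sum(v is None for v in self.items)


@dataclass(frozen=True)
class VisitRecord:
    """One subject-visit row of the longitudinal table."""

    subject_id: str
    visit: str  # "baseline" | "followup" | "final"
    days_since_injection: float
    koos_pain: Optional[float] = None  # 0-100, 100 = no pain
    vas_na: Optional[float] = None  # 0-10 cm, nominated activity
    vas_week: Optional[float] = None  # 0-10 cm, last week
    global_change: Optional[GlobalChange] = None
    stv_mm3: Optional[float] = None
    fluid_mm3: Optional[float] = None
    crystal_present: Optional[bool] = None
    kl_grade: Optional[int] = None

    def __post_init__(self) -> None:
        if self.koos_pain is not None and not 0.0 <= self.koos_pain <= 100.0:
            raise ValueError(f"koos_pain out of [0, 100]: {self.koos_pain}")
        for name in ("vas_na", "vas_week"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 10.0:
                raise ValueError(f"{name} out of [0, 10]: {v}")
        if self.kl_grade is not None and self.kl_grade not in (2, 3, 4):
            raise ValueError(f"kl_grade must be 2, 3 or 4, got {self.kl_grade}")


@dataclass(frozen=True)
class ResponderStatus:
    responder: bool
    criterion: Optional[str] = None  # "relative50" or "relative20+global"
    flagged: bool = False  # baseline 0: relative change undefined, absolute clause used

    def __bool__(self) -> bool:
        return self.responder


@dataclass(frozen=True)
class RelapseStatus:
    responder: bool
    relapsed: bool
    relapse_day: Optional[float] = None

    @property
    def persistent(self) -> bool:
        return self.responder and not self.relapsed


# ---------------------------------------------------------------------------
# Scoring and screening
# ---------------------------------------------------------------------------

def koos_pain_score(items: KoosPainItems) -> float:
    """Transform the nine pain items to the 0-100 subscale (100 = no pain).

    Standard KOOS rule: up to two missing items are tolerated, the mean of
    the answered items substitutes for them; more than two is unscorable.
    """
    if items.n_missing > 2:
        raise UnscorableError(f"{items.n_missing} items missing (max 2 allowed)")
    present = [v for v in items.items if v is not None]
    return 100.0 - (sum(present) / len(present)) * 25.0


def screen_eligibility(items: KoosPainItems, moderate_pain_48h: bool) -> bool:
    """Pain eligibility: >48 h of moderate pain in the last 2 weeks, or
    a P2-P9 item sum greater than 7 out of 32."""
    p2_to_p9 = items.items[1:]
    if any(v is None for v in p2_to_p9):
        raise UnscorableError("eligibility screening requires all of P2..P9")
    return bool(moderate_pain_48h or sum(p2_to_p9) > 7)


# ---------------------------------------------------------------------------
# Response / relapse classification
# ---------------------------------------------------------------------------

def _relative_improvement(baseline: float, delta: float,
                          denominator: str) -> Optional[float]:
    if denominator == "baseline":
        if baseline == 0:
            return None  # undefined; caller falls back to the absolute clause
        return delta / baseline
    if denominator == "scale":
        return delta / 100.0
    raise ValueError(f"unknown denominator convention: {denominator!r}")


def classify_responder(
    baseline: VisitRecord,
    followup: VisitRecord,
    *,
    improvement_categories: frozenset = DEFAULT_IMPROVEMENT_CATEGORIES,
    denominator: str = "baseline",
) -> ResponderStatus:
    """Apply the OARSI-OMERACT response rule to a baseline/follow-up pair.

    KOOS increase = pain improvement.  The conditional absolute clause
    (>= 3 points) is active only when the baseline score is 15 or less.
    When the baseline score is 0 the relative change is undefined; the
    subject is then classified on the absolute clause alone and flagged.
    """
    if baseline.koos_pain is None or followup.koos_pain is None:
        raise UnscorableError("both KOOS scores are required")
    if followup.global_change is None:
        raise UnscorableError("global change category is required at follow-up")
    b, f = baseline.koos_pain, followup.koos_pain
    delta = f - b
    abs_ok = (b > 15) or (delta >= 3)
    rel = _relative_improvement(b, delta, denominator)
    flagged = rel is None
    if flagged:
        rel_50 = rel_20 = delta > 0
    else:
        rel_50 = rel >= 0.50
        rel_20 = rel >= 0.20
    global_improved = followup.global_change in improvement_categories
    if rel_50 and abs_ok:
        return ResponderStatus(True, criterion="relative50", flagged=flagged)
    if rel_20 and abs_ok and global_improved:
        return ResponderStatus(True, criterion="relative20+global", flagged=flagged)
    return ResponderStatus(False, flagged=flagged)


def classify_relapse(baseline: VisitRecord, current: VisitRecord) -> bool:
    """True when pain has recurred to within 20% of the baseline KOOS score.

    KOOS is inverse-scored, so relapse means the current score has fallen
    back to at most 1.2x the baseline score.
    """
    if baseline.koos_pain is None or current.koos_pain is None:
        raise UnscorableError("both KOOS scores are required")
    return current.koos_pain <= baseline.koos_pain * 1.20


def classify_persistent(
    trajectory: Sequence[VisitRecord],
    baseline: VisitRecord,
    *,
    window_days: float = RELAPSE_WINDOW_DAYS,
) -> RelapseStatus:
    """Scan a responder's time-ordered trajectory for the first relapse.

    Relapse is assigned at the first record within ``window_days`` of the
    injection satisfying the within-20% rule; otherwise the subject has
    persistently responded.  The input must come from a responder.
    """
    days = [r.days_since_injection for r in trajectory]
    if any(b > a for a, b in zip(days[1:], days)):
        raise ValueError("trajectory must be time-ordered")
    for rec in trajectory:
        if rec.days_since_injection > window_days:
            break
        if rec.koos_pain is not None and classify_relapse(baseline, rec):
            return RelapseStatus(responder=True, relapsed=True,
                                 relapse_day=rec.days_since_injection)
    return RelapseStatus(responder=True, relapsed=False)


def global_change_from_delta(delta_koos: float, noise: float = 0.0) -> GlobalChange:
    """Map a realized KOOS pain change to a 5-category global impression.

    Thresholds at ±3 and ±10 points; ``noise`` lets a simulator add
    reporting error before categorisation.
    """
    d = delta_koos + noise
    if d >= 10:
        return GlobalChange.MUCH_BETTER
    if d >= 3:
        return GlobalChange.SLIGHTLY_BETTER
    if d > -3:
        return GlobalChange.UNCHANGED
    if d > -10:
        return GlobalChange.SLIGHTLY_WORSE
    return GlobalChange.MUCH_WORSE
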