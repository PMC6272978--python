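"""Selectivity ratios and selectivity-set assignment.

A compound tested against two targets (here cathepsin K and S) gets a
selectivity ratio SR = max(IC50_K, IC50_S) / min(IC50_K, IC50_S), always
expressed for the more potent target so SR >= 1. Compounds with SR at or
above ``selective_min`` (default 50) are selective for the favored target
(sets K/S or S/K); compounds below ``nonselective_max`` (default 10) are
non-selective (set KS). The band in between is labeled ``ambiguous`` rather
than silently binned, because both a 50-fold and a 10-fold convention are in
use for this panel; lowering ``selective_min`` to 10 recovers the laxer
convention. SR is computed from the raw IC50 ratio, which equals
10**|delta pIC50| exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .records import ActivityRecord


class Target(str, Enum):
    K = "K"
    S = "S"
    NONE = "none"


class SetLabel(str, Enum):
    K_OVER_S = "K/S"
    S_OVER_K = "S/K"
    KS_NONSELECTIVE = "KS"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SelectivityThresholds:
    """Threshold profile: SR >= selective_min is selective, SR < nonselective_max is not."""

    selective_min: float = 50.0
    nonselective_max: float = 10.0

    def __post_init__(self) -> None:
        if not (self.selective_min >= self.nonselective_max > 1.0):
            raise ValueError(
                "require selective_min >= nonselective_max > 1, got "
                f"{self.selective_min}, {self.nonselective_max}"
            )


#: The laxer 10-fold profile under which an SR of 25 counts as selective.
TENFOLD_THRESHOLDS = SelectivityThresholds(selective_min=10.0, nonselective_max=10.0)


@dataclass(frozen=True)
class SelectivityAssignment:
    compound_id: str
    sr: float
    favored_target: Target
    set_label: SetLabel


def selectivity_ratio(ic50_K: float, ic50_S: float) -> tuple[float, Target]:
    """Fold-ratio of the two potencies and the favored (more potent) target.

    Ties give (1.0, Target.NONE). Raises ``ValueError`` on non-positive input.
    """
    if ic50_K <= 0 or ic50_S <= 0:
        raise ValueError(f"IC50 values must be positive, got {ic50_K}, {ic50_S}")
    if ic50_K == ic50_S:
        return 1.0, Target.NONE
    if ic50_K < ic50_S:
        return ic50_S / ic50_K, Target.K
    return ic50_K / ic50_S, Target.S


def assign_set(
    sr: float,
    favored_target: Target,
    thresholds: SelectivityThresholds = SelectivityThresholds(),
) -> SetLabel:
    """Partition SR in [1, inf) into K/S, S/K, KS or ambiguous."""
    if sr < 1.0:
        raise ValueError(f"SR must be >= 1, got {sr}")
    if sr >= thresholds.selective_min:
        if favored_target is Target.K:
            return SetLabel.K_OVER_S
        if favored_target is Target.S:
            return SetLabel.S_OVER_K
        # sr >= selective_min with no favored target can only arise from
        # inconsistent caller input; sr > 1 implies a favored target exists.
        raise ValueError("selective SR requires a favored target")
    if sr < thresholds.nonselective_max:
        return SetLabel.KS_NONSELECTIVE
    return SetLabel.AMBIGUOUS


def assign(
    activity: ActivityRecord,
    thresholds: SelectivityThresholds = SelectivityThresholds(),
) -> SelectivityAssignment:
    """Full assignment for one activity record."""
    sr, favored = selectivity_ratio(activity.ic50_K, activity.ic50_S)
    return SelectivityAssignment(
        compound_id=activity.compound_id,
        sr=sr,
        favored_target=favored,
        set_label=assign_set(sr, favored, thresholds),
    )


def assign_all(
    activities: Iterable[ActivityRecord],
    thresholds: SelectivityThresholds = SelectivityThresholds(),
) -> list[SelectivityAssignment]:
    return [assign(a, thresholds) for a in activities]


def summarize_sets(assignments: Sequence[SelectivityAssignment]) -> dict[str, int]:
    """Per-set counts plus a ``total`` entry; total == len(assignments)."""
    counts = Counter(a.set_label.value for a in assignments)
    summary = {label.value: counts.get(label.value, 0) for label in SetLabel}
    summary["total"] = len(assignments)
    return summary
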