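"""Competition metrics and the V2 grouping of candidate loci.

Locally available microhomology pairs compete for the repair machinery:
a locus with one predominant pair tends to resolve into a single
deletion allele, while a locus with many near-equal pairs yields a
heterogeneous spectrum.  Two observable criteria capture this:

* criterion 1 — the top-ranked pattern's arm copies are separated by at
  most 5 bp of intervening sequence (proximity);
* criterion 2 — the top Pattern Score is at least 1.5x the second
  (low competition).

The four combinations partition loci into Groups 1-4; Group 4 (both
criteria) predicts a Predominant MMEJ Allele (PreMA) outcome.  The
legacy slope classifier (ordinary least-squares slope of Pattern Score
against rank, cutoff -40 score units per rank) is retained for
comparison with the earlier single-parameter analyses.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mh_core import MicrohomologyPattern

__all__ = [
    "CompetitionProfile",
    "rank_patterns",
    "top_ratio",
    "slope_value",
    "classify_group",
    "build_profile",
    "is_low_competition",
]

SPACING_MAX = 5          # criterion 1: intervening bases between arm copies
RATIO_MIN = 1.5          # criterion 2: top/second Pattern Score ratio
SLOPE_CUTOFF = -40.0     # legacy low-competition cutoff, score per rank


@dataclass(frozen=True)
class CompetitionProfile:
    """Ranked patterns for one locus plus the derived competition metrics."""

    ranked_patterns: tuple[MicrohomologyPattern, ...]
    top_score: float
    second_score: float | None
    ratio: float                 # math.inf when only one pattern exists
    slope_value: float | None    # None with < 2 patterns
    criterion1: bool
    criterion2: bool
    tie_top: bool
    group: int
    prema_candidate: bool

    @property
    def top_pattern(self) -> MicrohomologyPattern:
        return self.ranked_patterns[0]


def rank_patterns(
    patterns: list[MicrohomologyPattern],
) -> list[MicrohomologyPattern]:
    """Sort by descending score with a deterministic tie-break.

    Ties go to the longer arm, then the smaller deletion, then the
    smaller left coordinate, so any permutation of the input ranks
    identically.
    """
    return sorted(
        patterns,
        key=lambda p: (-p.score, -p.arm_len, p.deletion_len, p.left_start),
    )


def top_ratio(ranked: list[MicrohomologyPattern]) -> float:
    """Top-to-second Pattern Score ratio.

    A single pattern faces no competition at all, the limit case of low
    competition, and is reported as ``inf``; an exact tie gives 1.0.
    """
    if not ranked:
        raise ValueError("no patterns: locus has no competition profile")
    if len(ranked) == 1:
        return math.inf
    return ranked[0].score / ranked[1].score


def slope_value(
    ranked: list[MicrohomologyPattern], top_n: int = 10
) -> float | None:
    """OLS slope of Pattern Score against 1-based rank (top ``top_n``).

    Units are score per rank; the sequence is non-increasing so the
    slope is always <= 0.  Steeper (more negative) slopes mark
    lower-competition loci.  Returns ``None`` with fewer than two
    patterns.
    """
    if len(ranked) < 2:
        return None
    scores = [p.score for p in ranked[: min(top_n, len(ranked))]]
    ranks = np.arange(1, len(scores) + 1, dtype=float)
    slope = float(np.polyfit(ranks, np.asarray(scores, dtype=float), 1)[0])
    return slope


def classify_group(criterion1: bool, criterion2: bool) -> int:
    """Map the two criteria onto the Group 1-4 partition."""
    if criterion1 and criterion2:
        return 4
    if criterion1:
        return 3
    if criterion2:
        return 2
    return 1


def build_profile(
    patterns: list[MicrohomologyPattern],
    top_n: int = 10,
    spacing_max: int = SPACING_MAX,
    min_ratio: float = RATIO_MIN,
) -> CompetitionProfile | None:
    """Rank patterns and derive the full competition profile.

    Returns ``None`` for an empty pattern list: such a site has no
    MMEJ landscape and is unreportable rather than Group 1.
    """
    if not patterns:
        return None
    ranked = rank_patterns(patterns)
    ratio = top_ratio(ranked)
    second = ranked[1].score if len(ranked) > 1 else None
    tie_top = second is not None and ranked[0].score == second
    criterion1 = ranked[0].intervening_len <= spacing_max
    # a tied top allele cannot be predominant, and ratio 1.0 < min_ratio
    criterion2 = ratio >= min_ratio
    group = classify_group(criterion1, criterion2)
    return CompetitionProfile(
        ranked_patterns=tuple(ranked),
        top_score=ranked[0].score,
        second_score=second,
        ratio=ratio,
        slope_value=slope_value(ranked, top_n=top_n),
        criterion1=criterion1,
        criterion2=criterion2,
        tie_top=tie_top,
        group=group,
        prema_candidate=(group == 4),
    )


def is_low_competition(
    profile: CompetitionProfile, cutoff: float = SLOPE_CUTOFF
) -> bool:
    """Legacy slope-based classifier: slope strictly below ``cutoff``.

    A single-pattern locus has no slope but zero competition; it is
    treated as low-competition.
    """
    if profile.slope_value is None:
        return True
    return profile.slope_value < cutoff
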