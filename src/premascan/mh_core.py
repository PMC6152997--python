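"""Microhomology deletion-pattern enumeration and Bae-style scoring.

A DNA double-strand break (DSB) repaired by microhomology-mediated end
joining (MMEJ) anneals a pair of identical direct repeats ("microhomology
arms") flanking the break, deleting the intervening sequence plus one arm
copy.  This module enumerates every such repeat pair around a designated
cut site and scores each candidate deletion with the Bae et al. Pattern
Score,

    score = 100 * round(exp(-deletion_len / 20), 3) * (AT + 2 * GC)

where AT/GC count the bases of one arm copy and ``deletion_len`` is the
distance between the two arm copies (arm length + intervening bases).
The per-locus sum of Pattern Scores is the Microhomology Score, and the
score-weighted share of frame-shifting deletions is the out-of-frame
score.

Coordinates are 0-based and half-open throughout; ``cut_index`` counts
the bases 5' of the break, so the break lies between ``cut_index - 1``
and ``cut_index``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ScanConfig",
    "TargetLocus",
    "MicrohomologyPattern",
    "DeletionAllele",
    "enumerate_patterns",
    "pattern_score",
    "length_factor",
    "microhomology_score",
    "out_of_frame_score",
    "predicted_allele",
]

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class ScanConfig:
    """Enumeration and scoring parameters.

    min_arm
        Shortest arm considered a usable microhomology (bp).  Direct
        repeats of <= 2 bp are not treated as MMEJ substrates by default.
    window
        Search window on each side of the break (bp).
    include_2bp_arms
        Comparison mode that lowers the arm floor to 2 bp (used only to
        reproduce the arm-length sensitivity analyses; off by default).
    decay_constant
        Length weight of the exponential deletion-size penalty (bp).
    replicate_reference_rounding
        Round the length factor to 3 decimals before multiplication, for
        bit-parity with the reference (RGEN) implementation.
    """

    min_arm: int = 3
    window: int = 40
    include_2bp_arms: bool = False
    decay_constant: float = 20.0
    replicate_reference_rounding: bool = True

    def __post_init__(self) -> None:
        if self.min_arm < 2:
            raise ValueError(f"min_arm must be >= 2, got {self.min_arm}")
        if self.window < self.min_arm:
            raise ValueError(
                f"window ({self.window}) must be >= min_arm ({self.min_arm})"
            )

    @property
    def effective_min_arm(self) -> int:
        return 2 if self.include_2bp_arms else self.min_arm


@dataclass(frozen=True)
class TargetLocus:
    """A sequence with a designated cut position and search window.

    ``sequence`` is uppercased on construction.  The break lies between
    ``cut_index - 1`` and ``cut_index``; ``window`` bp are searched on
    each side of the break (truncated at the sequence ends).
    """

    sequence: str
    cut_index: int
    window: int = 40

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not 0 < self.cut_index < len(self.sequence):
            raise ValueError(
                f"cut_index {self.cut_index} out of range for sequence of "
                f"length {len(self.sequence)}"
            )
        if self.window < 2:
            raise ValueError(f"window must be >= 2, got {self.window}")

    @property
    def left_bound(self) -> int:
        return max(0, self.cut_index - self.window)

    @property
    def right_bound(self) -> int:
        return min(len(self.sequence), self.cut_index + self.window)


@dataclass(frozen=True)
class MicrohomologyPattern:
    """One direct-repeat pair spanning the break.

    The left arm copy occupies ``[left_start, left_start + arm_len)``
    entirely 5' of the break and the right copy
    ``[right_start, right_start + arm_len)`` entirely 3' of it.  MMEJ
    repair through this pattern deletes ``[left_start, right_start)``.
    """

    left_start: int
    right_start: int
    arm_seq: str
    score: float = 0.0

    @property
    def arm_len(self) -> int:
        return len(self.arm_seq)

    @property
    def deletion_len(self) -> int:
        return self.right_start - self.left_start

    @property
    def intervening_len(self) -> int:
        return self.deletion_len - self.arm_len

    @property
    def gc_count(self) -> int:
        return sum(1 for b in self.arm_seq if b in "GC")

    @property
    def at_count(self) -> int:
        return sum(1 for b in self.arm_seq if b in "AT")

    @property
    def out_of_frame(self) -> bool:
        return self.deletion_len % 3 != 0


@dataclass(frozen=True)
class DeletionAllele:
    """The single deletion allele produced by repair through one pattern."""

    resulting_sequence: str
    deletion_len: int
    deleted_span: tuple[int, int]
    junction_arm: str

    @property
    def retained_arm_span(self) -> tuple[int, int]:
        """Position of the retained arm copy in ``resulting_sequence``."""
        start = self.deleted_span[0]
        return (start, start + len(self.junction_arm))


def length_factor(deletion_len: int, config: ScanConfig | None = None) -> float:
    """Exponential deletion-size penalty, optionally reference-rounded."""
    config = config or ScanConfig()
    f = 1.0 / math.exp(deletion_len / config.decay_constant)
    if config.replicate_reference_rounding:
        f = round(f, 3)
    return f


def pattern_score(
    pattern: MicrohomologyPattern, config: ScanConfig | None = None
) -> float:
    """Bae-style Pattern Score of one microhomology pattern."""
    config = config or ScanConfig()
    weight = pattern.at_count + 2 * pattern.gc_count
    return 100.0 * length_factor(pattern.deletion_len, config) * weight


def _validate_window_alphabet(locus: TargetLocus) -> None:
    for i in range(locus.left_bound, locus.right_bound):
        if locus.sequence[i] not in _DNA:
            raise ValueError(
                f"non-ACGT base {locus.sequence[i]!r} at position {i} "
                "inside the search window; ambiguity codes are not valid "
                "microhomology substrates"
            )


def _resulting_sequence(sequence: str, left_start: int, right_start: int) -> str:
    return sequence[:left_start] + sequence[right_start:]


def deduplicate_patterns(
    sequence: str, patterns: list[MicrohomologyPattern]
) -> list[MicrohomologyPattern]:
    """Drop patterns indistinguishable from a longer-armed pattern.

    A pattern is removed when its arm is a substring of a longer
    pattern's arm and both deletions produce the identical resulting
    sequence: the two describe one physical deletion outcome, and
    keeping both would let a deletion compete with itself.
    """
    by_result: dict[str, list[MicrohomologyPattern]] = {}
    for p in patterns:
        by_result.setdefault(
            _resulting_sequence(sequence, p.left_start, p.right_start), []
        ).append(p)
    kept: list[MicrohomologyPattern] = []
    for group in by_result.values():
        for p in group:
            shadowed = any(
                q.arm_len > p.arm_len and p.arm_seq in q.arm_seq
                for q in group
            )
            if not shadowed:
                kept.append(p)
    kept.sort(key=lambda p: (p.left_start, p.right_start, p.arm_len))
    return kept


def enumerate_patterns(
    locus: TargetLocus, config: ScanConfig | None = None
) -> list[MicrohomologyPattern]:
    """Enumerate every deduplicated microhomology pattern at a locus.

    Every direct-repeat pair with arm length >= ``min_arm`` whose left
    copy lies wholly within ``[cut - window, cut)`` and right copy
    wholly within ``[cut, cut + window)`` is returned (windows truncated
    at the sequence ends), after removal of nested sub-arm duplicates.
    Output order is deterministic: (left_start, right_start, arm_len).
    """
    config = config or ScanConfig(window=locus.window)
    _validate_window_alphabet(locus)
    seq = locus.sequence
    cut = locus.cut_index
    lo, hi = locus.left_bound, locus.right_bound
    min_arm = config.effective_min_arm

    found: list[MicrohomologyPattern] = []
    max_k = min(cut - lo, hi - cut)
    for k in range(min_arm, max_k + 1):
        left_kmers: dict[str, list[int]] = {}
        for i in range(lo, cut - k + 1):
            left_kmers.setdefault(seq[i : i + k], []).append(i)
        for j in range(cut, hi - k + 1):
            arm = seq[j : j + k]
            for i in left_kmers.get(arm, ()):
                found.append(MicrohomologyPattern(i, j, arm))

    deduped = deduplicate_patterns(seq, found)
    return [
        MicrohomologyPattern(p.left_start, p.right_start, p.arm_seq,
                             score=pattern_score(p, config))
        for p in deduped
    ]


def microhomology_score(patterns: list[MicrohomologyPattern]) -> float:
    """Additive sum of all Pattern Scores at a locus (0 for none)."""
    return float(sum(p.score for p in patterns))


def out_of_frame_score(patterns: list[MicrohomologyPattern]) -> float | None:
    """Score-weighted percentage of frame-shifting deletion patterns.

    Returns ``None`` (a missing value, not zero) when the locus has no
    patterns: a locus without microhomology has no defined frame bias.
    """
    total = microhomology_score(patterns)
    if not patterns or total == 0:
        return None
    oof = sum(p.score for p in patterns if p.out_of_frame)
    return 100.0 * oof / total


def predicted_allele(
    locus: TargetLocus, pattern: MicrohomologyPattern
) -> DeletionAllele:
    """The deletion allele produced by repair through ``pattern``.

    The half-open span ``[left_start, right_start)`` is removed, which
    deletes the intervening sequence and the left arm copy; exactly one
    arm copy is retained at the junction.
    """
    seq = locus.sequence
    return DeletionAllele(
        resulting_sequence=_resulting_sequence(
            seq, pattern.left_start, pattern.right_start
        ),
        deletion_len=pattern.deletion_len,
        deleted_span=(pattern.left_start, pattern.right_start),
        junction_arm=pattern.arm_seq,
    )
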