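"""Independent oracles used to cross-check the implementation.

Deliberately written in a different style from the package: plain
quadratic substring scans and a transcription of the reference
(Bae-style) scoring loop, so agreement is evidence rather than
tautology.
"""
from __future__ import annotations

import math


def brute_force_pairs(seq: str, cut: int, window: int, min_arm: int):
    """Every (left_start, right_start, arm) identity pair, no dedup."""
    lo = max(0, cut - window)
    hi = min(len(seq), cut + window)
    pairs = []
    for k in range(min_arm, min(cut - lo, hi - cut) + 1):
        for i in range(lo, cut - k + 1):
            for j in range(cut, hi - k + 1):
                if seq[i : i + k] == seq[j : j + k]:
                    pairs.append((i, j, seq[i : i + k]))
    return pairs


def dedup_pairs(pairs):
    """Drop nested sub-arms describing the same physical deletion.

    A pair (i, j, arm) duplicates a longer pair (i2, j2, arm2) when it
    is the same deletion seen through a shorter arm at a shifted
    offset: the arm lies inside the longer arm's copies at the same
    shift on both sides.
    """
    kept = []
    for i, j, arm in pairs:
        k = len(arm)
        dup = False
        for i2, j2, arm2 in pairs:
            k2 = len(arm2)
            if k2 <= k:
                continue
            shift_l = i - i2
            shift_r = j - j2
            if (
                shift_l == shift_r
                and 0 <= shift_l <= k2 - k
                and arm2[shift_l : shift_l + k] == arm
            ):
                dup = True
                break
        if not dup:
            kept.append((i, j, arm))
    return kept


def reference_pattern_score(arm: str, deletion_len: int,
                            rounding: bool = True) -> float:
    """Transcription of the reference per-pattern scoring expression."""
    gc = sum(arm.count(c) for c in "GC")
    at = len(arm) - gc
    factor = 1.0 / math.exp(deletion_len / 20.0)
    if rounding:
        factor = round(factor, 3)
    return 100.0 * factor * (at + gc * 2)


def reference_locus_scores(seq: str, cut: int, window: int, min_arm: int = 3):
    """Reference-style full-locus computation.

    Returns (per-pattern score dict keyed by (left, right, arm),
    microhomology score, out-of-frame score or None).
    """
    pairs = dedup_pairs(brute_force_pairs(seq, cut, window, min_arm))
    scores = {}
    for i, j, arm in pairs:
        scores[(i, j, arm)] = reference_pattern_score(arm, j - i)
    total = sum(scores.values())
    if not scores:
        return scores, 0.0, None
    oof = sum(v for (i, j, _), v in scores.items() if (j - i) % 3 != 0)
    return scores, total, 100.0 * oof / total


def random_locus(rng, length: int):
    """Uniform random ACGT sequence with an interior cut site."""
    seq = "".join(rng.choice("ACGT") for _ in range(length))
    cut = rng.randrange(1, length)
    return seq, cut
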