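"""Synthetic loci and allele tables with constructed ground truth.

The generator emits a locus whose microhomology landscape inside the
search window is, by construction, exactly the planted repeat pair plus
any requested decoy pairs: the background is filled base by base under
the constraint that no 3-mer occurs on both sides of the break (any
shared repeat of >= 3 bp implies a shared 3-mer), and every emitted
locus is verified by an independent brute-force repeat audit before it
is returned.  This makes the expected top pattern, group label, and
predicted allele certainties rather than probabilities, so the rest of
the package can be tested without any external data.

Decoy pairs are additional cross-break repeats placed outside the
planted pair, with arm length/composition and spacing searched to bring
their Pattern Score as close as possible to ``decoy_strength`` times
the planted score (strength 1.0 forces high competition; Criterion 2
then fails).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .competition import CompetitionProfile, build_profile
from .mh_core import (
    DeletionAllele,
    MicrohomologyPattern,
    ScanConfig,
    TargetLocus,
    deduplicate_patterns,
    enumerate_patterns,
    length_factor,
    predicted_allele,
)
from .outcomes import ObservedAllele

__all__ = [
    "PlantSpec",
    "PlantedLocus",
    "FixtureInfeasibleError",
    "plant_locus",
    "simulate_allele_table",
    "allele_table_from_frame",
]


class FixtureInfeasibleError(RuntimeError):
    """The requested plant cannot be realized (geometry or retries)."""


@dataclass(frozen=True)
class PlantSpec:
    """Recipe for one planted locus.

    arm_len / arm_gc
        Length of the planted arm and how many of its bases are G/C.
    intervening_len
        Bases between the two arm copies; the break falls inside this
        gap (or between abutting arms when 0).
    n_decoys / decoy_strength
        Extra cross-break repeat pairs and their target Pattern Score
        relative to the planted pattern.
    window
        Search window audited on each side of the break (bp).
    """

    arm_len: int = 6
    arm_gc: int = 4
    intervening_len: int = 0
    n_decoys: int = 0
    decoy_strength: float = 1.0
    seed: int = 0
    locus_len: int = 120
    background_gc: float = 0.5
    window: int = 20
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.arm_len < 3:
            raise ValueError("arm_len must be >= 3")
        if not 0 <= self.arm_gc <= self.arm_len:
            raise ValueError("arm_gc must be within [0, arm_len]")
        if self.intervening_len < 0:
            raise ValueError("intervening_len must be >= 0")
        if not 0 <= self.background_gc <= 1:
            raise ValueError("background_gc must be a fraction")
        need = 2 * max(
            self.window,
            self.arm_len + self.intervening_len + 6 * (self.n_decoys + 1),
        )
        if self.locus_len < need:
            raise ValueError(
                f"locus_len {self.locus_len} too short to host the plants "
                f"plus window (need >= {need})"
            )


@dataclass(frozen=True)
class PlantedLocus:
    """A generated locus with its constructed expected answers."""

    locus: TargetLocus
    config: ScanConfig
    patterns: tuple[MicrohomologyPattern, ...]
    profile: CompetitionProfile
    expected_top: MicrohomologyPattern
    expected_group: int
    predicted: DeletionAllele
    spec: PlantSpec


def _brute_force_repeats(
    seq: str, cut: int, window: int, min_arm: int
) -> list[MicrohomologyPattern]:
    """Plain double-loop repeat audit, independent of the enumeration path."""
    lo, hi = max(0, cut - window), min(len(seq), cut + window)
    out = []
    for i in range(lo, cut):
        for j in range(cut, hi):
            k = 0
            while (
                i + k < cut and j + k < hi and seq[i + k] == seq[j + k]
            ):
                k += 1
            if k >= min_arm:
                # emit the maximal run and every sub-length tail >= min_arm
                for m in range(min_arm, k + 1):
                    out.append(MicrohomologyPattern(i, j, seq[i : i + m]))
    return out


def _saturates_context(kmers: set[str]) -> bool:
    """True if some 2-mer has all four of its left- or right-extensions
    in ``kmers`` — the background fill would then have no legal base
    adjacent to an arm edge with that 2-mer context."""
    for a in "ACGT":
        for b in "ACGT":
            ctx = a + b
            if all(ctx + c in kmers for c in "ACGT"):
                return True
            if all(c + ctx in kmers for c in "ACGT"):
                return True
    return False


def _random_arm(rng: np.random.Generator, length: int, gc: int,
                forbidden_3mers: set[str]) -> str | None:
    """An arm with the requested GC count, internally unique 3-mers,
    no 3-mer shared with previously placed arms, and no 2-mer context
    saturated by the accumulated arm vocabulary."""
    for _ in range(200):
        bases = [rng.choice(["G", "C"]) for _ in range(gc)]
        bases += [rng.choice(["A", "T"]) for _ in range(length - gc)]
        rng.shuffle(bases)
        arm = "".join(bases)
        kmers = [arm[i : i + 3] for i in range(length - 2)]
        if len(set(kmers)) != len(kmers):
            continue
        if any(k in forbidden_3mers for k in kmers):
            continue
        if _saturates_context(forbidden_3mers | set(kmers)):
            continue
        return arm
    return None


def _arm_3mers(arm: str) -> set[str]:
    return {arm[i : i + 3] for i in range(len(arm) - 2)}


def _plan_decoys(
    spec: PlantSpec,
    cut: int,
    planted_score: float,
    l_free: int,
    r_free: int,
    config: ScanConfig,
    rng: np.random.Generator,
    forbidden: set[str],
) -> list[tuple[int, int, str]] | None:
    """Choose (left_start, right_start, arm_seq) for each decoy.

    Decoys are stacked outward from the planted arms with a three-base
    spacer (enough slack for the constrained background fill).  For each slot, candidate (arm length, GC count) choices
    are tried in order of distance to the target score; the first
    candidate for which a clean arm (internally unique 3-mers, none
    shared with previously placed arms) can be drawn wins.  Returns
    ``None`` when a slot's arm cannot be constructed (caller retries);
    raises when no slot fits the window at all.
    """
    plans: list[tuple[int, int, str]] = []
    target = spec.decoy_strength * planted_score
    for _ in range(spec.n_decoys):
        candidates = []
        for dlen in range(3, spec.arm_len + 3):
            ls = l_free - 3 - dlen
            rs = r_free + 3
            if ls < cut - spec.window or rs + dlen > cut + spec.window:
                continue
            dd = rs - ls
            lf = length_factor(dd, config)
            for gc in range(dlen + 1):
                score = 100.0 * lf * ((dlen - gc) + 2 * gc)
                # a decoy must not displace the planted top pattern
                # unless explicitly asked to (strength > 1)
                if spec.decoy_strength <= 1.0 and score >= planted_score:
                    continue
                candidates.append((abs(score - target), ls, rs, dlen, gc))
        if not candidates:
            raise FixtureInfeasibleError(
                f"cannot place decoy inside window {spec.window} "
                f"(free space exhausted at left={l_free}, right={r_free})"
            )
        # bucket the score error and prefer short arms within a bucket:
        # only 64 3-mers exist and every arm burns some, so long arms
        # can make the no-stray-repeat background unsatisfiable
        tol = max(1e-9, 0.15 * planted_score)
        candidates.sort(key=lambda c: (int(c[0] / tol), c[3], c[0]))
        chosen = None
        for _, ls, rs, dlen, gc in candidates:
            arm = _random_arm(rng, dlen, gc, forbidden)
            if arm is not None:
                chosen = (ls, rs, arm)
                break
        if chosen is None:
            return None
        forbidden |= _arm_3mers(chosen[2])
        plans.append(chosen)
        l_free, r_free = chosen[0], chosen[1] + len(chosen[2])
    return plans


def _fill_background(
    spec: PlantSpec,
    cut: int,
    stamped: dict[int, str],
    rng: np.random.Generator,
) -> list[str] | None:
    """Fill unstamped positions so no 3-mer occurs on both sides of the
    break, except inside the stamped arms themselves."""
    n = spec.locus_len
    w = spec.window
    lo, hi = max(0, cut - w), min(n, cut + w)
    seq: list[str | None] = [None] * n
    for pos, base in stamped.items():
        seq[pos] = base

    def window_kmers(a: int, b: int, only_stamped: bool) -> set[str]:
        out = set()
        for j in range(a, b - 2):
            trio = seq[j : j + 3]
            if any(x is None for x in trio):
                continue
            if only_stamped and not all(p in stamped for p in (j, j + 1, j + 2)):
                continue
            out.add("".join(trio))
        return out

    left3 = window_kmers(lo, cut, only_stamped=True)
    stamped_right3 = window_kmers(cut, hi, only_stamped=True)
    right3 = set(stamped_right3)

    gc = spec.background_gc
    weights = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))

    # most-constrained first: gap bases wedged next to stamped arms have
    # the fewest legal choices, so decide them before the open background
    near_stamp = {
        i
        for i in range(n)
        if any(j in stamped for j in range(i - 2, i + 3))
    }
    unfilled = sorted(
        (i for i in range(n) if seq[i] is None),
        key=lambda i: (0 if i in near_stamp else 1, i),
    )
    orders = {
        i: [str(b) for b in
            rng.choice(bases, size=4, replace=False, p=weights / weights.sum())]
        for i in unfilled
    }

    def viable(i: int) -> list[tuple[int, int, str, list[tuple[str, str]]]]:
        # Only 64 3-mers exist, so wide windows must keep each side's
        # 3-mer vocabulary small: rank non-violating candidates by how
        # few 3-mers they add that their side has not already used.
        out = []
        for rank, cand in enumerate(orders[i]):
            ok = True
            n_new = 0
            new_kmers: list[tuple[str, str]] = []
            for j in range(i - 2, i + 1):
                if j < 0 or j + 3 > n:
                    continue
                trio = [seq[x] if x != i else cand for x in (j, j + 1, j + 2)]
                if any(x is None for x in trio):
                    continue
                kmer = "".join(trio)
                if lo <= j and j + 3 <= cut:           # fully left of break
                    if kmer in right3:
                        ok = False
                        break
                    if kmer not in left3:
                        n_new += 1
                        new_kmers.append(("L", kmer))
                elif cut <= j and j + 3 <= hi:         # fully right of break
                    if kmer in left3:
                        ok = False
                        break
                    if kmer not in right3:
                        n_new += 1
                        new_kmers.append(("R", kmer))
            if ok:
                out.append((n_new, rank, cand, new_kmers))
        out.sort(key=lambda t: (t[0], t[1]))
        return out

    # depth-first fill with backtracking: stamped arm edges and earlier
    # background choices interact through overlapping 3-mer windows, so
    # a greedy pass can dead-end where a small revision succeeds
    budget = 50_000
    depth = 0
    pending: list[list[tuple[int, int, str, list[tuple[str, str]]]]] = []
    applied: list[list[tuple[str, str]]] = []
    while depth < len(unfilled):
        if budget <= 0:
            return None
        if len(pending) == depth:
            pending.append(viable(unfilled[depth]))
        if not pending[depth]:
            pending.pop()
            depth -= 1
            if depth < 0:
                return None
            i_prev = unfilled[depth]
            seq[i_prev] = None
            for side, kmer in applied.pop():
                (left3 if side == "L" else right3).discard(kmer)
            continue
        _, _, cand, new_kmers = pending[depth].pop(0)
        seq[unfilled[depth]] = cand
        for side, kmer in new_kmers:
            (left3 if side == "L" else right3).add(kmer)
        applied.append(new_kmers)
        depth += 1
        budget -= 1
    return seq  # type: ignore[return-value]


def _expected_patterns(
    planted: tuple[int, int, str],
    decoys: list[tuple[int, int, str]],
) -> set[tuple[int, int, str]]:
    return {planted} | set(decoys)


def plant_locus(
    spec: PlantSpec, config: ScanConfig | None = None
) -> PlantedLocus:
    """Generate a locus whose in-window landscape is exactly as planted.

    Deterministic per ``spec.seed``.  Raises
    :class:`FixtureInfeasibleError` when the geometry cannot fit the
    window or the audit keeps failing after ``max_retries`` attempts.
    """
    config = config or ScanConfig(window=spec.window)
    rng = np.random.default_rng(spec.seed)
    cut = spec.locus_len // 2
    li = (spec.intervening_len + 1) // 2   # intervening bases 5' of break
    ri = spec.intervening_len - li

    p_left = cut - li - spec.arm_len
    p_right = cut + ri
    if p_left < cut - spec.window or p_right + spec.arm_len > cut + spec.window:
        raise FixtureInfeasibleError(
            "planted arms do not fit inside the search window"
        )

    for _ in range(spec.max_retries):
        forbidden: set[str] = set()
        arm = _random_arm(rng, spec.arm_len, spec.arm_gc, forbidden)
        if arm is None:
            continue
        forbidden |= _arm_3mers(arm)

        stamped: dict[int, str] = {}
        for off, base in enumerate(arm):
            stamped[p_left + off] = base
            stamped[p_right + off] = base

        planted_pat = MicrohomologyPattern(p_left, p_right, arm)
        planted_score = 100.0 * length_factor(
            planted_pat.deletion_len, config
        ) * (planted_pat.at_count + 2 * planted_pat.gc_count)

        plans = _plan_decoys(
            spec, cut, planted_score, p_left, p_right + spec.arm_len,
            config, rng, forbidden,
        )
        if plans is None:
            continue
        decoy_keys: list[tuple[int, int, str]] = []
        for ls, rs, darm in plans:
            for off, base in enumerate(darm):
                stamped[ls + off] = base
                stamped[rs + off] = base
            decoy_keys.append((ls, rs, darm))

        filled = _fill_background(spec, cut, stamped, rng)
        if filled is None:
            continue
        seq = "".join(filled)

        # independent brute-force audit of the emitted window
        brute = _brute_force_repeats(
            seq, cut, spec.window, config.effective_min_arm
        )
        audited = {
            (p.left_start, p.right_start, p.arm_seq)
            for p in deduplicate_patterns(seq, brute)
        }
        expected = _expected_patterns((p_left, p_right, arm), decoy_keys)
        if audited != expected:
            continue

        locus = TargetLocus(seq, cut, window=spec.window)
        patterns = enumerate_patterns(locus, config)
        profile = build_profile(patterns)
        assert profile is not None
        return PlantedLocus(
            locus=locus,
            config=config,
            patterns=tuple(patterns),
            profile=profile,
            expected_top=profile.top_pattern,
            expected_group=profile.group,
            predicted=predicted_allele(locus, profile.top_pattern),
            spec=spec,
        )

    raise FixtureInfeasibleError(
        f"no clean locus after {spec.max_retries} attempts for spec {spec}"
    )


def simulate_allele_table(
    planted: PlantedLocus,
    fractions: dict[str, float],
    depth: int,
    substitution_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial sample of reads with retained ground-truth labels.

    ``fractions`` covers {wildtype, top_mh, other_mmej, other_mutant}
    and must sum to 1 (tolerance 1e-9).  Substitutions are sprinkled
    uniformly off the retained arm (and off the corresponding arm span
    of wildtype reads) at ``substitution_rate`` per base.  Returns a
    DataFrame with columns allele_seq, count, true_class.
    """
    classes = ("wildtype", "top_mh", "other_mmej", "other_mutant")
    unknown = set(fractions) - set(classes)
    if unknown:
        raise ValueError(f"unknown outcome classes: {sorted(unknown)}")
    probs = [fractions.get(c, 0.0) for c in classes]
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {sum(probs)}, expected 1")
    if fractions.get("other_mmej", 0) > 0 and len(planted.patterns) < 2:
        raise ValueError("other_mmej fraction > 0 but locus has one pattern")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, probs)
    ref = planted.locus.sequence
    cut = planted.locus.cut_index

    second_allele = None
    if len(planted.patterns) > 1:
        ranked = planted.profile.ranked_patterns
        second_allele = predicted_allele(planted.locus, ranked[1])

    base_seqs: dict[str, list[tuple[str, tuple[int, int] | None]]] = {
        "wildtype": [(ref, planted.predicted.retained_arm_span)],
        "top_mh": [
            (planted.predicted.resulting_sequence,
             planted.predicted.retained_arm_span)
        ],
        "other_mmej": (
            [(second_allele.resulting_sequence, second_allele.retained_arm_span)]
            if second_allele is not None
            else []
        ),
        # distinct 1 bp insertions at the break; never MMEJ-consistent
        "other_mutant": [
            (ref[:cut] + b + ref[cut:], None) for b in "ACGT"
        ],
    }

    rows: dict[tuple[str, str], int] = {}
    alt = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for cls, n in zip(classes, counts):
        variants = base_seqs[cls]
        for r in range(int(n)):
            seq, arm_span = variants[r % len(variants)]
            if substitution_rate > 0:
                chars = list(seq)
                allowed = [
                    i for i in range(len(chars))
                    if arm_span is None or not arm_span[0] <= i < arm_span[1]
                ]
                n_sub = rng.binomial(len(allowed), substitution_rate)
                for i in rng.choice(allowed, size=min(n_sub, len(allowed)),
                                    replace=False):
                    chars[i] = alt[chars[i]][rng.integers(3)]
                seq = "".join(chars)
            key = (seq, cls)
            rows[key] = rows.get(key, 0) + 1

    df = pd.DataFrame(
        [
            {"allele_seq": seq, "count": c, "true_class": cls}
            for (seq, cls), c in sorted(rows.items())
        ]
    )
    return df


def allele_table_from_frame(df: pd.DataFrame) -> list[ObservedAllele]:
    """Convert a simulated (or CSV-loaded) table to observed alleles."""
    return [
        ObservedAllele(allele_seq=row["allele_seq"], count=int(row["count"]))
        for _, row in df.iterrows()
    ]
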