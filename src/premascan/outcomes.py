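"""Repair-outcome accounting against the predicted MMEJ landscape.

Observed alleles (subcloned reads or deep-sequencing windows aligned to
a +/- 25 bp frame around the cut) are classified against the predicted
deletion landscape:

* ``top_mh`` — matches the top-predicted deletion allele with at most 2
  substitutions, none of which fall on the retained microhomology arm;
* ``other_mmej`` — matches any other enumerated pattern's deletion
  allele under the same tolerance;
* ``wildtype`` — matches the reference with no indel (same substitution
  tolerance);
* ``other_mutant`` — everything else, including any allele carrying an
  insertion (insertions are never MMEJ-consistent);
* ``excluded`` — reads failing alignment sanity (invalid characters or
  a length discrepancy larger than the analysis window allows).

From the classified table the module derives mutagenic efficiency
(mutant/total), the Microhomology Fraction (MMEJ-consistent mutant
reads over mutant reads), the Top MH Fraction (top-allele reads over
mutant reads), and the PreMA call: the top predicted allele is the
modal mutant allele, comprises >= 50% of mutant reads, and the
mutagenic efficiency strictly exceeds 20%.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .mh_core import (
    DeletionAllele,
    MicrohomologyPattern,
    ScanConfig,
    TargetLocus,
    enumerate_patterns,
    predicted_allele,
)
from .competition import rank_patterns

__all__ = [
    "ObservedAllele",
    "OutcomeMetrics",
    "AlleleClassifier",
    "classify_read",
    "compute_metrics",
    "tide_adjusted_prevalence",
    "ANALYSIS_HALF_WINDOW",
]

ANALYSIS_HALF_WINDOW = 25     # bp each side of the cut
MAX_SUBSTITUTIONS = 2         # polymorphism tolerance on the window
EFFICIENCY_MIN = 0.2          # PreMA requires strictly more than this

CLASS_LABELS = ("wildtype", "top_mh", "other_mmej", "other_mutant", "excluded")


@dataclass(frozen=True)
class ObservedAllele:
    """One observed allele of the analysis window with its read count.

    Either ``allele_seq`` is given directly, or an indel descriptor
    ``(position, deleted_len, inserted)`` relative to the reference
    window is materialized against it.
    """

    allele_seq: str | None
    count: int
    indel: tuple[int, int, str] | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.allele_seq is None and self.indel is None:
            raise ValueError("need allele_seq or an indel descriptor")


@dataclass(frozen=True)
class OutcomeMetrics:
    total_reads: int
    excluded_reads: int
    mutant_reads: int
    mutagenic_efficiency: float | None
    mh_fraction: float | None
    top_mh_fraction: float | None
    prema: bool
    low_activity: bool


def _hamming(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


class AlleleClassifier:
    """Classifies observed alleles for one locus.

    Precomputes the enumerated patterns, their deletion alleles, and
    the top-predicted allele from the analysis-window locus.
    """

    def __init__(
        self,
        locus: TargetLocus,
        config: ScanConfig | None = None,
        patterns: list[MicrohomologyPattern] | None = None,
        max_substitutions: int = MAX_SUBSTITUTIONS,
    ) -> None:
        self.locus = locus
        self.config = config or ScanConfig(window=locus.window)
        self.max_substitutions = max_substitutions
        if patterns is None:
            patterns = enumerate_patterns(locus, self.config)
        self.patterns = rank_patterns(patterns)
        self.alleles = [predicted_allele(locus, p) for p in self.patterns]
        self.predicted: DeletionAllele | None = (
            self.alleles[0] if self.alleles else None
        )

    # -- single-read classification ------------------------------------
    def materialize(self, obs: ObservedAllele) -> str:
        if obs.allele_seq is not None:
            return obs.allele_seq.upper()
        pos, dlen, ins = obs.indel
        ref = self.locus.sequence
        return ref[:pos] + ins.upper() + ref[pos + dlen :]

    def _matches_deletion(self, seq: str, allele: DeletionAllele) -> bool:
        target = allele.resulting_sequence
        if len(seq) != len(target):
            return False
        mism = _hamming(seq, target)
        if len(mism) > self.max_substitutions:
            return False
        arm0, arm1 = allele.retained_arm_span
        return all(not arm0 <= i < arm1 for i in mism)

    def classify(self, obs: ObservedAllele) -> str:
        try:
            seq = self.materialize(obs)
        except (TypeError, IndexError):
            return "excluded"
        ref = self.locus.sequence
        if not seq or any(c not in "ACGT" for c in seq):
            return "excluded"
        # a deletion spanning the break can reach 2*window and still lie
        # inside the analysis frame; anything larger failed alignment
        if abs(len(seq) - len(ref)) > 2 * self.locus.window:
            return "excluded"
        if obs.indel is not None and obs.indel[1] > 0 and obs.indel[2]:
            return "other_mutant"  # compound deletion+insertion
        if self.predicted is not None and self._matches_deletion(
            seq, self.predicted
        ):
            return "top_mh"
        for allele in self.alleles[1:]:
            if self._matches_deletion(seq, allele):
                return "other_mmej"
        if len(seq) == len(ref) and len(_hamming(seq, ref)) <= self.max_substitutions:
            return "wildtype"
        return "other_mutant"

    def classify_table(self, table: list[ObservedAllele]) -> list[ObservedAllele]:
        return [
            obs if obs.class_label in CLASS_LABELS
            else replace(obs, class_label=self.classify(obs))
            for obs in table
        ]

    # -- locus-level metrics -------------------------------------------
    def metrics(self, table: list[ObservedAllele]) -> OutcomeMetrics:
        classified = self.classify_table(table)
        counts = {label: 0 for label in CLASS_LABELS}
        allele_counts: dict[str, int] = {}
        for obs in classified:
            counts[obs.class_label] += obs.count
            if obs.class_label in ("other_mmej", "other_mutant"):
                seq = self.materialize(obs)
                allele_counts[seq] = allele_counts.get(seq, 0) + obs.count

        total = sum(obs.count for obs in classified)
        excluded = counts["excluded"]
        analyzable = total - excluded
        mutant = counts["top_mh"] + counts["other_mmej"] + counts["other_mutant"]
        efficiency = mutant / analyzable if analyzable else None

        if mutant == 0:
            return OutcomeMetrics(
                total_reads=total,
                excluded_reads=excluded,
                mutant_reads=0,
                mutagenic_efficiency=efficiency,
                mh_fraction=None,
                top_mh_fraction=None,
                prema=False,
                low_activity=True,
            )

        mh_fraction = (counts["top_mh"] + counts["other_mmej"]) / mutant
        top_fraction = counts["top_mh"] / mutant
        # modal test: the top predicted allele outnumbers every other
        # distinct mutant allele (a tie is not "most predominant")
        top_count = counts["top_mh"]
        other_max = max(allele_counts.values(), default=0)
        modal = top_count > 0 and top_count > other_max
        prema = (
            modal
            and top_fraction >= 0.5
            and efficiency is not None
            and efficiency > EFFICIENCY_MIN
        )
        return OutcomeMetrics(
            total_reads=total,
            excluded_reads=excluded,
            mutant_reads=mutant,
            mutagenic_efficiency=efficiency,
            mh_fraction=mh_fraction,
            top_mh_fraction=top_fraction,
            prema=prema,
            low_activity=(efficiency is not None and efficiency < EFFICIENCY_MIN),
        )


def classify_read(
    obs: ObservedAllele,
    locus: TargetLocus,
    config: ScanConfig | None = None,
    patterns: list[MicrohomologyPattern] | None = None,
) -> str:
    """Classify one observed allele against the locus landscape."""
    return AlleleClassifier(locus, config, patterns).classify(obs)


def compute_metrics(
    table: list[ObservedAllele],
    locus: TargetLocus,
    config: ScanConfig | None = None,
    patterns: list[MicrohomologyPattern] | None = None,
) -> OutcomeMetrics:
    """Classify a table of observed alleles and derive the metrics."""
    return AlleleClassifier(locus, config, patterns).metrics(table)


def tide_adjusted_prevalence(
    tide_table: pd.DataFrame,
    predicted_size: int,
    size_col: str = "indel_size",
    pct_col: str = "percentage",
    sig_col: str | None = "significant",
) -> float:
    """Adjusted prevalence of the predicted deletion from a decomposition.

    Given an indel-size decomposition (size, percentage of total signal,
    optional significance flag) from a chromatogram-decomposition tool,
    returns the share of the predicted deletion size among significant
    mutant signal, renormalized to the mutant (size != 0) fraction —
    the decomposition analogue of the Top MH Fraction.
    """
    df = tide_table
    if sig_col is not None and sig_col in df.columns:
        df = df[df[sig_col].astype(bool)]
    mutant = df[df[size_col] != 0]
    denom = float(mutant[pct_col].sum())
    if denom == 0:
        warnings.warn("no significant mutant signal in decomposition table")
        return 0.0
    hit = mutant[mutant[size_col] == predicted_size]
    if hit.empty:
        warnings.warn(
            f"predicted deletion size {predicted_size} absent from "
            "decomposition table"
        )
        return 0.0
    return float(hit[pct_col].sum()) / denom
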