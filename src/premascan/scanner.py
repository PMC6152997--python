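"""Candidate cut-site discovery on raw sequence.

Scans a sequence for protospacer-adjacent motifs (PAM, IUPAC-encoded) on
both strands, places the nuclease break at a configurable offset from
the PAM (SpCas9 default: blunt cut 3 nt 5' of an NGG), builds the
microhomology landscape at each implied break, and recommends sites
whose competition profile falls in Group 4 (PreMA candidates).  A TALEN
layout is supported by placing the break at the spacer midpoint.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Seq import Seq

from .competition import CompetitionProfile, build_profile
from .mh_core import (
    DeletionAllele,
    ScanConfig,
    TargetLocus,
    enumerate_patterns,
    predicted_allele,
)

__all__ = [
    "TargetingScheme",
    "CandidateSite",
    "PrevalenceSummary",
    "find_pam_sites",
    "scan",
    "site_at_cut",
    "talen_cut_index",
    "annotate_frame",
    "prevalence_screen",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class TargetingScheme:
    """How a programmable nuclease selects and cuts its target.

    ``cut_offset`` is the signed position of the break relative to the
    PAM-proximal end of the PAM: -3 puts a blunt cut 3 nt 5' of the PAM
    (SpCas9).  TALEN mode instead anchors the break at a spacer
    midpoint via :func:`talen_cut_index`.
    """

    pam: str = "NGG"
    cut_offset: int = -3
    guide_len: int = 20
    mode: str = "crispr"
    talen_spacer: tuple[int, int] = (14, 16)

    def __post_init__(self) -> None:
        if not self.pam:
            raise ValueError("pam must be non-empty")
        bad = [c for c in self.pam.upper() if c not in IUPAC]
        if bad:
            raise ValueError(f"invalid IUPAC letter(s) in pam: {bad}")
        if self.guide_len <= 0:
            raise ValueError("guide_len must be positive")
        if self.mode not in ("crispr", "talen"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class CandidateSite:
    """A PAM-anchored (or TALEN-anchored) cut site with its MMEJ profile."""

    site_id: str
    strand: str                       # "+" or "-"
    pam_start: int                    # forward-strand 0-based PAM start
    cut_index: int
    guide_seq: str
    profile: CompetitionProfile | None
    predicted: DeletionAllele | None
    frame_shift: bool | None
    recommended: bool
    truncated_guide: bool = False
    truncated_window: bool = False

    @property
    def group(self) -> int | None:
        return self.profile.group if self.profile is not None else None


@dataclass(frozen=True)
class PrevalenceSummary:
    """Unique-cut-site accounting for a whole-sequence screen."""

    total_sites: int                   # candidate sites incl. both strands
    unique_cut_sites: int
    recommended_cut_sites: int
    fraction_recommended: float | None
    out_of_frame_fraction: float | None  # among recommended cut sites


def _iupac_regex(pam: str) -> str:
    return "".join(
        f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c]
        for c in pam.upper()
    )


def find_pam_sites(
    sequence: str, scheme: TargetingScheme
) -> list[tuple[int, str]]:
    """All forward- and reverse-strand PAM matches, as forward coordinates.

    A reverse-strand hit is reported by the forward-strand start of the
    interval the PAM occupies (the forward sequence there matches the
    reverse complement of the PAM).  Ambiguous bases in the subject
    never match.  Order: position, then strand ("+" before "-").
    """
    sequence = sequence.upper()
    pam = scheme.pam.upper()
    fwd = re.compile(f"(?=({_iupac_regex(pam)}))")
    rc_pam = str(Seq(pam).reverse_complement())
    rev = re.compile(f"(?=({_iupac_regex(rc_pam)}))")
    hits = [(m.start(), "+") for m in fwd.finditer(sequence)]
    hits += [(m.start(), "-") for m in rev.finditer(sequence)]
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _cut_index_for(pam_start: int, strand: str, scheme: TargetingScheme) -> int:
    if strand == "+":
        return pam_start + scheme.cut_offset
    return pam_start + len(scheme.pam) - scheme.cut_offset


def site_at_cut(
    sequence: str,
    cut_index: int,
    config: ScanConfig,
    site_id: str,
    strand: str = "+",
    pam_start: int = -1,
    guide_seq: str = "",
    truncated_guide: bool = False,
    include_group3: bool = False,
) -> CandidateSite:
    """Build the MMEJ profile and recommendation for one break position."""
    locus = TargetLocus(sequence, cut_index, window=config.window)
    patterns = enumerate_patterns(locus, config)
    profile = build_profile(patterns)
    predicted = frame_shift = None
    if profile is not None:
        predicted = predicted_allele(locus, profile.top_pattern)
        frame_shift = predicted.deletion_len % 3 != 0
    recommended = profile is not None and (
        profile.group == 4 or (include_group3 and profile.group == 3)
    )
    truncated_window = (
        cut_index - config.window < 0
        or cut_index + config.window > len(sequence)
    )
    return CandidateSite(
        site_id=site_id,
        strand=strand,
        pam_start=pam_start,
        cut_index=cut_index,
        guide_seq=guide_seq,
        profile=profile,
        predicted=predicted,
        frame_shift=frame_shift,
        recommended=recommended,
        truncated_guide=truncated_guide,
        truncated_window=truncated_window,
    )


def _guide_for(
    sequence: str, pam_start: int, strand: str, scheme: TargetingScheme
) -> tuple[str, bool]:
    g = scheme.guide_len
    if strand == "+":
        start = pam_start - g
        guide = sequence[max(0, start) : pam_start]
        return guide, start < 0
    start = pam_start + len(scheme.pam)
    raw = sequence[start : start + g]
    return str(Seq(raw).reverse_complement()), len(raw) < g


def scan(
    sequence: str,
    scheme: TargetingScheme | None = None,
    config: ScanConfig | None = None,
    include_group3: bool = False,
    record_id: str = "seq",
) -> list[CandidateSite]:
    """Scan one sequence and profile every PAM-implied cut site.

    Sites whose break would fall outside the sequence are dropped;
    sites with a shortened guide or a search window clipped by the
    sequence end are kept and flagged.  Sites with no microhomology
    pattern are retained ungrouped but never recommended.
    """
    scheme = scheme or TargetingScheme()
    config = config or ScanConfig()
    sequence = sequence.upper()
    sites: list[CandidateSite] = []
    for pam_start, strand in find_pam_sites(sequence, scheme):
        cut = _cut_index_for(pam_start, strand, scheme)
        if not 0 < cut < len(sequence):
            continue
        guide, trunc_guide = _guide_for(sequence, pam_start, strand, scheme)
        sites.append(
            site_at_cut(
                sequence,
                cut,
                config,
                site_id=f"{record_id}:{cut}:{strand}",
                strand=strand,
                pam_start=pam_start,
                guide_seq=guide,
                truncated_guide=trunc_guide,
                include_group3=include_group3,
            )
        )
    return sites


def talen_cut_index(left_arm_end: int, spacer_len: int) -> int:
    """Break position for a TALEN spacer starting at ``left_arm_end``.

    The break is placed at the spacer midpoint; for an odd spacer the
    extra base goes 5' of the break.
    """
    if spacer_len <= 0:
        raise ValueError("spacer_len must be positive")
    return left_arm_end + (spacer_len + 1) // 2


def annotate_frame(
    site: CandidateSite,
    coding_intervals: list[tuple[int, int]] | None = None,
) -> str:
    """Frame consequence of the site's predicted deletion.

    Returns "out-of-frame", "in-frame", "indeterminate" (deletion
    overlaps a coding-interval boundary, i.e. a putative splice
    junction), or "none" when the site has no predicted allele.
    Intervals are 0-based, half-open on the scanned sequence.
    """
    if site.predicted is None:
        return "none"
    d0, d1 = site.predicted.deleted_span
    if coding_intervals:
        for start, end in coding_intervals:
            for boundary in (start, end):
                if d0 < boundary < d1:
                    return "indeterminate"
    return "out-of-frame" if site.predicted.deletion_len % 3 != 0 else "in-frame"


def prevalence_screen(
    sequence: str,
    scheme: TargetingScheme | None = None,
    config: ScanConfig | None = None,
    include_group3: bool = False,
) -> PrevalenceSummary:
    """Count unique cut sites and the PreMA-candidate subset.

    Forward and reverse PAM hits implying the same break position share
    one deletion landscape (enumeration depends only on the break), so
    they are counted once; both guides remain in :func:`scan` output.
    """
    sites = scan(sequence, scheme, config, include_group3=include_group3)
    by_cut: dict[int, list[CandidateSite]] = {}
    for s in sites:
        by_cut.setdefault(s.cut_index, []).append(s)
    n_unique = len(by_cut)
    recommended = {
        cut for cut, group in by_cut.items() if any(s.recommended for s in group)
    }
    n_rec = len(recommended)
    oof = None
    if n_rec:
        n_oof = sum(
            1 for cut in recommended if by_cut[cut][0].frame_shift
        )
        oof = n_oof / n_rec
    return PrevalenceSummary(
        total_sites=len(sites),
        unique_cut_sites=n_unique,
        recommended_cut_sites=n_rec,
        fraction_recommended=(n_rec / n_unique) if n_unique else None,
        out_of_frame_fraction=oof,
    )
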