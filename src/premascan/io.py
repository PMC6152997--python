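"""File I/O: FASTA input, CSV reports, YAML configuration.

Internal coordinates are 0-based half-open; reports additionally carry
1-based inclusive columns for human readers.  Reports open with
commented header lines recording the tool version and a hash of the
configuration, and are bit-identical across runs on identical inputs.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .mh_core import MicrohomologyPattern
from .scanner import CandidateSite

__all__ = [
    "read_fasta",
    "write_report",
    "read_report",
    "load_config",
    "config_hash",
    "patterns_to_frame",
    "sites_to_frame",
]

_VALID_FASTA = frozenset("ACGTRYSWKMBDHVN")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercased sequence) pairs.

    Wrapped and unwrapped dialects are both accepted.  Duplicate ids,
    empty records, and non-IUPAC characters (e.g. "U") are rejected
    with the offending record and position named.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty record {rec.id!r} in {path}")
        for i, c in enumerate(seq):
            if c not in _VALID_FASTA:
                raise ValueError(
                    f"invalid character {c!r} at position {i} of record "
                    f"{rec.id!r} in {path}"
                )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def config_hash(config: object) -> str:
    """Short stable hash of any (dataclass or mapping) configuration."""
    if is_dataclass(config) and not isinstance(config, type):
        payload = asdict(config)
    else:
        payload = config
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _fmt(value: object, col: str) -> object:
    if isinstance(value, float):
        if col.endswith("score"):
            return f"{value:.1f}"       # reference display granularity
        return f"{value:.4g}"
    return value


def write_report(
    df: pd.DataFrame, path: str | Path, config: object | None = None
) -> None:
    """Write a CSV report with a commented provenance header."""
    path = Path(path)
    formatted = df.copy()
    for col in formatted.columns:
        formatted[col] = [_fmt(v, col) for v in formatted[col]]
    with open(path, "w", newline="") as fh:
        fh.write(f"# premascan v{__version__}\n")
        fh.write(f"# config_hash={config_hash(config or {})}\n")
        fh.write("# coordinates: *_start 0-based half-open; *_start1 1-based inclusive\n")
        formatted.to_csv(fh, index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def patterns_to_frame(
    locus_id: str, patterns: list[MicrohomologyPattern]
) -> pd.DataFrame:
    cols = [
        "locus_id", "left_start", "right_start", "left_start1", "right_start1",
        "arm_seq", "arm_len", "deletion_len", "intervening_len", "pattern_score",
    ]
    rows = [
        {
            "locus_id": locus_id,
            "left_start": p.left_start,
            "right_start": p.right_start,
            "left_start1": p.left_start + 1,
            "right_start1": p.right_start + 1,
            "arm_seq": p.arm_seq,
            "arm_len": p.arm_len,
            "deletion_len": p.deletion_len,
            "intervening_len": p.intervening_len,
            "pattern_score": p.score,
        }
        for p in patterns
    ]
    return pd.DataFrame(rows, columns=cols)


def sites_to_frame(sites: list[CandidateSite]) -> pd.DataFrame:
    cols = [
        "site_id", "strand", "pam_start", "pam_start1", "cut_index",
        "guide_seq", "group", "criterion1", "criterion2", "ratio",
        "slope_value", "top_pattern_arm", "top_pattern_score",
        "predicted_deletion_len", "frame_shift", "recommended",
        "truncated_guide", "truncated_window",
    ]
    rows = []
    for s in sites:
        prof = s.profile
        top = prof.top_pattern if prof is not None else None
        rows.append(
            {
                "site_id": s.site_id,
                "strand": s.strand,
                "pam_start": s.pam_start,
                "pam_start1": s.pam_start + 1,
                "cut_index": s.cut_index,
                "guide_seq": s.guide_seq,
                "group": prof.group if prof else None,
                "criterion1": prof.criterion1 if prof else None,
                "criterion2": prof.criterion2 if prof else None,
                "ratio": prof.ratio if prof else None,
                "slope_value": prof.slope_value if prof else None,
                "top_pattern_arm": top.arm_seq if top else None,
                "top_pattern_score": top.score if top else None,
                "predicted_deletion_len": (
                    s.predicted.deletion_len if s.predicted else None
                ),
                "frame_shift": s.frame_shift,
                "recommended": s.recommended,
                "truncated_guide": s.truncated_guide,
                "truncated_window": s.truncated_window,
            }
        )
    return pd.DataFrame(rows, columns=cols)
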