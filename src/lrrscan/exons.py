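"""Exon-boundary phasing against the repeat consensus frame.

In genes encoding tandem LRR proteins, exon boundaries tend to recur at a
fixed column of the repeat consensus; here each exon is assigned the
consensus column ("phase", 1-based) at which its first encoded residue
falls, and each exon's encoded peptide is classified as a typical repeat
(right length and consensus fit) or atypical (too short and/or no fit).
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from pathlib import Path
from typing import Sequence

import pandas as pd

from .consensus import (
    DEFAULT_MIN_SCORE,
    ConsensusPattern,
    score_window,
)
from .core import ExonRecord, ProteinRecord, ValidationError
from .segment import RepeatAnnotation


@dataclasses.dataclass(frozen=True)
class ExonClassConfig:
    """Parameters for exon-encoded repeat classification.

    Typical internal repeats are 28-29 residues; the final exon may encode
    a longer C-terminal capping repeat (bounds configurable, default 30-40
    residues, matching capping repeats a handful of residues longer than
    internal ones).  "Atypical" means too short and/or consensus score
    below ``min_score`` - the disjunction is deliberate.
    """

    min_score: float = DEFAULT_MIN_SCORE
    typical_lengths: tuple[int, ...] = (28, 29)
    capping_min: int = 30
    capping_max: int = 40
    exon_range: tuple[int, int] | None = None


def phase_exons(
    exons: Sequence[ExonRecord],
    repeats: Sequence[RepeatAnnotation] | None = None,
    *,
    frame_anchor: int | None = None,
    repeat_length: int = 28,
) -> tuple[list[ExonRecord], int | None]:
    """Fill each exon's phase; return (exons, modal phase).

    With segmenter output available, the phase is the offset of the exon
    start within the repeat (fitting or atypical) that contains it - this
    tolerates mixed 28/29-residue repeats.  Without repeats, a fixed frame
    (``frame_anchor`` = residue position of consensus column 1, plus a
    uniform ``repeat_length``) gives phase
    ``((start - anchor) mod repeat_length) + 1``.  Exons outside the frame
    get phase ``None`` with a warning.
    """
    if repeats is None and frame_anchor is None:
        raise ValidationError("phase_exons needs repeats or a frame_anchor")
    phased: list[ExonRecord] = []
    for exon in exons:
        phase: int | None = None
        if repeats is not None:
            host = next(
                (r for r in repeats if r.start <= exon.protein_start <= r.end),
                None,
            )
            if host is not None:
                phase = exon.protein_start - host.start + 1
        elif exon.protein_start >= frame_anchor:
            phase = (exon.protein_start - frame_anchor) % repeat_length + 1
        if phase is None:
            warnings.warn(
                f"exon {exon.exon_number} at {exon.protein_start} lies outside "
                "the repeat frame; phase undefined",
                stacklevel=2,
            )
        phased.append(dataclasses.replace(exon, phase=phase))
    phases = [e.phase for e in phased if e.phase is not None]
    modal = Counter(phases).most_common(1)[0][0] if phases else None
    return phased, modal


@dataclasses.dataclass(frozen=True)
class ExonClassSummary:
    n_analyzed: int
    n_typical: int
    atypical_exons: tuple[int, ...]
    modal_phase: int | None


def classify_exon_repeats(
    record: ProteinRecord,
    exons: Sequence[ExonRecord],
    patterns: Sequence[ConsensusPattern],
    config: ExonClassConfig = ExonClassConfig(),
    *,
    repeats: Sequence[RepeatAnnotation] | None = None,
    frame_anchor: int | None = None,
) -> tuple[list[ExonRecord], ExonClassSummary]:
    """Classify each exon's encoded peptide as a typical LRR or atypical.

    An exon is scored in the repeat frame implied by its phase: the scored
    window starts ``phase - 1`` residues before the exon (the exon encodes
    the repeat whose consensus it interrupts).  Typical requires length in
    ``typical_lengths`` (the final exon may instead fall in the capping
    bounds) and best consensus score >= ``min_score``.
    """
    if config.exon_range is not None:
        lo, hi = config.exon_range
        exons = [e for e in exons if lo <= e.exon_number <= hi]
    for exon in exons:
        if exon.protein_start < 1 or exon.protein_end > len(record):
            raise ValidationError(
                f"exon {exon.exon_number} span {exon.protein_start}-"
                f"{exon.protein_end} outside sequence of length {len(record)}"
            )
    phased, modal = phase_exons(
        exons,
        repeats,
        frame_anchor=frame_anchor if repeats is None else None,
        repeat_length=patterns[0].length if patterns else 28,
    )
    last_number = max((e.exon_number for e in phased), default=None)
    out: list[ExonRecord] = []
    n_typical = 0
    atypical: list[int] = []
    for exon in phased:
        is_last = exon.exon_number == last_number
        length_ok = exon.length_aa in config.typical_lengths
        capping = (
            is_last
            and config.capping_min <= exon.length_aa <= config.capping_max
        )
        score = _best_frame_score(record, exon, patterns)
        reasons = []
        if not (length_ok or capping):
            reasons.append("length")
        if score is None or score < config.min_score:
            reasons.append("no_fit")
        typical = not reasons
        exon = dataclasses.replace(
            exon,
            typical=typical,
            score=score,
            atypical_reason="+".join(reasons) or None,
        )
        if typical:
            n_typical += 1
        else:
            atypical.append(exon.exon_number)
        out.append(exon)
    summary = ExonClassSummary(
        n_analyzed=len(out),
        n_typical=n_typical,
        atypical_exons=tuple(sorted(atypical)),
        modal_phase=modal,
    )
    return out, summary


def _best_frame_score(
    record: ProteinRecord,
    exon: ExonRecord,
    patterns: Sequence[ConsensusPattern],
) -> float | None:
    """Best pattern score for the repeat frame the exon interrupts.

    Falls back to scoring at the exon start when the phase is unknown.
    Returns ``None`` when no pattern window fits inside the sequence.
    """
    offset = (exon.phase - 1) if exon.phase else 0
    start = exon.protein_start - offset
    best: float | None = None
    for pat in patterns:
        s = start
        if s < 1:
            s = 1
        if s + pat.length - 1 > len(record):
            continue
        score = score_window(record, s, pat).score
        if best is None or score > best:
            best = score
    return best


def write_exon_report(exons: Sequence[ExonRecord], path: str | Path) -> None:
    """TSV report: exon number, span, length, phase, score, flag, reason."""
    df = pd.DataFrame(
        [
            (
                e.exon_number,
                e.protein_start,
                e.protein_end,
                e.length_aa,
                e.phase,
                None if e.score is None else round(e.score, 4),
                e.typical,
                e.atypical_reason,
            )
            for e in exons
        ],
        columns=[
            "exon_number",
            "protein_start",
            "protein_end",
            "length_aa",
            "phase",
            "score",
            "typical",
            "atypical_reason",
        ],
    )
    df.to_csv(path, sep="\t", index=False)
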