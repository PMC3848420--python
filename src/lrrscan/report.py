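"""Architecture report: one machine-readable summary per protein.

Chains segmentation, exon phasing/classification (when an exon table is
supplied), motif scanning and the solenoid-geometry summary into a stable
JSON-serializable document.  Re-running with identical inputs and config
yields an identical report (no timestamps inside the document).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

from . import __version__
from .consensus import ConsensusPattern
from .core import DomainSpan, ExonRecord, ProteinRecord, molecular_weight
from .exons import ExonClassConfig, classify_exon_repeats, write_exon_report
from .motifs import MotifDefinition, scan
from .segment import (
    SegmentConfig,
    UndefinedResultError,
    check_alternation,
    segment,
    threshold_sensitivity,
    write_repeat_table,
)
from .solenoid import SolenoidParams, summarize

#: Reference domain architecture of human NLRC5, as annotated in the
#: literature (1-based inclusive residue spans).  WH and SH bounds are not
#: published as full spans and are therefore not listed.
NLRC5_DOMAINS: tuple[DomainSpan, ...] = (
    DomainSpan("uCARD", 1, 197),
    DomainSpan("NACHT", 198, 369),
    DomainSpan("AxP", 370, 453),
    DomainSpan("linker", 653, 687),
    DomainSpan("LRR", 688, 1866),
)


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"{stage}: {cause}")
        self.stage = stage
        self.cause = cause


REQUIRED_KEYS = (
    "record",
    "tool_version",
    "config",
    "domains",
    "repeats",
    "alternation_fraction",
    "motifs",
    "solenoid",
    "threshold_sensitivity",
)


def build_report(
    record: ProteinRecord,
    patterns: Sequence[ConsensusPattern],
    motif_definitions: Sequence[MotifDefinition],
    *,
    exons: Sequence[ExonRecord] | None = None,
    segment_config: SegmentConfig = SegmentConfig(),
    exon_config: ExonClassConfig = ExonClassConfig(),
    solenoid_params: SolenoidParams = SolenoidParams(),
    domains: Sequence[DomainSpan] | None = None,
) -> dict:
    """Run every stage and assemble the architecture report."""
    try:
        repeats = segment(record, patterns, segment_config)
        sensitivity = threshold_sensitivity(record, patterns, segment_config)
    except Exception as exc:  # pragma: no cover - segmentation is total
        raise StageError("repeat_segmenter", exc) from exc
    fitting = [r for r in repeats if r.fits_consensus]
    try:
        alternation = check_alternation(repeats)
    except UndefinedResultError:
        alternation = None

    exon_section = None
    if exons is not None:
        try:
            classified, summary = classify_exon_repeats(
                record, list(exons), patterns, exon_config, repeats=repeats
            )
        except Exception as exc:
            raise StageError("exon_phaser", exc) from exc
        exon_section = {
            "n_analyzed": summary.n_analyzed,
            "n_typical": summary.n_typical,
            "atypical_exons": list(summary.atypical_exons),
            "modal_phase": summary.modal_phase,
            "exons": [
                {
                    "exon_number": e.exon_number,
                    "protein_start": e.protein_start,
                    "protein_end": e.protein_end,
                    "length_aa": e.length_aa,
                    "phase": e.phase,
                    "score": None if e.score is None else round(e.score, 4),
                    "typical": e.typical,
                    "atypical_reason": e.atypical_reason,
                }
                for e in classified
            ],
        }

    try:
        hits = scan(record, motif_definitions)
    except Exception as exc:  # pragma: no cover - scanning is total
        raise StageError("motif_scanner", exc) from exc

    report = {
        "record": {
            "id": record.id,
            "length_aa": len(record),
            "molecular_weight_kda": round(molecular_weight(record), 3),
            "molecular_weight_kda_monoisotopic": round(
                molecular_weight(record, monoisotopic=True), 3
            ),
        },
        "tool_version": __version__,
        "config": {
            "segment": dataclasses.asdict(segment_config),
            "exon": dataclasses.asdict(exon_config),
            "solenoid": dataclasses.asdict(solenoid_params),
            "patterns": [
                {"name": p.name, "length": p.length, "insertion_site": p.insertion_site}
                for p in patterns
            ],
        },
        "domains": [dataclasses.asdict(d) for d in (domains or ())],
        "repeats": {
            "n_total": len(repeats),
            "n_fitting": len(fitting),
            "n_atypical": len(repeats) - len(fitting),
            "annotations": [dataclasses.asdict(r) for r in repeats],
        },
        "alternation_fraction": alternation,
        "exons": exon_section,
        "motifs": [
            {
                "name": h.name,
                "start": h.start,
                "end": h.end,
                "matched": h.matched,
                "detail": list(h.detail),
            }
            for h in hits
        ],
        "solenoid": summarize(len(repeats), solenoid_params),
        "threshold_sensitivity": sensitivity.to_dict(orient="records"),
    }
    validate_report(report)
    return report


def validate_report(report: dict) -> None:
    """Check the report against the shipped schema (required keys/types)."""
    missing = [k for k in REQUIRED_KEYS if k not in report]
    if missing:
        raise StageError("cli_report", KeyError(f"missing report keys: {missing}"))
    if not isinstance(report["repeats"]["annotations"], list):
        raise StageError("cli_report", TypeError("repeats.annotations must be a list"))


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_tsv_outputs(
    record: ProteinRecord,
    patterns: Sequence[ConsensusPattern],
    prefix: str,
    *,
    exons: Sequence[ExonRecord] | None = None,
    segment_config: SegmentConfig = SegmentConfig(),
    exon_config: ExonClassConfig = ExonClassConfig(),
) -> list[Path]:
    """Write the repeat (and exon) TSV tables next to the JSON report."""
    written: list[Path] = []
    repeats = segment(record, patterns, segment_config)
    path = Path(f"{prefix}.repeats.tsv")
    write_repeat_table(repeats, path)
    written.append(path)
    if exons is not None:
        classified, _ = classify_exon_repeats(
            record, list(exons), patterns, exon_config, repeats=repeats
        )
        path = Path(f"{prefix}.exons.tsv")
        write_exon_report(classified, path)
        written.append(path)
    return written
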