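"""Functional sequence-motif scanning.

Covers the motif families that anchor NLR domain annotation: the Walker A
(P-loop) and Walker B motifs and Sensor 1 of the NACHT NTPase, the AxP/GxP
structural motif, the winged-helix (WH) consensus and its conserved
histidine, basic-cluster nuclear localization signals, and cysteine
spacing patterns of LRR capping motifs (e.g. Cx23Cx5Cx6Cx12C).

Motif class-patterns are literal-alphabet patterns (unlike the repeat
consensus language): plain letters match themselves, ``x``/``X`` matches
any residue and ``[ABC]`` a bracketed residue set.
"""

from __future__ import annotations

import dataclasses
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .core import AMINO_ACIDS, ProteinRecord, ValidationError

_BASIC = frozenset("KR")
_TOKEN_RE = re.compile(r"\[[A-Z]+\]|.")


@dataclasses.dataclass(frozen=True)
class MotifDefinition:
    """One motif to search for.

    ``mode``:
      * ``literal`` - exact substring,
      * ``class`` - literal-alphabet pattern with ``x`` and bracket sets,
      * ``spacing`` - cysteines separated by the given gap lengths
        (``body`` = list of gaps, ``tolerance`` = per-gap slack),
      * ``basic_cluster`` - maximal windows with >= ``min_basics`` K/R
        within ``window`` residues (``body`` = (min_basics, window)),
      * ``position`` - residue-identity check at a fixed position
        (``body`` = (position, residue)).

    ``search_span`` optionally restricts the scan to a 1-based inclusive
    region (used e.g. for the three-residue Sensor 1, which is too short
    for reliable de novo scanning outside the NACHT domain).
    """

    name: str
    mode: str
    body: object
    tolerance: int = 0
    search_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("literal", "class", "spacing", "basic_cluster", "position"):
            raise ValidationError(f"motif {self.name}: unknown mode {self.mode!r}")
        if self.mode == "literal":
            bad = [c for c in self.body if c not in AMINO_ACIDS]
            if bad:
                raise ValidationError(
                    f"motif {self.name}: illegal residue {bad[0]!r} in literal body"
                )
        if self.mode == "spacing":
            if not self.body or any(g < 0 for g in self.body):
                raise ValidationError(
                    f"motif {self.name}: spacing gaps must be non-negative and non-empty"
                )


@dataclasses.dataclass(frozen=True)
class MotifHit:
    """A located motif instance, 1-based inclusive span."""

    name: str
    start: int
    end: int
    matched: str
    detail: tuple[int, ...] = ()


def scan(
    record: ProteinRecord, definitions: Iterable[MotifDefinition]
) -> list[MotifHit]:
    """All non-overlapping (per motif) hits, leftmost first."""
    hits: list[MotifHit] = []
    for d in definitions:
        if d.mode == "literal":
            hits.extend(_scan_literal(record, d))
        elif d.mode == "class":
            hits.extend(_scan_class(record, d))
        elif d.mode == "spacing":
            hits.extend(find_cys_spacing(record, list(d.body), tolerance=d.tolerance, name=d.name))
        elif d.mode == "basic_cluster":
            min_basics, window = d.body
            hits.extend(
                find_basic_cluster(
                    record,
                    min_basics=min_basics,
                    window=window,
                    name=d.name,
                    search_span=d.search_span,
                )
            )
        elif d.mode == "position":
            pos, residue = d.body
            if pos <= len(record) and record.residue(pos) == residue:
                hits.append(MotifHit(d.name, pos, pos, residue, (pos,)))
    return hits


def _span(record: ProteinRecord, d: MotifDefinition) -> tuple[int, int]:
    return d.search_span if d.search_span is not None else (1, len(record))


def _scan_literal(record: ProteinRecord, d: MotifDefinition) -> list[MotifHit]:
    lo, hi = _span(record, d)
    text = record.sequence
    body = str(d.body)
    hits = []
    pos = lo - 1
    while True:
        i = text.find(body, pos, hi)
        if i < 0:
            break
        hits.append(MotifHit(d.name, i + 1, i + len(body), body))
        pos = i + len(body)  # non-overlapping, leftmost first
    return hits


def compile_class_pattern(spec: str) -> list[frozenset[str]]:
    """Compile a literal-alphabet motif pattern into per-position sets."""
    out: list[frozenset[str]] = []
    for token in _TOKEN_RE.findall(spec):
        if token in ("x", "X"):
            out.append(frozenset(AMINO_ACIDS))
        elif token.startswith("["):
            members = token[1:-1]
            bad = [c for c in members if c not in AMINO_ACIDS]
            if bad:
                raise ValidationError(f"illegal residue {bad[0]!r} in {spec!r}")
            out.append(frozenset(members))
        elif token in AMINO_ACIDS:
            out.append(frozenset(token))
        else:
            raise ValidationError(f"illegal token {token!r} in motif pattern {spec!r}")
    return out


def _scan_class(record: ProteinRecord, d: MotifDefinition) -> list[MotifHit]:
    sets = compile_class_pattern(str(d.body))
    lo, hi = _span(record, d)
    m = len(sets)
    seq = record.sequence
    hits = []
    start = lo
    while start + m - 1 <= hi:
        window = seq[start - 1 : start + m - 1]
        if all(ch in s for ch, s in zip(window, sets)):
            hits.append(MotifHit(d.name, start, start + m - 1, window))
            start += m  # non-overlapping
        else:
            start += 1
    return hits


def find_cys_spacing(
    record: ProteinRecord,
    spacing: Sequence[int],
    *,
    tolerance: int = 0,
    name: str = "cys_spacing",
) -> list[MotifHit]:
    """Cysteine chains with the stated inter-Cys gaps (+- tolerance per gap).

    ``spacing`` lists the number of non-Cys residues between consecutive
    cysteines, so ``[23, 5, 6, 12]`` describes Cx23Cx5Cx6Cx12C and a
    tolerance-0 hit spans exactly 51 residues.  The hit span runs from the
    first to the last cysteine; ``detail`` carries the cysteine positions.
    """
    if not spacing:
        raise ValidationError("spacing list must be non-empty")
    cys = [i + 1 for i, ch in enumerate(record.sequence) if ch == "C"]
    cys_set = set(cys)
    chains: list[tuple[int, ...]] = []

    def extend(chain: tuple[int, ...], level: int) -> None:
        if level == len(spacing):
            chains.append(chain)
            return
        base = chain[-1] + spacing[level] + 1
        for cand in range(base - tolerance, base + tolerance + 1):
            if cand in cys_set:
                extend(chain + (cand,), level + 1)

    for start in cys:
        extend((start,), 0)
    return [
        MotifHit(
            name,
            chain[0],
            chain[-1],
            record.slice(chain[0], chain[-1]),
            chain,
        )
        for chain in sorted(set(chains))
    ]


def find_basic_cluster(
    record: ProteinRecord,
    *,
    min_basics: int = 5,
    window: int = 14,
    name: str = "basic_cluster",
    search_span: tuple[int, int] | None = None,
) -> list[MotifHit]:
    """Maximal basic-residue clusters: windows of <= ``window`` residues
    holding >= ``min_basics`` K/R.

    Overlapping qualifying windows are merged and the merged span trimmed
    to its first and last basic residue, so a poly-basic stretch yields a
    single maximal hit rather than a ladder of overlapping ones.  Defaults
    (5 basics in 14 residues) describe a bipartite NLS-sized cluster.
    """
    if window < min_basics:
        raise ValidationError("window must be >= min_basics")
    lo, hi = search_span if search_span is not None else (1, len(record))
    seq = record.sequence
    qualifying: list[tuple[int, int]] = []
    for start in range(lo, hi - window + 2):
        stretch = seq[start - 1 : start + window - 1]
        if sum(1 for ch in stretch if ch in _BASIC) >= min_basics:
            qualifying.append((start, start + window - 1))
    # merge overlapping or adjacent windows
    merged: list[list[int]] = []
    for s, e in qualifying:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    hits = []
    for s, e in merged:
        basics = [i for i in range(s, e + 1) if seq[i - 1] in _BASIC]
        s2, e2 = basics[0], basics[-1]
        hits.append(
            MotifHit(name, s2, e2, record.slice(s2, e2), tuple(basics))
        )
    return hits


def revalidate(record: ProteinRecord, hit: MotifHit, definition: MotifDefinition) -> bool:
    """Check that a reported hit still satisfies its definition in place."""
    if record.slice(hit.start, hit.end) != hit.matched:
        return False
    if definition.mode == "literal":
        return hit.matched == definition.body
    if definition.mode == "class":
        sets = compile_class_pattern(str(definition.body))
        return len(hit.matched) == len(sets) and all(
            ch in s for ch, s in zip(hit.matched, sets)
        )
    if definition.mode == "spacing":
        gaps = [b - a - 1 for a, b in zip(hit.detail, hit.detail[1:])]
        ok_gaps = all(
            abs(g - want) <= definition.tolerance
            for g, want in zip(gaps, definition.body)
        )
        return (
            ok_gaps
            and len(gaps) == len(definition.body)
            and all(record.residue(p) == "C" for p in hit.detail)
        )
    if definition.mode == "basic_cluster":
        return all(record.residue(p) in _BASIC for p in hit.detail)
    if definition.mode == "position":
        pos, residue = definition.body
        return hit.start == pos and record.residue(pos) == residue
    return False


# ---------------------------------------------------------------------------
# Motif config file
# ---------------------------------------------------------------------------

def _parse_body(mode: str, raw: str) -> object:
    if mode in ("literal", "class"):
        return raw
    if mode == "spacing":
        return [int(x) for x in raw.split(",")]
    if mode == "basic_cluster":
        a, b = raw.split(",")
        return (int(a), int(b))
    if mode == "position":
        pos, residue = raw.split(":")
        return (int(pos), residue)
    raise ValidationError(f"unknown motif mode {mode!r}")


def load_motif_config(path: str | Path) -> list[MotifDefinition]:
    """Load motif definitions from a tab-separated config file.

    Columns: name, mode, body, tolerance, search_start, search_end
    (0/0 for an unrestricted scan).
    """
    defs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["name", "mode", "body", "tolerance", "search_start", "search_end"]
        if header != expected:
            raise ValidationError(f"motif config {path}: header must be {expected}")
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, mode, body, tol, lo, hi = line.rstrip("\n").split("\t")
            span = (int(lo), int(hi)) if int(lo) and int(hi) else None
            defs.append(
                MotifDefinition(
                    name=name,
                    mode=mode,
                    body=_parse_body(mode, body),
                    tolerance=int(tol),
                    search_span=span,
                )
            )
    return defs


def default_motifs() -> list[MotifDefinition]:
    """The shipped motif set: NLRC5-numbered literal validation motifs plus
    generalized Walker patterns for non-NLRC5 inputs."""
    ref = resources.files("lrrscan.data").joinpath("motifs.tsv")
    with resources.as_file(ref) as path:
        return load_motif_config(path)
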