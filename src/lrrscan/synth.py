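"""Ground-truth-labelled synthetic proteins and exon tables.

The generator emulates the statistical structure the analysis assumes:
tandem 28/29-residue RI-like repeats sampled from the alternating type-1 /
type-2 consensus patterns, point-mutation noise that respects residue
synonym classes, short degenerate repeat units, flanking non-repeat
sequence, planted functional motifs (Walker A/B, NLS basic cluster,
cysteine capping spacings, ...), and exon tables whose boundaries fall at
a configured consensus column (default 6).

Everything is reproducible from the config seed.  The ``nlrc5_mimic``
preset lays out a full synthetic stand-in with the architecture reported
for human NLRC5 (1866 residues, motifs at their literature coordinates,
exons 7-49 with seven designated degenerate exons); it is a synthetic
construct for end-to-end pipeline validation, not the real sequence.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np

from .consensus import ConsensusPattern, default_patterns
from .core import AMINO_ACIDS, ExonRecord, ProteinRecord, ValidationError


class LayoutError(ValidationError):
    """A planted motif collides with a repeat unit."""


@dataclasses.dataclass(frozen=True)
class PlantedMotif:
    """A motif written into the generated sequence.

    ``kind`` is ``literal`` (``payload`` = residue string written at
    ``start``) or ``positions`` (``payload`` = tuple of (position, residue)
    pairs).  ``allow_overlap`` permits planting inside repeat units (used
    for capping motifs, which genuinely overlap the first repeat).
    """

    name: str
    kind: str
    payload: object
    start: int | None = None
    allow_overlap: bool = False

    def positions(self) -> list[tuple[int, str]]:
        if self.kind == "literal":
            return [(self.start + i, ch) for i, ch in enumerate(str(self.payload))]
        if self.kind == "positions":
            return [(int(p), r) for p, r in self.payload]
        raise ValidationError(f"planted motif {self.name}: unknown kind {self.kind!r}")

    def span(self) -> tuple[int, int]:
        pos = [p for p, _ in self.positions()]
        return min(pos), max(pos)


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic protein.

    ``degenerate_units`` maps 1-based unit indices to their (short)
    lengths; those units carry background sequence instead of a consensus
    sample.  ``cterm_cap`` makes the last unit a C-terminal capping repeat
    whose exon peptide has the given length (internal-repeat consensus
    plus a tail).  ``flank_exclude`` removes residues from the background
    alphabet so planted Cys/basic motifs stay unambiguous.
    """

    n_units: int = 5
    type_policy: str = "alternating"  # or "random"
    degenerate_units: Mapping[int, int] = dataclasses.field(default_factory=dict)
    cterm_cap: int | None = None
    mutation_rate: float = 0.0
    within_class_prob: float = 0.7
    flank_n: int = 50
    flank_c: int = 50
    planted_motifs: tuple[PlantedMotif, ...] = ()
    exon_phase: int = 6
    first_exon_number: int = 1
    flank_exclude: str = "C"
    record_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValidationError("mutation_rate must be in [0,1]")
        if not 0.0 <= self.within_class_prob <= 1.0:
            raise ValidationError("within_class_prob must be in [0,1]")
        if self.type_policy not in ("alternating", "random"):
            raise ValidationError("type_policy must be 'alternating' or 'random'")
        if self.n_units < 1:
            raise ValidationError("n_units must be at least 1")
        for idx, length in self.degenerate_units.items():
            if not 1 <= idx <= self.n_units:
                raise ValidationError(f"degenerate unit index {idx} out of range")
            if not self.exon_phase <= length <= 27:
                raise ValidationError(
                    f"degenerate unit {idx}: length {length} must be in "
                    f"[{self.exon_phase}, 27]"
                )
        if self.cterm_cap is None and self.flank_c < self.exon_phase - 1:
            raise ValidationError(
                "flank_c must cover exon_phase-1 residues past the last unit"
            )


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Planted layout of a generated protein."""

    repeats: tuple[tuple[int, int, str], ...]  # (start, end, type/atypical)
    motifs: Mapping[str, tuple[tuple[int, str], ...]]
    exons: tuple[ExonRecord, ...]
    mutations: tuple[tuple[int, str, str], ...]  # (position, old, new)
    exon_phase: int

    @property
    def fitting_spans(self) -> list[tuple[int, int, str]]:
        return [r for r in self.repeats if r[2] != "atypical"]

    def to_dict(self) -> dict:
        return {
            "repeats": [list(r) for r in self.repeats],
            "motifs": {k: [list(p) for p in v] for k, v in self.motifs.items()},
            "exons": [
                [e.exon_number, e.protein_start, e.protein_end] for e in self.exons
            ],
            "mutations": [list(m) for m in self.mutations],
            "exon_phase": self.exon_phase,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _sample_repeat(pattern: ConsensusPattern, rng: np.random.Generator) -> list[str]:
    out = []
    for p in pattern.positions:
        if p.constrained:
            members = sorted(p.allowed)
        else:
            members = list(AMINO_ACIDS)
        out.append(members[rng.integers(len(members))])
    return out


def _background(n: int, alphabet: str, rng: np.random.Generator) -> list[str]:
    return [alphabet[i] for i in rng.integers(len(alphabet), size=n)]


def generate(
    config: GeneratorConfig,
    patterns: Sequence[ConsensusPattern] | None = None,
) -> tuple[ProteinRecord, GroundTruth]:
    """Generate one protein and its ground truth, reproducibly per seed."""
    if patterns is None:
        patterns = default_patterns()
    pats = [p for p in patterns if p.name in ("type1", "type2")]
    if len(pats) < 2:
        raise ValidationError("generator needs the type1 and type2 patterns")
    by_name = {p.name: p for p in pats}
    rng = np.random.default_rng(config.seed)
    alphabet = "".join(
        ch for ch in AMINO_ACIDS if ch not in set(config.flank_exclude)
    )

    # --- unit layout --------------------------------------------------
    units: list[tuple[str, int]] = []  # (kind, length) kind in type names/"degenerate"
    next_type = "type1"
    for i in range(1, config.n_units + 1):
        if i in config.degenerate_units:
            units.append(("degenerate", config.degenerate_units[i]))
            continue
        if config.type_policy == "alternating":
            t = next_type
            next_type = "type2" if t == "type1" else "type1"
        else:
            t = ("type1", "type2")[rng.integers(2)]
        length = by_name[t].length
        if config.cterm_cap is not None and i == config.n_units:
            length = config.exon_phase - 1 + config.cterm_cap
        units.append((t, length))

    # --- assemble sequence -------------------------------------------
    chars: list[str] = _background(config.flank_n, alphabet, rng)
    starts: list[int] = []
    repeats_gt: list[tuple[int, int, str]] = []
    mutable: list[tuple[int, ConsensusPattern]] = []  # (0-based seq pos of col 1, pattern)
    for i, (kind, length) in enumerate(units, start=1):
        start = len(chars) + 1
        starts.append(start)
        if kind == "degenerate":
            chars.extend(_background(length, alphabet, rng))
            repeats_gt.append((start, start + length - 1, "atypical"))
        else:
            pat = by_name[kind]
            sample = _sample_repeat(pat, rng)
            mutable.append((len(chars), pat))
            chars.extend(sample)
            if length > pat.length:  # C-terminal capping tail
                chars.extend(_background(length - pat.length, alphabet, rng))
            repeats_gt.append((start, start + pat.length - 1, kind))
    last_unit_end = len(chars)
    chars.extend(_background(config.flank_c, alphabet, rng))

    # --- point mutations over consensus-derived positions ------------
    mutations: list[tuple[int, str, str]] = []
    for base, pat in mutable:
        for p in pat.positions:
            idx = base + p.index - 1
            if rng.random() >= config.mutation_rate:
                continue
            old = chars[idx]
            if p.constrained and rng.random() < config.within_class_prob:
                choices = sorted(p.allowed - {old})
            else:
                choices = [c for c in AMINO_ACIDS if c != old]
            if not choices:
                choices = [c for c in AMINO_ACIDS if c != old]
            new = choices[rng.integers(len(choices))]
            chars[idx] = new
            mutations.append((idx + 1, old, new))

    # --- plant motifs -------------------------------------------------
    motif_gt: dict[str, tuple[tuple[int, str], ...]] = {}
    pattern_spans = [(s, e) for s, e, t in repeats_gt if t != "atypical"]
    for motif in config.planted_motifs:
        lo, hi = motif.span()
        if hi > len(chars):
            raise LayoutError(
                f"planted motif {motif.name} at {lo}-{hi} exceeds sequence "
                f"length {len(chars)}"
            )
        if not motif.allow_overlap:
            for s, e in pattern_spans:
                if lo <= e and s <= hi:
                    raise LayoutError(
                        f"planted motif {motif.name} at {lo}-{hi} collides "
                        f"with repeat {s}-{e}"
                    )
        placed = []
        for pos, residue in motif.positions():
            chars[pos - 1] = residue
            placed.append((pos, residue))
        motif_gt[motif.name] = tuple(placed)

    # --- exon table ---------------------------------------------------
    phase = config.exon_phase
    exons: list[ExonRecord] = []
    for i, start in enumerate(starts):
        e_start = start + phase - 1
        if i + 1 < len(starts):
            e_end = starts[i + 1] + phase - 2
        elif config.cterm_cap is not None:
            e_end = start + units[-1][1] - 1
        else:
            e_end = last_unit_end + phase - 1
        exons.append(
            ExonRecord(config.first_exon_number + i, e_start, e_end)
        )

    record = ProteinRecord(
        id=config.record_id,
        sequence="".join(chars),
        description=f"synthetic tandem-LRR protein (seed {config.seed})",
    )
    truth = GroundTruth(
        repeats=tuple(repeats_gt),
        motifs=motif_gt,
        exons=tuple(exons),
        mutations=tuple(mutations),
        exon_phase=phase,
    )
    return record, truth


def shuffle_null(record: ProteinRecord, seed: int) -> ProteinRecord:
    """Residue-composition-preserving permutation of a sequence."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(record.sequence))
    shuffled = "".join(record.sequence[i] for i in perm)
    return ProteinRecord(
        id=f"{record.id}_shuffled",
        sequence=shuffled,
        description=f"shuffled null of {record.id} (seed {seed})",
    )


# ---------------------------------------------------------------------------
# NLRC5-mimic preset
# ---------------------------------------------------------------------------

#: Degenerate (too short / non-consensus) units of the mimic, keyed by unit
#: index; unit i is encoded by exon i+6, so these are exons 11, 12, 16, 17,
#: 21, 26 and 30.  Lengths are 20-21 residues, sized so the stand-in spans
#: residues 688-1866 like the domain it imitates.
MIMIC_DEGENERATE: dict[int, int] = {5: 20, 6: 20, 10: 20, 11: 20, 15: 20, 20: 20, 24: 21}

MIMIC_MOTIFS: tuple[PlantedMotif, ...] = (
    PlantedMotif("walker_a", "literal", "GKAGMGKT", start=228),
    PlantedMotif("walker_b", "literal", "LLIFDGLDEAL", start=303),
    PlantedMotif("sensor1", "literal", "TSR", start=345),
    PlantedMotif("axp", "literal", "AVP", start=404),
    PlantedMotif("wh_consensus", "literal", "FYAKDI", start=475),
    PlantedMotif("wh_his", "positions", ((491, "H"),)),
    PlantedMotif(
        "nls_basic_cluster",
        "positions",
        ((121, "K"), (122, "R"), (132, "R"), (133, "R"), (134, "K")),
    ),
    PlantedMotif(
        "lrr_n_capping",
        "positions",
        ((648, "C"), (672, "C"), (678, "C"), (685, "C"), (698, "C")),
        allow_overlap=True,
    ),
)


def nlrc5_mimic(seed: int = 0, *, mutation_rate: float = 0.02) -> GeneratorConfig:
    """Config for the synthetic NLRC5 stand-in.

    43 repeat units starting at residue 688, alternating types with seven
    designated degenerate units, a 36-residue C-terminal capping exon,
    exons numbered 7-49 with phase-6 boundaries, and all validation motifs
    planted at their literature coordinates.  Background excludes C, K and
    R so the planted cysteine capping pattern and NLS cluster are the only
    such signals outside the repeats.
    """
    return GeneratorConfig(
        n_units=43,
        type_policy="alternating",
        degenerate_units=MIMIC_DEGENERATE,
        cterm_cap=36,
        mutation_rate=mutation_rate,
        within_class_prob=0.7,
        flank_n=687,
        flank_c=0,
        planted_motifs=MIMIC_MOTIFS,
        exon_phase=6,
        first_exon_number=7,
        flank_exclude="CKR",
        record_id="NLRC5_mimic",
        seed=seed,
    )
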