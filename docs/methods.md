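# Methods

## Scope and model

`lrrscan` annotates the architecture of tandem leucine-rich-repeat (LRR)
proteins of the ribonuclease-inhibitor-like (RI-like) subfamily, with the
NOD-like receptor NLRC5 as the motivating case. The pipeline has four
analytic stages plus a synthetic-data generator used for validation:

1. **Consensus scoring.** An RI-like repeat is 28–29 residues with a
   conserved pattern: the concave-face β-strand motif `LxxLxLxx[NC]xL`
   followed by convex-side constraints. A pattern is an ordered list of
   per-column residue-class constraints over the synonym classes
   aliphatic {L,I,V}, hydroxyl {S,T}, acid/amide {E,D,Q,N}, basic {R,K},
   a nonpolar class, literal residues and a wildcard. A window's score is
   the *unweighted fraction of constrained columns matched*. This is
   deliberate: the scientific criterion being reproduced is
   presence/absence of consensus residues, not a log-odds profile, so no
   PSSM or HMM machinery is used.
2. **Segmentation.** All windows of either repeat type scoring at or
   above the threshold are candidates; a dynamic program selects the
   maximal-scoring set of non-overlapping windows, with small bonuses for
   tandem adjacency (gap 0, +0.1) and type alternation within a run
   (+0.05) to mirror how RI-like repeats occur (back-to-back, alternating
   A/B-style types). Gaps of 10–27 residues between chained repeats are
   emitted as *atypical* segments (degenerate repeats), not silently
   dropped. Ties between equal-scoring chains resolve toward the chain
   whose first repeat starts most N-terminally, then pattern order, so
   segmentation is deterministic.
3. **Exon phasing.** Each exon is assigned the consensus column at which
   its first encoded residue falls ("phase", 1-based to match consensus
   column numbering). When segmenter output is available the phase is the
   offset within the containing repeat annotation, which tolerates mixed
   28/29-residue repeats; otherwise a fixed frame anchor plus a uniform
   repeat length gives `((start − anchor) mod length) + 1`. Exon-encoded
   peptides are classified *typical* when their length is 28–29 (the
   final exon may instead be a 30–40-residue C-terminal capping repeat)
   AND the consensus score in the frame implied by the exon's phase
   reaches the threshold; *atypical* means too short and/or no fit — the
   disjunction is deliberate, and the per-exon report records which
   condition failed.
4. **Motif scanning and geometry.** Functional motifs are searched as
   literals (the NLRC5 validation coordinates), literal-alphabet class
   patterns (generalized Walker A `[AG]xxxxGK[ST]`, Walker B
   `[LIVMF]×4 DxxDE`), cysteine spacing chains (capping motifs such as
   Cx23Cx5Cx6Cx12C), maximal basic-residue clusters (NLS-sized: ≥5 K/R in
   ≤14 residues), and single-position residue-identity checks (the WH
   histidine). The solenoid module treats the repeat stack as a
   superhelix: `full_turns = n_repeats / repeats_per_turn`, and builds a
   Cα-only trace for visualization.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| repeat lengths | 28 (type 1), 29 (type 2) | residues | RI-like subfamily lengths; type 2 carries the insertion column |
| fit threshold `min_score` | 0.75 | fraction of 15 constrained columns | see calibration below |
| segmentation `max_gap` | 30 | residues | one degenerate repeat unit may separate tandem runs |
| atypical gap bounds | 10–27 | residues | shorter gaps are loops, ≥28 could hold a full repeat |
| exon phase convention | column 6 | consensus column | boundary column observed for repeat-encoding exons; 1-based like the consensus numbering |
| capping exon bounds | 30–40 | residues | C-terminal capping repeats run several residues longer than internal ones (e.g. 36 aa in NLRC5, 34 in RI) |
| NLS cluster | ≥5 basics in ≤14 | residues | the NLRC5 NLS (K121…K134) spans 14 residues with 5 basics |
| solenoid | 21.5 repeats/turn, 4.8 Å rise, 30 Å radius | — | presentation defaults calibrated so a 43-repeat domain closes exactly two circles; *not* measured values. An RI-like single-horseshoe preset (≈16 repeats per ~0.7 turn) is also shipped |

### Threshold calibration

The fit criterion in the source analyses is qualitative ("fits the
consensus"), so the threshold is fixed by a null argument, not by any
dataset: for each constrained column the probability that a random
residue matches its class is small (3/20 for the aliphatic class, 2/20
for basics, 1/20 for glycine, …), so the number of matched columns in
background sequence is a sum of independent Bernoullis. Computed exactly,
a Leu-biased background (the composition of a shuffled repeat protein,
~33% L/I/V) crosses a 0.6 threshold somewhere in a 335-residue sequence
with probability near 1, crosses 0.7 with probability ≈3%, and crosses
0.75 with probability ≈0.2%. Noise-free repeats score exactly 1.0, and at
a 5% per-position mutation rate (30% of mutations leaving the synonym
class) a planted repeat falls below 0.75 with probability ≈7·10⁻⁵. The
default is therefore 0.75; `--min-score` exposes it, and every repeat
count is reported next to a threshold-sensitivity table so users can see
how the count moves with the cut.

The shipped type-1/type-2 patterns each constrain 15 of their columns.
Patterns with fewer than 8 constrained columns are rejected at config
load: an information-poor consensus cannot separate repeats from Leu-rich
background at any usable threshold (a generic 8-column strand-only
pattern already passes 0.75 on shuffled nulls at 6/8 matches).

The exact type-1/type-2 consensus strings of the original manual
alignment are published only as a figure; the shipped pattern file
approximates them with the RI-like subfamily consensus (strand motif plus
convex-side constraints, the two types differing in their convex-side
columns, type 2 carrying the insertion). The pattern file is data, not
code — replace it with exact project-specific strings via `--patterns`.

## Synthetic data: what it emulates, what it does not

The generator plants, per seed: repeats sampled uniformly within each
constrained column's class (wildcards uniform over the 20 residues),
alternating or random type sequences, per-position Bernoulli mutations
(within-class with probability 0.7), degenerate short units, flanks of
uniform background, literal/positional motifs, and an exon table whose
boundaries sit at the configured phase. The flank alphabet can be
depleted (default: no Cys; the NLRC5 mimic also removes K/R) so planted
cysteine-spacing and basic-cluster motifs are the unique such signals
outside the repeat region — a deliberate idealization for unambiguous
ground truth.

The `nlrc5-mimic` preset reproduces the published NLRC5 architecture as a
synthetic stand-in: 1866 residues; repeats from 688; 43 exon-encoded
units (exons 7–49) of which the seven degenerate ones are exons 11, 12,
16, 17, 21, 26 and 30 (20–21 residues each, sized so the repeat region
spans 688–1866); a 36-residue C-terminal capping exon; Walker A/B,
Sensor 1, AxP, WH, NLS and the Cx23Cx5Cx6Cx12C capping cysteines at
their literature coordinates; default mutation rate 0.02. The real
NLRC5 repeats deviate from the consensus in ways uniform within-class
sampling does not capture (position-specific residue preferences,
indels, composition bias), so passing on the mimic demonstrates that the
pipeline recovers the architecture it is pointed at — not that the
shipped patterns equal the original alignment's. In particular, on real
NLRC5 the published sequence-alignment count (33 consensus-fitting
repeats) and the exon-analysis count (36 typical) come from two different
procedures and disagree; one scoring rule cannot plant both, so the
mimic plants the exon-consistent 36 and the sensitivity table carries the
count's dependence on the threshold.

Adjacent degenerate exons (11+12 and 16+17) merge into single ~40-residue
gaps between fitting repeats; such gaps exceed the atypical emission
bounds, so those two regions are reported only through the exon
classification, and the affected exons get phase `None` with a warning.

## Numerical choices and degenerate inputs

- Coordinates are 1-based inclusive everywhere; 0-based half-open
  conversion helpers are internal.
- Molecular weight uses the standard average residue-mass table
  (Biopython's), minus one water per peptide bond, reported in kDa;
  monoisotopic mass is reported alongside. Unknown residues (X) are
  rejected by default because class matching is undefined for them.
- Sequences shorter than one repeat segment to an empty list (not an
  error); alternation is undefined (raises) below two fitting repeats.
- The solenoid trace places residue j of repeat i at helix parameter
  t = i + j/m; the alternating radial offset is solved in closed form so
  every consecutive Cα distance is exactly 3.8 Å, which leaves per-repeat
  rise exact by construction. Parameter sets whose base path already
  exceeds 3.8 Å per residue are rejected. With zero rise and an integer
  repeats-per-turn the trace closes into a planar ring (the wrap-around
  Cα distance equals the bond length).
- PDB output is written directly in fixed-width v3.3 ATOM format (CA
  atoms, GLY, chain A, TER + END); tests read it back with an independent
  parser (biotite).

## Problem sizes used in validation

Property studies run at sizes where exhaustive oracles are feasible and
the suite stays fast: window-scan equivalence on 200-residue sequences,
chain optimality against full subset enumeration on ≤150-residue
sequences, boundary recovery over 20 seeds × 8 repeats at 5% mutation,
and the shuffled null over 100 seeds of a 10-repeat protein. The
acceptance script repeats these at the same sizes with seeds derived from
its `--seed`.

## Known limitations

- The repeat period is fixed by the pattern set (28/29); no de novo
  period inference.
- Scoring is presence/absence; two proteins with equal match counts but
  different residue preferences are indistinguishable.
- Exon protein spans are taken from the input table verbatim; deriving
  them from genomic annotation (CDS phase arithmetic) is the caller's
  responsibility.
- Cysteine-rich regions beyond the explicit spacing pattern are exposed
  only as raw scan results; no density classifier is attempted because no
  quantitative criterion exists for one.
- The solenoid model is a topology sketch: no side chains, no secondary
  structure, no energetics.
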