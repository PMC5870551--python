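# Methods

This note records the models, conventions and numerical choices behind
`cmaptools`, including the decisions made where more than one defensible
convention exists.

## Contact data model

A contact is a pair of 1-based residue positions in the target sequence with
a predictor-native score and distance bounds (default 0–8 Å). Pairs are
stored canonically with `res1_index < res2_index`; residue codes and chain
labels swap along with the indices. Self-pairs are rejected at construction
rather than silently dropped: a self-pair in an input file indicates
malformed data, and discarding it would mask the problem.

Duplicate pairs arriving during parsing follow a keep-first policy with a
warning. Prediction files are conventionally sorted best-first, so the first
occurrence of a pair is its highest-ranked one. `replace` and `error`
policies are available for programmatic construction.

Score sorting is deterministic across platforms: descending raw score, ties
broken by ascending `(res1_index, res2_index)`. Min–max rescaling maps raw
scores into [0, 1] without touching them; when every score is identical the
map carries no ranking information and all scaled scores are set to 0.0
(any constant would be arbitrary; zero signals "no discrimination") with a
warning.

Top-`⌊f·L⌋` selection rounds the contact count down to a whole number. The
product `f·L` is computed as `floor(round(f·L, 9))`: binary floating point
makes products like `0.3 × 10` come out as `2.999…96`, and a naive floor
would select one contact too few. The unit tests check the rule against
exact rational arithmetic over a 4 000-point `(f, L)` grid.

## Matching and precision

`match()` classifies each predicted pair against a reference (structure-
derived) map given the set of structurally resolved residue indices: a pair
present in the reference is a true positive; a pair absent from it with both
residues resolved is a false positive; a pair touching an unresolved residue
stays unknown. Precision is `TP / (TP + FP)` with unknown-status contacts
excluded from both numerator and denominator — a residue the structure does
not resolve makes a prediction unevaluable, not wrong. When a selection
contains no classifiable pair at all, the map-level accessor raises, while
the curve-level evaluator reports the factor as a gap so multi-factor curves
still render.

Both maps must be in the same numbering frame; no implicit re-alignment is
performed because silent realignment hides registration bugs. A window-scan
renumbering helper maps author numbering onto sequence positions when the
structure's residue identities match a unique window of the target sequence
exactly, and refuses (demanding a manual offset) when zero or several
windows match.

## Structure-derived contacts

A residue's representative atom is Cβ, with Cα fallback for glycine or when
Cβ is missing — the CASP convention. Two residues are in contact when their
representative atoms are within 8.0 Å, boundary inclusive; cutoff and
separation filter are configurable. Only the first MODEL of an ensemble file
is used, one chain per evaluation, and alternate locations resolve to the
highest-occupancy conformer. Parsing is limited to PDB-format ATOM records;
that is self-contained and sufficient for desk-scale evaluation inputs.

Evaluation applies the same minimum sequence separation (default 5) to both
the prediction and the structure map so the comparison is like-for-like;
"long-range" operations default to separation ≥ 23, the community
convention.

## Alignment statistics

Pairwise identity is the fraction of alignment columns where both sequences
carry the same non-gap character, with the **full alignment length** as
denominator. Gap positions therefore count against identity. This is the
simplest symmetric convention and makes the Neff definition unambiguous;
alternatives (ungapped-overlap denominators) give different absolute values
and would silently change Neff.

The number of effective sequences is the standard redundancy-corrected
depth: `Neff = Σᵢ 1/|Nᵢ|` where `Nᵢ` is the set of sequences at identity ≥ t
to sequence *i*. The sequence itself always belongs to `Nᵢ` — including when
heavy gapping pushes its full-length self-identity below t — which keeps
every term finite and the bounds `1 ≤ Neff ≤ N` exact. The default threshold
t = 0.8 is the common choice for reweighting in co-evolution pipelines and
is configurable. Accumulation uses exact rational arithmetic so that, e.g.,
six identical sequences give Neff = 1.0 exactly rather than 0.999…;
neighbour tests compare integer match counts against `t·L − 1e-9` to avoid
float-division jitter at exact-threshold identities. The computation is the
exact O(N²L) sum — these are desk-scale inputs and correctness beats
approximate shortcuts.

Coverage-based trimming drops low-coverage sequences first, then shallow
columns, in that order; the first sequence is treated as the query and is
never dropped, because downstream contact indices refer to it.

## File formats

Seventeen contact dialects and four sequence formats are registered, each
with read and write support. The line-oriented dialects share one
table-driven implementation; CASP RR (stateful header/sequence/model blocks)
and CCMpred (dense L×L matrix) have dedicated code. Column layouts are fixed
in the registry descriptors and exercised bit-exactly by round-trip tests.

Conventions:

- Scores are written as fixed-point with six decimals; no scientific
  notation, no locale-dependent decimal commas. Round-trip fixtures
  pre-round scores to six decimals accordingly.
- Each dialect declares the fields it cannot carry (`lossy_fields`); writing
  drops them with a log message, and `restrict_to_representable` computes
  the projection a round-trip preserves. COMSAT carries no score column;
  its contacts read back with raw score 1.0.
- CCMpred matrices must be square; exact-zero off-diagonal cells mean "no
  prediction" and produce no contact (a dense matrix cannot otherwise
  represent a sparse prediction losslessly). On asymmetric input the
  upper-triangle value wins, with a warning above an absolute difference of
  1e-6. Writing requires a known chain length (attached sequence or
  `length_hint`).
- Gap characters `-` and `.` are both accepted on read and normalized to
  `-`. A3M lowercase insert states are kept verbatim by default; a
  `strip_inserts` option removes them to produce a rectangular alignment.
  Stockholm `#=` markup lines are preserved as opaque remarks and not
  regenerated on write.
- The format sniffer only answers when a structural signature is
  unambiguous (CASP RR header, Stockholm magic, `>` records, square numeric
  matrix) and returns `unknown` otherwise — a five-column numeric table
  could be PSICOV or MetaPSICOV, and guessing would misparse silently.
  The EPC-Map preamble is written as `PFRMAT EPC-MAP` so it cannot be
  mistaken for CASP RR's `PFRMAT RR` signature.

## Figures

Every figure function writes the image (PNG/SVG/PDF) and returns a manifest
of the plotted data. The manifest is the testable contract — pixel
comparison is brittle — and is invariant to rendering-only parameters (dpi,
size, colors). For the contact-map scatter every series contributes both
orientations of each pair, so the manifest always holds
`2·(|map| + |second| + |reference|)` points; the rendered figure places the
primary map's canonical orientation above the diagonal and the comparison
map's below. When a reference map is supplied without an explicit
resolved-residue set, the contiguous index span the reference covers is
assumed resolved.

The coverage figure plots per-column non-gap depth (not sorted per-sequence
coverage — the other defensible reading of "coverage figure"); horizontal
guides at depths of 1× and 5× the alignment length reflect common
depth-adequacy rules of thumb and are drawn only when inside the plotted
range.

## Synthetic data

The generators exist so the whole stack is testable offline, and their
defaults define the conditions the test suite runs under.

- **Chains** are self-avoiding walks with a fixed 3.8 Å step (the Cα–Cα
  virtual bond length) and a minimum non-bonded approach of 3.9 Å.
  `compactness` interpolates between a persistent, nearly straight chain
  (0: contacts only at sequence separations ≤ 2) and a walk confined to a
  sphere sized for dense packing (1: many long-range contacts). Proposal
  noise escalates across rejected placements so the center pull cannot trap
  the walk against its own chain; after 300 rejections the walk restarts
  (up to 25 restarts) before failing with advice to lower the compactness.
  This emulates chain connectivity and packing density only — no secondary
  structure, no physical energetics — so tests passing on these chains
  demonstrate bookkeeping correctness, not predictive performance on real
  folds.
- **Predictions** construct their true-positive composition exactly:
  `round(p·n)` pairs drawn from the reference map, ranked above decoys
  drawn from non-contact pairs at the same separation filter, with strictly
  descending scores. Downstream precision values are therefore known by
  construction, with no sampling error.
- **Alignments** descend from one random ancestor with independent
  per-position mutations and gaps per member; the query (first sequence) is
  the ungapped ancestor. Mutation and gap rates map directly onto expected
  identity and coverage, which is what the statistics under test measure.
  There is no co-evolving column model — these alignments exercise depth
  and coverage code, not contact inference.
- All randomness comes from `numpy.random.Generator(PCG64)` with explicit
  seed material; numpy guarantees stream stability across platforms, so
  identical parameters give byte-identical fixtures everywhere.

Problem sizes used by the test suite and the acceptance script — chains of
50–200 residues, alignments up to 30 × 60, 50 round-trip objects per format,
200 precision-oracle triples, a 4 000-point floor-rule grid — were chosen as
the smallest scales at which every code path and edge case is exercised;
all computations are exact at any scale.

## Known limitations

- PDB-format input only; mmCIF, hetero atoms, solvent and inter-chain
  contact evaluation are out of scope.
- The sequence hierarchy has no phylogenetic downweighting; Neff uses flat
  neighbourhood counts.
- Distance-distribution (distogram) representations are not modelled; a
  contact is binary within its distance bounds.
- The renumbering helper requires an exact residue-identity window match;
  structures with point mutations relative to the target sequence need a
  manual offset.
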