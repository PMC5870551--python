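# cmaptools

Residue–residue contact predictions as first-class Python objects.

Co-evolution methods (PSICOV, CCMpred, plmDCA, GREMLIN, EVfold, meta-predictors
and their relatives) all emit the same thing — a scored list of residue pairs
predicted to be in contact in the folded protein — but in mutually
incompatible text dialects. Anyone building on top of these predictions ends
up rewriting the same three tools: format converters, alignment-quality
statistics, and precision evaluation against a known structure. `cmaptools`
packages those tools behind one hierarchical data model, for structural
bioinformaticians who consume or produce contact predictions and for
pipeline authors who need to move between predictors.

## What it computes

**Data model.** Contacts live in a three-tier hierarchy — `Contact` (one
scored pair, 1-based indices, canonical *i* < *j*), `ContactMap` (one
prediction, optionally carrying its target `Sequence`), `ContactFile` (one or
more maps plus metadata) — with a parallel two-tier `Sequence`/`SequenceFile`
hierarchy for alignments.

**Format conversion.** 17 contact dialects (CASP RR, PSICOV, MetaPSICOV,
CCMpred matrices, EVfold, plmDCA, FreeContact, GREMLIN, bbcontacts,
PconsC/2/3, EPC-Map, BCL::Contact, COMSAT, MEMPACK, FLIB) and 4
sequence/alignment formats (FASTA, A3M, Stockholm, JONES) with read *and*
write support behind three entry points: `read`, `write`, `convert`.
Round-trips are lossless over each dialect's representable fields.

**Alignment statistics.** The depth of a multiple sequence alignment drives
co-evolution prediction quality; raw counts overstate it when sequences are
redundant. The number of effective sequences is

```
Neff = Σᵢ 1 / |{ j : id(i, j) ≥ t }|
```

with pairwise identity `id` measured over the full alignment length (gaps
never match), threshold `t = 0.8` by default, and every sequence always a
member of its own neighbourhood. Per-column depth, per-sequence coverage and
coverage-based trimming round out the module.

**Precision evaluation.** Observed contacts are extracted from PDB
coordinates as Cβ–Cβ pairs within 8 Å (Cα for glycine — the CASP convention).
A prediction is pruned of short-range pairs (|i−j| < 5), sorted by score, cut
at the top ⌊f·L⌋ pairs for each factor f (L = target length, rounded down to
a whole number of contacts), and scored as precision = TP/(TP+FP); pairs
touching residues unresolved in the structure are excluded from the ratio
rather than counted against it.

**Figures.** Contact-map scatter (mirrored, or prediction vs. second map
across the diagonal, colored by match status), per-column coverage profiles,
and stepwise precision curves — each returned with a plain-data manifest of
exactly what was plotted, so results are testable without pixel comparison.

## Worked example

```python
from io import StringIO
from cmaptools import io
from cmaptools.core import ContactFile
from cmaptools.msa import alignment_stats
from cmaptools.structure import contacts_from_structure, evaluate
from cmaptools.synthetic import synth_alignment, synth_chain, synth_prediction

# a toy 60-residue chain and a prediction built to be 75% true
sites, seq = synth_chain(60, seed=11, compactness=0.8)
reference = contacts_from_structure(sites, distance_cutoff=8.0, min_separation=5)
prediction = synth_prediction(reference, n_predicted=60, tp_fraction=0.75,
                              seed=5, min_separation=5)

# write as CASP RR, convert to PSICOV
buf = StringIO()
io.write(buf, "casprr", ContactFile(target="toy", maps=[prediction]))
buf.seek(0); out = StringIO()
io.convert(buf, "casprr", out, "psicov")
print("first psicov line:", out.getvalue().splitlines()[0])

# precision at L/2 and L
for r in evaluate(prediction, sites, L=60, factors=(0.5, 1.0)):
    print(f"factor {r.factor}: selected {r.n_selected}, "
          f"TP {r.n_tp}, FP {r.n_fp}, precision {r.precision:.3f}")

# alignment depth corrected for redundancy
aln = synth_alignment(n=20, length=60, mutation_rate=0.08, gap_rate=0.05, seed=3)
stats = alignment_stats(aln, identity_threshold=0.8)
print(f"alignment: {stats.n_sequences} sequences, Neff = {stats.neff:.2f}")
```

prints

```
first psicov line: 7 12 0 8 1.000000
factor 0.5: selected 30, TP 30, FP 0, precision 1.000
factor 1.0: selected 60, TP 45, FP 15, precision 0.750
alignment: 20 sequences, Neff = 4.20
```

The top-L/2 cut selects only the true pairs (they are ranked above every
decoy), so precision is 1.0 there and exactly the constructed 0.75 at full
selection. Twenty alignment members at 8% mutation collapse to ≈ 4 effective
sequences once redundancy at the 0.8 identity threshold is discounted.

The same operations are available from the shell:

```sh
cmaptools convert prediction.rr casprr prediction.psicov psicov
cmaptools msatool alignment.a3m --threshold 0.8
cmaptools precision prediction.rr target.fasta model.pdb --factor 1.0
cmaptools plot peval prediction.rr target.fasta model.pdb -o curve.png
```

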