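# Methods

This note documents the models implemented in `il4kit`, the defaults and
why they were chosen, what the synthetic benchmark does and does not
establish, and the numerical conventions used throughout.

## Problem and data model

The unit of computation is a labelled peptide: an 8–22-residue sequence
over the 20 standard amino acids, marked as an IL4 inducer (positive), a
non-inducer (negative) or unlabeled. Labels come from which input file a
record was read from, never from FASTA headers. Dataset construction
applies, in order: the 8–22 length window, within-class deduplication
(first occurrence kept), and a cross-class conflict check — a sequence
appearing in both classes is an input error rather than being resolved by
a precedence rule, because assay databases give no principled way to pick
a side. Non-standard residue codes (B, J, O, U, X, Z) are rejected in
strict mode or dropped with a warning in lenient mode; every encoding
below is defined only on the 20-letter alphabet.

## Feature encodings

* **AAC / DPC.** Percent composition of residues (20 dims) and of
  overlapping ordered dipeptides (400 dims). Rows sum to 100 exactly;
  column order is fixed alphabetical by one-letter code everywhere, for
  determinism across runs.
* **AAP.** The pair-propensity weight for ordered pair *p* is
  `log((F⁺(p)+ε⁺)/(F⁻(p)+ε⁻))`, where `F±` are relative pair frequencies
  in the positive/negative training set and `ε± = pseudocount / (total
  pairs in that set)` (default pseudocount 1, i.e. scale-free additive
  smoothing; it only prevents `log 0`). Weights are linearly rescaled so
  the largest magnitude is 1, then multiplied elementwise into the
  peptide's DPC vector. Swapping the classes negates every weight. The
  propensity-weighted-composition construction (rather than emitting raw
  propensities of occurring pairs) was chosen because it yields the
  standard fixed 400-length vector and degrades gracefully to DPC when the
  table is uninformative; the choice is recorded in the table's
  provenance.
* **Binary profiles.** One-hot encoding of the first `window` residues
  from the N- or C-terminus (position 1 = the terminal residue; C-terminal
  positions count inward). Peptides shorter than the window are zero-padded
  at the far positions rather than excluded, keeping the matrix
  rectangular; each occupied 20-block contains exactly one 1.
* **Physicochemical summaries.** Eight per-residue scales ship as editable
  tables (Hopp–Woods hydrophilicity, Eisenberg hydrophobicity,
  Kyte–Doolittle hydropathy, unit side-chain charge with His at +0.1,
  Charton steric parameter, Zamyatnin side-chain volume, free-amino-acid
  pI, Mitaku amphiphilicity). The exact source tables behind published
  analyses of this kind are generally not recoverable, so the scale name
  travels with every output and users can substitute their own mapping.
  Summaries are per-peptide sums (optionally over selected 1-based
  terminal positions) and per-position means over the first 15 terminal
  positions; a peptide shorter than a position simply does not contribute
  there.

## Exclusive motif discovery

A motif is an ordered pattern of literal residues, residue-class symbols
and gaps matching 1–5 arbitrary residues (`-` in the text dialect; gaps
may not be adjacent or terminal). Class alphabets: the Betts–Russell
property classes (hydrophobic, polar, small, charged, aromatic, aliphatic)
and the Koolman–Rohm biochemistry-atlas classes (acidic, basic, neutral,
aliphatic, aromatic, sulfur); both groupings are shipped as editable
config since textbook editions differ at the margins. A motif is
*exclusive* when it matches at least `min_support` peptides of its class
(default 3) and zero of the other class on the discovery data.

Search is breadth-first pattern growth: level 1 is every literal and
class symbol with sufficient positive support; each frontier pattern is
extended on the right by a literal, a class symbol, or a gap followed by
either. Positive support is anti-monotone under extension and prunes the
search. Two deliberate choices:

* a pattern that reaches exclusivity is emitted and **not** extended —
  any specialization matches a subset of its peptides, so extension could
  only lower coverage;
* the frontier is capped at a beam width (default 5,000 patterns per
  level, highest support first; ties broken by fewer elements then text,
  which also makes the output invariant to input peptide order).

Match states are kept as per-peptide end-position bitmasks (one uint64, as
peptides are at most 57 residues for this engine), so an extension is two
integer operations on a vector; this is what makes fold-local discovery
inside cross-validation affordable. Model fitting and cross-validation
use a reduced beam of 500 per level: on 500+500-peptide datasets this cuts
a discovery run from ~35 s to ~1.7 s per class alphabet on one CPU, and
the beam affects only how exhaustively the pattern space is enumerated —
exclusivity and support of everything returned are unconditional. Up to
`max_motifs` (100) motifs are returned per alphabet, ranked by coverage;
the hybrid model pools, for each of the three alphabets, the top 10 by
greedy *unique* coverage (each pick maximises peptides not covered by
earlier picks), mirroring the classical two-step motif selection.

Matching is unanchored and implemented by direct end-position
propagation; the test suite verifies agreement with an independently
constructed regular-expression oracle on 10,000+ random pattern/peptide
pairs.

## Classifier and hybrid score

The SVM is a C-SVC (libsvm via scikit-learn) with linear, polynomial
(degree 2–3) or RBF kernel; parameters follow SVMlight vocabulary: `g`
(RBF width), `c` (cost), `j` (extra cost on positive-class errors, mapped
to an asymmetric class weight). Scores are signed decision-function
values, not probabilities, so the classical −1…+1 threshold sweep applies
directly. The hybrid score adds +1 for a positive-exclusive motif hit and
−1 for a negative-exclusive hit; a peptide matching both sides nets 0
(the two weights are independent and additive — no precedence rule is
needed). `hybrid − svm ∈ {−1, 0, +1}` always.

Default per-scheme hyperparameters record the published optima for this
problem class (AAC/DPC: g 0.001, c 3; AAP: g 0.1, c 1; all rbf, j 1).
These were tuned on the original IEDB-derived data; on other datasets
(including the synthetic benchmark) the intended protocol is to re-tune
over the default grid (g ∈ {0.001, 0.01, 0.05, 0.1}, c ∈ {1, 2, 3, 4, 9},
j ∈ {1, 5}, rbf, plus linear/polynomial spot checks) — on the benchmark
g = 0.1 makes the RBF Gram matrix nearly diagonal (median g·d² ≈ 23) and
the model memorises rather than learns.

## Evaluation protocol

Stratified k-fold (default 5) cross-validation: each class is permuted
with a seeded generator and dealt round-robin, so per-class fold sizes
differ by at most one; every peptide is tested exactly once. Metrics are
sensitivity, specificity, accuracy in percent and the MCC, reported at
every threshold from −1.0 to +1.0 in steps of 0.1. Conventions: a score
equal to the threshold counts as positive; a zero factor in the MCC
denominator gives MCC 0; an evaluation with a class absent reports that
class's rate as missing (NaN with a warning), not as 0. The best row is
the maximum MCC, ties broken by higher accuracy then lower threshold.
Both the pooled sweep (all held-out scores tallied together — the
headline, because a threshold means the same thing in every fold) and the
across-fold average of per-fold metrics are available, since published
tables of this kind rarely state which aggregation they used. ROC AUC is
computed from the full score ranking (normalised Mann–Whitney U,
half-credit ties), not from the coarse threshold grid.

**Leakage policy.** By default the AAP table and the motif sets are
fitted inside each training fold. `paper_mode=True` fits both once on the
whole dataset before splitting, replicating the historical protocol and
the optimism it introduces (the original authors themselves note the AAP
whole-data bias). Measured on the default benchmark: paper-mode SVM MCC
0.52 / hybrid 0.60 (10-seed medians, hybrid above SVM in every seed);
leak-free SVM 0.49 / hybrid 0.48 at seed 42. Two honest observations
follow: (i) whole-data fitting inflates apparent performance, and (ii)
under leak-free evaluation the ±1 motif weight adds little here, because
motifs exclusive on the training folds are no longer perfectly exclusive
on held-out peptides. The acceptance check of hybrid-over-SVM ordering
therefore runs in paper-mode, which is the protocol it mirrors.

## Synthetic benchmark

The generator emulates the statistical structure of a cytokine-labelled
MHC class II peptide set without redistributing assay data. Default
scenario (`default_benchmark_scenario()`): 500 peptides per class,
lengths uniform on 8–22, i.i.d. residues from a uniform background with
+2 percentage points added to E, F, K, I in positives and to G, D, L in
negatives (the directions observed in real inducer/non-inducer
comparisons; distributions renormalised, so the realised E gap is ≈1.8
points), and one planted motif per class — `[charged]K-K` in positives,
`L-L-L` in negatives — each overwriting a random window of 35 % of its
class (overwriting, not inserting, preserves the length distribution;
gap lengths are drawn uniformly in 1–5, re-drawn up to 20 times to fit
short peptides, falling back to minimal gaps). A Swiss-Prot-like average
composition table is included for emulating random protein-derived
negatives. Everything derives from one integer seed; the same seed gives
byte-identical FASTA. A manifest records which peptides carry planted
realisations, and every carrier verifiably matches its motif.

What a green benchmark run establishes: the pipeline recovers planted
compositional and motif signal, orderings behave as expected, and a null
scenario (bias and motifs disabled) yields chance-level performance
(best-threshold MCC median within ±0.1 of 0, AUC within ±0.07 of 0.5
over 10 seeds). What it does not establish: anything about MHC-binding
biology, allele restriction, assay noise, or the numerical performance
attainable on real IEDB data — real peptides are not i.i.d. residue
strings, and real discriminative motifs are rarer and weaker than planted
ones.

## Known limitations

* The motif search guarantees the exclusivity/support/ranking contract,
  not equivalence with any historical motif-discovery binary whose
  internal search order is unpublished.
* Decision values from different kernels/configs are not calibrated;
  thresholds are comparable only within one fitted model.
* `pseudocount`, class alphabets and PCP scales are conventions, not
  fitted quantities; all are exposed as editable configuration and
  recorded in provenance.
* Model persistence uses Python pickle: load models only from sources you
  trust.
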