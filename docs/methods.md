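# Methods

## Problem and data model

The task is 3-class classification of screened instances: given a compound
and a concentration, predict whether it increases, decreases, or does not
change glial phagocytic activity. A screen readout is a per-well signal
normalized to the plate median, β (dimensionless, 1.0 = plate-typical
activity); classes follow the fixed thresholds β ≥ 1.3 → *increase*,
β ≤ 0.7 → *decrease*, otherwise *no change*, with the boundaries inclusive
on the outer classes. Replicate (compound, dose) measurements are collapsed
to their median β and re-thresholded; replicate label conflicts are logged,
not hidden. The binary relaxation maps *decrease* → positive and everything
else → negative, leaving record counts and identities untouched.

## Molecular representation

SMILES are parsed with RDKit; multi-fragment inputs (salts) keep the
largest fragment, and atoms are renumbered to RDKit's canonical ranks so
any spelling of a molecule yields the same graph. Atom features are six
fixed-order blocks (total dimension 37): valence one-hot (7 slots),
H-count one-hot (6), hybridization one-hot (5: sp, sp2, sp3, sp3d, other),
element one-hot (11: C N O S F Cl Br I P B + other), heavy-atom degree
one-hot (7), and an aromaticity flag. Out-of-vocabulary values (valence
> 6, degree > 6, > 5 hydrogens, exotic elements) map into the block's last
slot, so featurization is total and never crashes on unusual chemistry.
Bond features (dimension 6) are a bond-type one-hot (single, double,
triple, aromatic — rarer order types are treated as single) plus
conjugation and ring-membership flags. Hydrogens are implicit: counted in
the H block, never graph nodes. Static fingerprints are RDKit Morgan
fingerprints (default radius 3, 1024 bits); scaffolds follow the
Bemis–Murcko convention, with acyclic molecules mapping to an explicit
empty-scaffold sentinel rather than an empty string.

## Diversity analytics

Pairwise dissimilarity between fingerprints uses the cosine distance
(vectors) and the Jaccard dissimilarity (bit supports as sets). The
summary reports distributional statistics over the n(n−1)/2 actual pairs
*and* two aggregate normalizations: `mean` (sum / pair count) and
`halfsq_score` (sum / (n²/2)), a convention that differs from the true pair
count by the factor (n−1)/n. Both are surfaced rather than silently
choosing one; they agree to within 1/n. All-zero fingerprints are an
error, not a silent 0/0 — the caller must filter featureless inputs.
PCA of the bit matrix uses scikit-learn on centered data; an all-identical
input produces zero coordinates with a warning.

## Models

Prediction factorizes as h_c = f_comp(c), o = f_out(h_c, d). The dose is a
single scalar, linearly rescaled to [0, 1] over the training dose ladder
(raw-μM mode is available by config) and concatenated to the embedding.

Embedding families: `static_fp` (the Morgan fingerprint, no training);
`linear` (a shared per-atom MLP followed by mean/sum readout — no topology
at all, which is exactly why it serves as the baseline); and four
message-passing families of the standard formulations: `sage`
(neighbor-mean aggregation with separate self/neighbor weights), `gat`
(single-head attention over incoming edges, self-loops added), `ecc` (a
small MLP maps each bond's features to a per-edge weight matrix), and
`nefp` (neighbor states concatenated with bond features, summed, then
mixed). Readout is mean by default, sum by config. Heads: an MLP trained
by mini-batch cross-entropy with Adam, or a random forest
(scikit-learn) on fingerprint + dose. The forest head is restricted to the
static-fingerprint family and, being imbalance-tolerant, skips
undersampling. All weights use fan-in-scaled uniform initialization; every
source of randomness flows from one seed per run, so refitting with the
same seed reproduces predictions bit for bit, as does a save/load round
trip (single `.npz` archive holding spec, parameters and vocabularies).

The neural stack runs on a purpose-built reverse-mode autodiff core over
numpy (`phagoscreen.autodiff`): dense ops, row gather/scatter for batched
disjoint-union graphs, per-edge matrix–vector products, and a fused
softmax cross-entropy. Every backward rule is checked against central
finite differences in the test suite. Single-head attention was chosen for
`gat` as the minimal faithful variant; multi-head support was not needed
for any property this package asserts.

## Evaluation protocol

Risk assessment uses a stratified 20% holdout touched exactly once; model
selection uses stratified 3-fold cross-validation on the remaining 80%,
with grid search maximizing mean validation macro-AUROC, refit on the full
development set before the single test pass. Stratification is either
*simple* (outcome label) or *complex* (label × molecule-size bin × dose,
with size bins the quartiles of atom counts over the development set).
Strata too small to split merge into coarser keys — (label, dose), then
label — with a warning. The reported ± values are standard deviations over
folds.

Per-epoch undersampling draws a fresh subset each epoch from one seed
stream. The default mode samples every class down to the smallest class
size, so each epoch is exactly balanced while successive epochs rotate
through the majority class (covering >99% of it within 200 epochs at
screen-like imbalance); a variant that only downsamples the majority to
the mean of the other class sizes is available (`mode="mean"`). Macro-AUROC
is the unweighted mean of one-vs-rest AUROCs (scikit-learn, midrank ties);
a class without positives or negatives is an error naming the class, never
a silent skip.

## Virtual screening

A trained model scores a new library at the five screen doses. Per-dose
argmax labels are consolidated: unanimous ladders keep their label, any
disagreement yields *mixed*. Consolidation deliberately uses argmax labels
rather than score averaging, since *mixed* is defined by the outcome
changing with dose. Confidence is the mean over doses of the
consolidated class's probability (a min-over-doses variant is available);
ranking filters to the target class (mixed compounds are never ranked) and
breaks ties by compound id. ATC level-1 tallies count every code of a
multi-coded compound and report unmapped compounds separately.

## The synthetic screen

The real screen is unpublished, so the generator emulates its statistical
shape: ~10³ compounds, the dose ladder {1.39, 2.78, 5.56, 11.11, 22.22} μM,
and an 81/9/10 no-change/increase/decrease marginal. Molecules are built
as sub–ring(pattern)–linker–ring(pattern)–sub from 26 substituents and 16
linkers, with each benzene ring's two attachment points arranged ortho,
meta or para. All arrangements have identical atom-feature multisets, so
substitution patterns are *provably* invisible to the topology-blind
linear family — only the wiring differs. Four planted clauses assign
effects as motif × dose interactions:

| ring patterns | effect   | active doses |
|---------------|----------|--------------|
| ortho + ortho | decrease | ≥ 5.56 μM    |
| ortho + para  | decrease | < 5.56 μM    |
| para + para   | increase | ≥ 5.56 μM    |
| ortho + meta  | increase | < 5.56 μM    |

The pattern-pair frequencies (0.10, 0.10, 0.09, 0.09, remainder
meta-heavy neutral) make the planted label marginal exactly 81/9/10, and
the complementary dose gates make the per-dose label marginal flat: dose
alone predicts nothing, atom composition alone predicts nothing, so any
model that scores above chance must have learned the interaction. Records
not covered by a clause draw labels from a background distribution
adjusted so the overall marginal still lands on the configured baseline.
β values are sampled uniformly inside the band matching each label —
(1.3, 1.8) increase, (0.2, 0.7] decrease, (0.7, 1.3) no change — which
exercises the inclusive/exclusive threshold boundaries; with zero label
noise, re-thresholding β recovers every planted label exactly. The default
label-flip noise is 2%, a nod to the borderline wells of a real assay.
Generated libraries have mean pairwise Jaccard dissimilarity ≈ 0.83 at
n = 200–500 — the high-diversity regime of real screening collections.

What the generator does *not* emulate: real pharmacology, dose–response
curve shapes (effects are step functions of dose), plate artifacts beyond
median normalization, and the scaffold breadth of a real vendor library
(all molecules share the two-ring skeleton). Passing tests therefore show
that the pipeline recovers structure–dose interactions it is pointed at,
not that any architecture would win on the real screen.

## Problem sizes and numerical choices

The shipped experiments use 500 compounds × 5 doses with an 80/20 split —
large enough that the planted-rule experiment separates architectures
decisively (graph attention ≈ 0.92–0.96 held-out macro-AUROC across seeds;
linear ≈ 0.51–0.54) while a full run stays in the minutes range on one
CPU. The planted-rule training configuration is 2 layers, hidden width 64,
sum readout, head [64, 32], Adam at 3 × 10⁻³ for 150 epochs (40 for the
linear baseline, which converges long before that and gains nothing
after). Near-zero cosine distances between identical fingerprints are
snapped to exactly 0 (float roundoff otherwise leaves ~1e-16 residue);
empty aggregation buckets in segment means yield zero rows rather than
NaN; attention softmax subtracts a per-node maximum for stability.

## Known limitations

Stereochemistry, tautomers and protonation states are out of scope (the
parser's canonical form decides identity). The ECC family is the most
expensive (per-edge weight matrices) and the slowest to train at equal
width. Grid search is exhaustive, not adaptive, and there is no nested CV;
the test set estimate is a single draw by design. The generator's pattern
classes cover disubstituted benzenes only — motifs on fused or
heteroaromatic systems would need new templates and SMARTS.
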