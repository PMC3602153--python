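# Methods

This note documents the models, numerical choices and limitations behind
`pdzscan`, in the order data flows through the package.

## Structure model and geometry

PDB input is read through Biopython and reduced to a flat atom list with
0-based, contiguous residue indices per chain (author numbering is kept
for reporting only). Only one model of a multi-model (NMR) file is used,
by default the first. HETATM records, waters and non-standard residues
are discarded; alternate locations resolve to the highest occupancy,
ties broken alphabetically by altloc id.

**Dihedrals.** φ is computed with the atan2 formulation on
(C_{i−1}, N_i, CA_i, C_i), reported in (−180, 180]. Undefined positions
(chain start, missing backbone atoms) are flagged `None`, never silently
zero; in the binary feature encoding an undefined φ contributes 0 to the
positive-φ bit.

**Hydrogen bonds.** The encoding needs only side-chain-involving bonds,
classified as side chain → main-chain amide, side chain → main-chain
carbonyl, or side chain → side chain. Donors and acceptors come from a
fixed per-residue table. Because most inputs carry no hydrogens, the
criterion is donor–acceptor distance ≤ 3.5 Å plus an
antecedent–donor–acceptor angle ≥ 90° (the antecedent is the donor's
bonded heavy atom, falling back to CA). Both cutoffs are arguments.
Backbone–backbone bonds are not reported. These are standard geometric
criteria; the reference software this replaces does not publish its
exact geometry, so the table and cutoffs are deliberately pluggable.

**Solvent accessibility.** Shrake–Rupley with probe 1.4 Å, 960
golden-spiral sphere points per atom, and Chothia van der Waals radii.
Relative accessibility divides each residue's area by an extended
Gly-X-Gly reference (Miller et al. values); ≥ 7% counts as solvent
accessible. Exposure is computed in a canonical molecular frame anchored
on the first three non-collinear atoms, which makes areas *and* the
exposed surface points exactly invariant under rigid motion of the
input — a property the test suite asserts at 1e−9. The point count is a
parameter, so a 10×-density run of the same code serves as a convergence
oracle; the implementation must agree with it within 5% per residue and
with the closed form 4π(r+p)² for an isolated atom within 0.5%.

**Core binding site.** Given domain–peptide complexes, a binding-site
column is any alignment column whose residue has a heavy atom strictly
closer than 4.5 Å to any peptide heavy atom in at least `min_structures`
complexes (default: a majority). The boundary is exclusive and only
heavy atoms vote; these two conventions were genuinely open and are
recorded as configuration. The shipped default site is simply the ten
configured positions of the synthetic fixtures; `derive_core_positions`
reproduces the derivation for real complex sets.

## Feature encoding

The 240-value structure vector is the concatenation, over the ten site
positions, of [50 binaries | 10 areas | 90 electrostatic | 90
hydrophobicity]. Surface properties are deliberately simple, desk-scale
physical models standing behind a pluggable interface:

* electrostatic potential: Coulomb sum over a bundled partial-charge
  table (±1 e on Lys/Arg termini split over symmetric atoms, −0.5 e per
  carboxylate oxygen, small His charges) with distance-dependent
  dielectric ε = 4r, evaluated at exposed Shrake–Rupley points, in
  kcal/(mol·e);
* hydrophobicity: the Kyte–Doolittle index of the residue owning each
  surface point.

Per position, the 9 samples are the exposed points nearest the side
chain's centroid, ordered by distance; distances are rounded to 1e−6 Å
before the stable sort so float noise cannot reorder the selection. A
residue exposing no surface contributes zeros (logged). Everything is
deterministic given the structure — no sampling seed exists to vary.

Peptides use a 5 × 20 one-hot encoding over the alphabet A,C,D,…,Y
(alphabetical one-letter codes); ligand positions are numbered −4…0 with
0 at the C-terminus. Min–max scaling to [0, 1] is fitted on training
domain vectors only; transformed values outside the fitted range are
*not* clamped (an unseen value of 20 after fitting on {0, 10} maps to
2.0), so held-out domains may legitimately leave the unit interval.

## Training data

PWMs use probabilities (count + pc) / (n + 20·pc) and log₂-odds scoring
against a uniform 0.05 background (the background vector is
replaceable). Artificial negatives are drawn uniformly (seeded) from the
bottom quantile (default 0.25) of PWM scores over a peptide pool, never
including a known positive. A peptide is *genomic* when its last four
residues terminate some proteome sequence; training domains need ≥ 4
genomic positives and ≥ 1 negative.

The semi-supervised expansion loop scans the proteome's unique tails,
and for every domain above `hit_threshold` adds its top `per_domain_cap`
hits by decision value (excluding known pairs) as negatives with source
`svm_negative`, retrains, and repeats up to `max_rounds`. Defaults
(cap 10, threshold 1000, 5 rounds) are sized for real proteome scales of
~40k unique tails and thousands of hits per domain; the tests and the
acceptance script use cap 50 and threshold 5 against toy proteomes of a
few hundred tails, the same ~10% ratio of cap to over-prediction. A
retrain whose rescan does not lower the mean hit count keeps its
negatives but is not counted as an accepted round, so the accepted-round
means are non-increasing by construction; all rounds are reported.
Experimental records are never removed, and no peptide may carry both
labels for one domain (checked, an error).

## The classifier

The RBF-kernel dual is solved by scikit-learn's SVC (libSVM). The class
weighting implements the printed tie C⁺ = (n⁺/n⁻) C⁻ exactly, which
with n⁺ < n⁻ *down-weights* the positive class — the opposite of the
common heuristic; `invert_class_weights=True` selects the conventional
n⁻/n⁺ form. Prediction never calls the solver: decision values are
recomputed from the stored support vectors, dual coefficients and bias
via the kernel expansion, with sgn(0) = +1. The test suite verifies the
expansion against both the solver's own decision function (1e−6) and a
brute-force per-support-vector sum (1e−9), plus the dual box and
equality constraints. Grid search maximizes mean inner-CV ROC AUC over
powers-of-two grids (γ ∈ 2^{−15..3}, C⁻ ∈ 2^{−5..15}, 5 inner folds by
default), breaking ties toward smaller C then smaller γ; whether the
original protocol optimized accuracy or AUC, and its fold count, were
unstated, so these are package choices. Models persist as a plain text
archive (header + support-vector rows) that round-trips decision values
bit-for-bit.

## Evaluation

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP);
zero-denominator ratios are reported as `None`, never 0. ROC AUC is the
trapezoidal/midrank estimator (equal to the Mann–Whitney U statistic
over n⁺n⁻, asserted to 1e−9); PR AUC is the step-wise average-precision
estimator, whose random-scorer fixed point is the positive fraction.
Schemes: ten-fold over interactions; leave-12%-of-domains,
leave-8%-of-peptides, and both, each as ten repeated random hold-outs of
whole entities with all their interactions. The similarity-filtered
variant retains a training domain only if its binding-site sequence
identity to *every* test domain is below the threshold (fraction
identity by default; the metric is a parameter), caps training sets at
500 interactions by seeded subsampling, and records empty or
single-class runs as missing rather than zero. The cap's RNG is
decoupled from the fold stream so a degenerate threshold (e.g. 1.01)
reproduces plain leave-domains fold composition exactly. Scalers and any
grid search are refit inside each training fold only.

## Proteome scanning and specificity

Each (domain, unique C-terminal pentapeptide) pair is predicted once;
hits (decision ≥ 0, or a stricter `--min-decision`) expand back to every
protein carrying that tail. Per-domain unique-peptide hit counts are the
over-prediction diagnostic. A domain's specificity PWM is built from its
hit peptides (≥ 4 required, counted with multiplicity) and compared to a
reference by similarity 1 − D/D_max, with D the Euclidean (Frobenius)
distance between probability matrices and D_max = √(2·columns) the
largest distance two column-stochastic matrices can achieve. The fixed
points — 1 for identical matrices, 0 for position-wise disjoint one-hot
consensi — are what the tests pin down; the exact normalization used in
prior work was unavailable, so this documented form is the package's
own and is pluggable. Logos are information-content letter stacks
(Schneider–Stephens heights), a reporting convenience only.

## Synthetic fixtures

The generator emulates the shape of the real problem at desk scale. Toy
domains are a 10-residue β-strand plus a 12-residue α-helix built by
NeRF chain extension at ideal bond geometry, with single pseudo-atom
side chains at Cβ-extended positions carrying the real side chain's
representative atom name (so charges, donors and acceptors resolve).
Two archetypes differ in binding-site chemistry (charged/polar pool
KDERSNQT vs hydrophobic pool LIVFAMYW, plus 2 seeded per-domain site
mutations), and each archetype has a planted 5-position PWM (class
I-like consensus RETQV, class II-like NFDVL; 0.6 probability mass on the
consensus letter). Positives are unique draws from the archetype PWM;
negatives are uniform background rejected whenever they out-score the
weakest positive. Toy proteomes mix PWM-sampled binder tails
(`binder_fraction`) with uniform background tails; binder tails are
*samples*, not bare consensi, because specificity recovery needs peptide
diversity. The default conditions are 20 domains, 30 positives + 60
negatives each, 300-protein proteomes (600–1200 where scans need more
statistics), γ = 0.01 and C⁻ = 4 throughout.

What passing these fixtures does and does not show: the pipeline
recovers a planted, learnable signal through every stage (encoding,
weighting, CV partitioning, scanning, specificity summarization), and
its null behaves correctly under label permutation. The fixtures are not
PDZ folds; they say nothing about homology-model quality, real binding
energetics, or the biological precision of proteome-scale predictions,
which in the real setting is bounded by the sparse negative data this
same expansion procedure exists to mitigate.

## Known limitations

* The electrostatic and hydrophobicity surface models are intentionally
  minimal; absolute values are only meaningful after min–max scaling,
  and conclusions should not rest on their physical magnitudes.
* The H-bond table ignores hydrogens, bifurcated bonds and
  metal-mediated contacts.
* `derive_core_positions` assumes a user-supplied alignment; no multiple
  sequence alignment is computed in-package.
* Reported headline numbers from real phage-display/microarray training
  sets are not reproducible here: that data, the 80+ real structures and
  the external interaction databases are outside this package's scope.
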