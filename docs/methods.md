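# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `kinomanifold`, in the spirit of a model-description
appendix.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Molecule standardization and descriptors

Raw SMILES are standardized by (i) keeping the largest fragment that
contains carbon, with ties broken by heavy-atom count then molecular
weight (bare counter-ions are never chosen; a salt with no organic parent
raises an error); (ii) canonical-tautomer normalization using RDKit's
default tautomer scoring, configured to *retain* sp³ and double-bond
stereo descriptors so stereochemistry survives standardization; and
(iii) canonical SMILES emission.  Standardization is idempotent, which the
test suite checks on every fixture molecule.  Tautomer canonicalization is
version-sensitive: a different RDKit release may pick a different
canonical tautomer for some inputs, changing the emitted string but not
the downstream logic.

The descriptor profile is a fixed, ordered 20-vector covering aromatic
topology (aromatic rings / carbocycles / heterocycles), topological
complexity (ring count, aliphatic carbocycles/heterocycles, bridgehead
atoms), physicochemical properties (molecular weight, logP, QED, synthetic
accessibility score, Labute accessible surface area, Hall–Kier alpha) and
pharmacophoric elements (H-bond donors/acceptors, rotatable bonds, sp³
fraction, stereocenters, amide bonds).  The 20th descriptor is the
aromatic-atom fraction (aromatic atoms / heavy atoms), our concrete
realization of "aromaticity" as a scalar; it is configurable because other
definitions (e.g. aromatic bond fraction) are defensible.  Amide bonds are
counted by `C(=O)N` substructure match without ring restriction;
stereocenters include unassigned centers.  The synthetic-accessibility
score uses the SA-score contrib module shipped with RDKit.

Library filters implement drug-likeness bounds (defaults: MW < 700 Da,
logP ∈ [−4, 6], ≤ 6 rotatable bonds, ≤ 12 HBD, ≤ 12 HBA) plus a
biologically-relevant-element whitelist (C, N, O, F, S, P, Cl, Br, I).
Each rejected molecule is charged to the *first* rule it violates, checked
in a fixed order (element, computability, MW, logP, rotatable, HBD, HBA),
so per-rule counts plus the retained count always equal the input count.

Fingerprints are Morgan circular fingerprints, radius 2, folded to 2048
bits (both configurable); Tanimoto similarity is |A∩B|/|A∪B| on the on-bit
sets, with the empty–empty case defined as 1.  Similarity above 0.75 is
reported as "high similarity" throughout.

## The autoencoder

The latent model is a character-level variational autoencoder implemented
directly in NumPy: SMILES are tokenized (two-character elements and
bracket atoms are atomic tokens), one-hot encoded to a fixed maximum
length, and mapped by a single-hidden-layer MLP encoder to a Gaussian
posterior whose mean is the deterministic embedding.  The decoder is a
single-hidden-layer MLP from the latent point to per-position softmax
logits; stochastic decoding samples every position independently at a
configurable temperature and truncates at the first end/pad token.  This
position-factorized decoder was chosen over a recurrent one as the
simplest architecture that supports the full encode/stochastic-decode
contract and trains to exact reconstruction on desk-scale corpora in
seconds; the embedding interface is duck-typed (`encode`,
`sample_smiles`), so a stronger external encoder can be plugged in without
touching any downstream stage, and the test suite exercises that contract
with a lookup-table fake.

Training uses Adam (default learning rate 1e-3) on cross-entropy plus a
KL term with linear warm-up (default weight 0.05 over 200 epochs), full
trajectory logged, hard abort on non-finite loss.  Defaults: latent
dimension 196 to match the convention for SMILES autoencoder embeddings,
though every desk-scale run in the package configures 8–16; hidden width
256; 1500 epochs.  Determinism: a single config seed drives weight
initialization, shuffling and the reparametrization draws.

Decoding follows a retry protocol: up to `max_attempts` (default 500)
stochastic decodes per latent vector; the first output that parses as a
valid molecule *and* whose canonical SMILES is at least
`min_smiles_length` (default 10) characters long is standardized and
returned with the attempt count; otherwise the vector is reported
undecodable.  Decoded strings are re-canonicalized before the length
check, which makes the filter independent of decoder idiosyncrasies such
as redundant ring-closure digits.  An optional jitter mode perturbs the
latent point per attempt instead of relying on decoder stochasticity
alone.

## The KAL scorer

The Kinase Association Likelihood is a random forest (defaults: 500 trees,
unlimited depth, √p features per split, fixed seed; desk-scale runs use
200 trees) over the 20-descriptor profile.  The training assembly takes
all target-family ligands as positives and, as negatives, all other-family
kinase ligands plus a seeded uniform subsample of the drug-like background
pool — subsampled precisely so the negative majority cannot swamp the
minority positive class.  Molecules appearing in both classes (by
canonical SMILES) are dropped from the negatives with a recorded count.

The score is the forest's positive-class vote fraction in [0, 1].  It is a
*structural likeness* to the target family's chemical space, not a potency
prediction.  Scores above 0.7 are flagged "potential target-family-like";
generated-set reports use a 0.5 baseline for optimizer outputs.

Evaluation defaults to stratified 5-fold cross-validation with pooled
out-of-fold predictions; resubstitution is available by scoring the
training assembly directly with the fitted model.  Metrics follow the
standard confusion-matrix definitions (accuracy = (TP+TN)/all, precision
= TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean), with macro
(unweighted) and support-weighted averages; ROC-AUC is computed as the
Mann–Whitney rank probability with ties counted half, which the tests
verify against exhaustive pair enumeration.  Feature importances are Gini
mean-decrease-in-impurity, normalized to sum to 1.  A multiclass
(per-family) variant trains on the same descriptors; on any library whose
families share descriptor structure the binary target-vs-rest F1 is
expected to exceed the same family's multiclass F1, and the suite checks
that direction on the synthetic library.

## Bayesian optimization

The surrogate is a Gaussian process with a constant × Matérn 5/2 kernel
plus a white-noise term, fitted by scikit-learn; hyperparameters are
re-optimized by maximum marginal likelihood every `refit_period` steps
(default 100) and held fixed in between.  The acquisition is Expected
Improvement with jitter ξ = 0.01,

EI = (μ − y⁺ − ξ)·Φ(u) + σ·φ(u),  u = (μ − y⁺ − ξ)/σ,

with the σ = 0 limit max(μ − y⁺ − ξ, 0); it is maximized by L-BFGS-B from
10 seeded random restarts inside the search box, falling back to the best
random probe if every restart fails.  The search box defaults to the
per-dimension min/max of the embedded reference library expanded by 10% —
a data-driven proxy for "the full latent box" that is well-defined for any
encoder.

The objective maps a latent vector to the KAL score of its decoded
molecule; undecodable vectors score 0 (no molecule ⇒ no kinase likeness),
with a skip mode available by filtering the history.  Unbiased runs
initialize with uniform draws in the box; biased runs prepend the
encodings of reference ligands, which are evaluated and enter the GP
before any acquisition step.  Stopping: a step budget (default 1500) or a
plateau — best-so-far improvement below 0.001 over 100 consecutive steps;
desk-scale runs shrink the budget and window but keep the rules.  Above a
history cap the GP refits on the top half of scores plus a random
complement, bounding the cubic cost.  Per-vector decode seeds are derived
by hashing the rounded latent coordinates, so objective evaluations are
reproducible regardless of evaluation order.

## Cluster-guided remodeling

K-means (seeded k-means++, 10 restarts) partitions the embedded library;
cluster-count selection runs a small remodeling trial per candidate k
(range 2–5) and ranks by valid-output yield with mean pairwise Tanimoto
distance as tie-break, ties going to the smallest k.  Remodeling moves
each encoding a fraction s (default 0.8) toward its nearest centroid and
adds isotropic Gaussian noise.  The noise default is sd = 5.0 in raw
latent units, the full-scale study condition; because desk-scale latent
clouds have per-dimension spreads near 1, campaigns configure a
proportionally small value (0.25) and a relative-to-spread mode is
provided.  Inputs are assigned to clusters by nearest centroid of their
own encoding.  Generated duplicates are merged with multiplicity recorded,
and a per-stage loss ledger (decode-failed, length-filtered,
descriptor-failed) makes the conservation law — every input accounted for
exactly once — checkable, which the suite does with stub harnesses and the
real toy model.

## Landscape diagnostics

PCA is the standard mean-centered orthogonal projection with components
ordered by explained variance.  Kernel density maps use a Gaussian KDE
with Scott's-rule bandwidth on a 200×200 grid spanning the data range
plus a 5% margin; degenerate (zero-variance) inputs raise an error
advising jitter.  Per-family latent statistics report, per family, the
global min/max over all entries and the extrema of per-dimension means and
standard deviations (singleton families report zero spread).
Generated-set reports compute qualifier counts and percentages (rounded
half-up to two decimals to match printed-report style), KAL summaries
among qualifiers, mean and max of per-molecule maximum Tanimoto similarity
to the references, high-similarity counts (> 0.75), property histograms
(integer bins for ring counts, 20 equal-width bins for continuous
properties) and per-origin-family attribution fractions that sum to 1.

## Synthetic fixtures

The toy library emulates the *structure* of a kinase/background corpus,
not its chemistry: three "kinase-like" families (default 50 molecules
each) built from fused bicyclic aromatic cores — quinazoline-,
benzimidazole- and quinoline-like templates — decorated with small
single-attachment substituents via string templates, against a background
(default 180) of acyclic/low-ring fragment chains.  The kinase families
therefore carry ≥ 2 aromatic rings where the background has essentially
none, a deliberately strong, learnable contrast.  Consequences for
interpretation: a saturated KAL AUC on this library demonstrates that the
pipeline recovers a designed signal, not that real kinase/background
discrimination is this easy; real corpora have overlapping property
distributions, activity noise and far larger chemical diversity, none of
which the fixtures model.  Sizes were chosen so every stage (VAE training,
5-fold CV, BO, remodeling) runs in minutes on one CPU while keeping at
least tens of molecules per family for stratified splitting.  The
Gaussian-mixture latent fixture provides exact component labels for
clustering and optimizer tests.

## Campaign orchestration and seeds

A single campaign seed fans out to per-stage seeds via
`sha256("{seed}:{stage}")` truncated to 31 bits — documented so any stage
can be re-run in isolation — and the manifest records every derived seed
and artifact path.  Identical configs reproduce byte-identical generated
sets.

## Known limitations

- The position-factorized decoder cannot model long-range SMILES syntax
  dependencies; away from the training manifold its samples are mostly
  invalid, which the decode-retry protocol handles but does not fix.  This
  mirrors, in exaggerated form, the validity decay any SMILES decoder
  shows in sparse latent regions.
- KAL inherits every bias of its descriptor set; two molecules with
  identical descriptor vectors are indistinguishable regardless of
  scaffold.
- The GP surrogate treats the decode-then-score objective as noiseless
  between refits, though decode stochasticity makes it piecewise constant
  in the seed; per-vector seed derivation keeps it at least deterministic.
- Tautomer canonicalization and SA-score values depend on the RDKit
  version in use.
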