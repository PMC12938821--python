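# kinomanifold

Interpretable, latent-space generative design of kinase-family-targeted
ligands — at desk scale, on synthetic libraries, with every stage of the
pipeline exposed as an importable, testable component.

## The problem

Kinase inhibitors share a conserved ATP-site chemistry: fused aromatic
cores, hinge-region hydrogen-bond acceptors, moderate molecular weight.
Generative models over SMILES embed molecules into a continuous latent
space where these shared features make kinase ligands cluster into a
low-volume manifold.  `kinomanifold` implements a chemistry-first pipeline
for navigating that manifold toward a chosen target family:

1. **chemstore** — standardization (salt stripping, tautomer
   normalization, canonicalization), a fixed 20-descriptor chemical
   profile, Lipinski-style library filters, Morgan-fingerprint Tanimoto
   similarity.
2. **latent_core** — a trainable character-level SMILES variational
   autoencoder with deterministic posterior-mean encoding, stochastic
   temperature-sampled decoding and a decode-retry protocol (up to 500
   attempts per latent vector; decoded SMILES shorter than 10 characters
   are discarded).  Any object exposing `encode`/`sample_smiles` can
   substitute for the built-in model.
3. **kal** — the **Kinase Association Likelihood**: a random forest on the
   20 descriptors, trained on target-family ligands vs. other-family
   ligands plus a subsampled drug-like background.  Its positive-class
   vote fraction estimates the probability a molecule lies in the target
   family's chemical space (a structural likeness score, *not* an activity
   prediction).  Includes precision/recall/F1 reports, rank-statistic
   ROC-AUC and Gini feature importances.
4. **bayesopt** — KAL-guided global search: Gaussian-process surrogate
   (Matérn 5/2, hyperparameters by maximum marginal likelihood, periodic
   refits), Expected Improvement maximized by multi-start L-BFGS-B,
   unbiased (uniform box draws) or biased (encoded reference ligands)
   initialization, plateau and step-budget stopping.
5. **neighborhood** — cluster-guided local remodeling: K-means partitions
   the latent cloud and every molecule is interpolated toward its cluster
   centroid,

   ```
   x* = x + s · (c − x) + ε,   ε ~ N(0, σ² I)
   ```

   with scaling factor `s` (default 0.8) and low-magnitude isotropic noise,
   then decoded, length-filtered and KAL-scored.  `s = 0` is the original
   encoding, `s = 1` the centroid; without noise the contraction identity
   `‖x* − c‖ = (1 − s)‖x − c‖` holds exactly.
6. **landscape** — PCA projection, kernel-density maps, per-family latent
   statistics (global range plus extrema of per-dimension means and
   spreads) and generated-set reports (qualifier fractions, KAL/Tanimoto
   summaries, property histograms, per-origin-family attribution).
7. **synthkit** — seeded synthetic fixtures: a multi-family toy library
   whose kinase-like families are built from fused aromatic scaffold cores
   (quinazoline- and pyrimidine-like) against an acyclic low-ring
   background, plus Gaussian-mixture latent fixtures with known labels.
8. **cli** — configuration-driven campaign orchestration with full seed
   capture (`kinomanifold campaign|vae|kal|bo|sample|report`).

## Worked example

```python
from kinomanifold.kal import (AssemblyPolicy, RfConfig, assemble_training_set,
                              classification_metrics, cross_validated_scores,
                              train_kal, kal_score)
from kinomanifold.synthkit import LibrarySpec, generate_toy_library

library = generate_toy_library(LibrarySpec(seed=11))
positives  = [m for m in library if m.family == "SRC"]
kinase_neg = [m for m in library if m.family in ("LCK", "EGFR")]
background = [m for m in library if m.family == "background"]

assembly = assemble_training_set(positives, kinase_neg, background,
                                 AssemblyPolicy(background_subsample=180, seed=3))
rf = RfConfig(n_estimators=200, seed=3)
y, y_pred, y_score = cross_validated_scores(assembly, rf)
report = classification_metrics(y, y_pred, scores=y_score)
model = train_kal(assembly, rf)
```

Running `python examples/03_kal_scoring.py` prints:

```
training assembly: 50 positives, 280 negatives
stratified 5-fold CV: AUC 1.000, accuracy 1.000, positive-class F1 1.000
KAL(CCCCNc1ncnc2ccccc12) = 0.955  (target-family ligand)
KAL(COCCNCOCCNCCCC(=O)O) = 0.000  (background)
```

The designed contrast — kinase-like families carry two fused aromatic
rings, the background none — is fully learnable, so cross-validated AUC
saturates and a quinazoline scores near 1 while an acyclic background
molecule scores near 0.  `examples/` contains one short script per
capability (standardization/filters, VAE training, KAL, Bayesian
optimization, local remodeling, landscape diagnostics), each printing the
numbers it computes.

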