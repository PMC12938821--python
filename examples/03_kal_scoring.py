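"""Train the Kinase Association Likelihood (KAL) scorer and inspect it.

KAL is a random forest over 20 chemical descriptors that outputs the
probability a molecule lies in the target family's chemical space — a
structural likeness score, not an activity prediction.  The synthetic
library's kinase-like families carry a designed ring-count signal, so the
scorer should separate them from background and rank ring-related
descriptors highly.
"""

from kinomanifold.kal import (
    AssemblyPolicy,
    RfConfig,
    assemble_training_set,
    classification_metrics,
    cross_validated_scores,
    feature_importances,
    kal_score,
    train_kal,
)
from kinomanifold.synthkit import LibrarySpec, generate_toy_library

library = generate_toy_library(LibrarySpec(seed=11))
positives = [m for m in library if m.family == "SRC"]
kinase_neg = [m for m in library if m.family in ("LCK", "EGFR")]
background = [m for m in library if m.family == "background"]

assembly = assemble_training_set(
    positives, kinase_neg, background,
    AssemblyPolicy(background_subsample=len(background), seed=3))
print(f"training assembly: {len(assembly.positives)} positives, "
      f"{len(assembly.negatives)} negatives")

rf = RfConfig(n_estimators=200, seed=3)
y, y_pred, y_score = cross_validated_scores(assembly, rf)
report = classification_metrics(y, y_pred, scores=y_score)
print(f"stratified 5-fold CV: AUC {report.roc_auc:.3f}, "
      f"accuracy {report.accuracy:.3f}, "
      f"positive-class F1 {report.per_class[1]['f1']:.3f}")

model = train_kal(assembly, rf)
print("\ntop-5 Gini feature importances:")
for name, value in feature_importances(model)[:5]:
    print(f"  {name:24s} {value:.3f}")

probe_pos, probe_bg = positives[0], background[0]
print(f"\nKAL({probe_pos.smiles}) = {kal_score(model, probe_pos):.3f}  (target-family ligand)")
print(f"KAL({probe_bg.smiles}) = {kal_score(model, probe_bg):.3f}  (background)")
# Scores near 1 mean the molecule sits squarely in the learned target-family
# chemical space; near 0 means generic drug-like matter.
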