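"""Kinase Association Likelihood (KAL) scoring.

KAL is a chemistry-first similarity score: a random forest trained on the
fixed 20-descriptor profile of a target-family ligand set (positives)
against other-family ligands plus a subsampled drug-like background
(negatives).  The forest's positive-class vote fraction is the probability
that a molecule lies within the target family's chemical space — a
structural likeness score, not an activity prediction.  Molecules scoring
above 0.7 are conventionally flagged "potential target-family-like".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .chemstore import DESCRIPTOR_NAMES, CanonicalMolecule, descriptor_array

#: KAL probability above which a molecule is called "potential target-like".
QUALIFIER_THRESHOLD = 0.7


@dataclass(frozen=True)
class AssemblyPolicy:
    """How the negative class is assembled around the positives."""

    background_subsample: int
    seed: int = 0


@dataclass
class TrainingAssembly:
    """Positives vs. (other-family ligands + subsampled background).

    Classes are disjoint by canonical SMILES; molecules appearing in both
    pools are dropped from the negatives with a logged count.
    """

    positives: List[CanonicalMolecule]
    negatives: List[CanonicalMolecule]
    seed: int
    n_overlap_removed: int = 0

    @property
    def molecules(self) -> List[CanonicalMolecule]:
        return self.positives + self.negatives

    @property
    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.positives) + [0] * len(self.negatives))


def assemble_training_set(
    positives: Sequence[CanonicalMolecule],
    kinase_negatives: Sequence[CanonicalMolecule],
    background_pool: Sequence[CanonicalMolecule],
    policy: AssemblyPolicy,
) -> TrainingAssembly:
    """Build the two-class training set with a seeded background subsample.

    Negatives are all other-family kinase ligands plus a uniform random
    subsample of the background pool of the configured size, keeping the
    negative majority bounded so the minority positive class stays learnable.
    """
    if policy.background_subsample > len(background_pool):
        raise ValueError(
            f"background pool ({len(background_pool)}) smaller than requested "
            f"subsample ({policy.background_subsample})"
        )
    rng = np.random.default_rng(policy.seed)
    picks = rng.choice(len(background_pool), size=policy.background_subsample, replace=False)
    negatives = list(kinase_negatives) + [background_pool[i] for i in sorted(picks)]
    pos_smiles = {m.smiles for m in positives}
    kept = [m for m in negatives if m.smiles not in pos_smiles]
    return TrainingAssembly(
        positives=list(positives),
        negatives=kept,
        seed=policy.seed,
        n_overlap_removed=len(negatives) - len(kept),
    )


@dataclass
class RfConfig:
    n_estimators: int = 500
    max_depth: Optional[int] = None
    max_features: str = "sqrt"
    seed: int = 0


class KalModel:
    """Fitted random-forest scorer bound to the fixed descriptor ordering."""

    def __init__(self, forest: RandomForestClassifier, feature_names=DESCRIPTOR_NAMES):
        self.forest = forest
        self.feature_names = tuple(feature_names)

    @property
    def classes_(self):
        return self.forest.classes_

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability for descriptor rows (binary models)."""
        pos_col = int(np.where(self.forest.classes_ == 1)[0][0])
        return self.forest.predict_proba(X)[:, pos_col]

    def save(self, path) -> None:
        joblib.dump({"forest": self.forest, "feature_names": self.feature_names}, path)

    @classmethod
    def load(cls, path) -> "KalModel":
        blob = joblib.load(path)
        return cls(blob["forest"], blob["feature_names"])


def train_kal(assembly: TrainingAssembly, rf_config: Optional[RfConfig] = None,
              labels: Optional[Sequence] = None) -> KalModel:
    """Fit the forest on the assembly's descriptors.

    ``labels`` overrides the binary positive/negative labels to train the
    multiclass (per-family) variant on the same 20 descriptors.
    """
    rf_config = rf_config or RfConfig()
    y = np.asarray(labels) if labels is not None else assembly.labels
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    X = descriptor_array(assembly.molecules)
    forest = RandomForestClassifier(
        n_estimators=rf_config.n_estimators,
        max_depth=rf_config.max_depth,
        max_features=rf_config.max_features,
        random_state=rf_config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return KalModel(forest)


def kal_score(model: KalModel, mol: CanonicalMolecule) -> float:
    """Positive-class vote fraction for one molecule (deterministic)."""
    return float(model.score_matrix(descriptor_array([mol]))[0])


def kal_scores(model: KalModel, mols: Sequence[CanonicalMolecule]) -> np.ndarray:
    if not mols:
        return np.zeros(0)
    return model.score_matrix(descriptor_array(mols))


def cross_validated_scores(
    assembly: TrainingAssembly,
    rf_config: Optional[RfConfig] = None,
    n_splits: int = 5,
    labels: Optional[Sequence] = None,
):
    """Stratified K-fold pooled out-of-fold predictions.

    Returns ``(y_true, y_pred, y_score)`` where ``y_score`` is the
    positive-class probability (binary labels only; None otherwise).
    """
    rf_config = rf_config or RfConfig()
    y = np.asarray(labels) if labels is not None else assembly.labels
    X = descriptor_array(assembly.molecules)
    binary = set(np.unique(y).tolist()) == {0, 1}
    y_pred = np.empty_like(y)
    y_score = np.full(len(y), np.nan) if binary else None
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rf_config.seed)
    for train_i, test_i in skf.split(X, y):
        forest = RandomForestClassifier(
            n_estimators=rf_config.n_estimators,
            max_depth=rf_config.max_depth,
            max_features=rf_config.max_features,
            random_state=rf_config.seed,
            n_jobs=1,
        )
        forest.fit(X[train_i], y[train_i])
        y_pred[test_i] = forest.predict(X[test_i])
        if binary:
            pos_col = int(np.where(forest.classes_ == 1)[0][0])
            y_score[test_i] = forest.predict_proba(X[test_i])[:, pos_col]
    return y, y_pred, y_score


# ---------------------------------------------------------------------------
# Metrics: confusion counts, precision/recall/F1 report, rank AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1/support plus accuracy and averages.

    Macro averages are unweighted class means; weighted averages are
    support-weighted, mirroring the usual classification-report layout.
    """

    per_class: Dict[object, dict]
    accuracy: float
    macro: dict
    weighted: dict
    roc_auc: Optional[float] = None

    def to_rows(self) -> List[list]:
        rows = [[str(c), v["precision"], v["recall"], v["f1"], v["support"]]
                for c, v in self.per_class.items()]
        n = sum(v["support"] for v in self.per_class.values())
        rows.append(["Macro Avg", self.macro["precision"], self.macro["recall"], self.macro["f1"], n])
        rows.append(["Weighted Avg", self.weighted["precision"], self.weighted["recall"], self.weighted["f1"], n])
        return rows


def confusion_counts(y_true: Sequence, y_pred: Sequence, positive) -> ConfusionCounts:
    """One-vs-rest confusion counts for a given positive class."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if p == positive:
            tp += t == positive
            fp += t != positive
        else:
            fn += t == positive
            tn += t != positive
    return ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))


def classification_metrics(y_true: Sequence, y_pred: Sequence,
                           scores: Optional[Sequence[float]] = None) -> MetricsReport:
    """Accuracy, per-class precision/recall/F1/support and macro/weighted means.

    Accuracy = (TP + TN) / all in the binary case, equivalently the fraction
    of exact label matches in general.  Classes appearing only in the
    predictions get zero support.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if not y_true or len(y_true) != len(y_pred):
        raise ValueError("label lists must be non-empty and equal length")
    classes = sorted(set(y_true) | set(y_pred), key=str)
    per_class = {}
    for c in classes:
        cc = confusion_counts(y_true, y_pred, c)
        per_class[c] = {
            "precision": cc.precision,
            "recall": cc.recall,
            "f1": cc.f1,
            "support": cc.tp + cc.fn,
        }
    n = len(y_true)
    accuracy = sum(t == p for t, p in zip(y_true, y_pred)) / n
    macro = {k: float(np.mean([v[k] for v in per_class.values()])) for k in ("precision", "recall", "f1")}
    weighted = {
        k: float(sum(v[k] * v["support"] for v in per_class.values()) / n)
        for k in ("precision", "recall", "f1")
    }
    auc = None
    if scores is not None:
        auc = roc_auc([1 if t == 1 else 0 for t in y_true], scores)
    return MetricsReport(per_class=per_class, accuracy=accuracy, macro=macro,
                         weighted=weighted, roc_auc=auc)


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-probability AUC: P(score(+) > score(-)), ties counted half.

    Computed via the Mann-Whitney U statistic from midranks, so it is exact
    including tied scores.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: one class absent")
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s))
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0  # midrank (1-based)
        i = j + 1
    rank_sum_pos = ranks[y == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def feature_importances(model: KalModel) -> List[Tuple[str, float]]:
    """Gini (mean-decrease-in-impurity) importances, descending; sum to 1."""
    imp = model.forest.feature_importances_
    pairs = sorted(zip(model.feature_names, imp), key=lambda kv: -kv[1])
    return [(name, float(v)) for name, v in pairs]
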