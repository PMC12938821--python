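"""KAL training assembly, scoring, and the metrics/AUC machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinomanifold.chemstore import CanonicalMolecule
from kinomanifold.kal import (
    AssemblyPolicy,
    RfConfig,
    assemble_training_set,
    classification_metrics,
    confusion_counts,
    cross_validated_scores,
    feature_importances,
    kal_score,
    kal_scores,
    roc_auc,
    train_kal,
)


def _fake_pool(prefix, n):
    # assembly logic only touches .smiles identity, not chemistry
    return [CanonicalMolecule(smiles=f"{prefix}{i}") for i in range(n)]


class TestAssembly:
    def test_published_scale_arithmetic(self):
        """1502 positives + 9000 kinase negatives + 14530 background
        subsample -> 23530 negatives, 25032 total."""
        assembly = assemble_training_set(
            _fake_pool("pos", 1502), _fake_pool("kin", 9000), _fake_pool("bg", 20000),
            AssemblyPolicy(background_subsample=14530, seed=0),
        )
        assert len(assembly.negatives) == 23530
        assert len(assembly.molecules) == 25032

    def test_same_seed_same_subsample(self):
        pools = (_fake_pool("p", 10), _fake_pool("k", 20), _fake_pool("b", 60))
        a = assemble_training_set(*pools, AssemblyPolicy(background_subsample=30, seed=5))
        b = assemble_training_set(*pools, AssemblyPolicy(background_subsample=30, seed=5))
        assert [m.smiles for m in a.negatives] == [m.smiles for m in b.negatives]

    def test_overlap_removed_from_negatives(self):
        pos = _fake_pool("x", 5)
        kin = pos[:2] + _fake_pool("k", 5)  # 2 molecules in both pools
        a = assemble_training_set(pos, kin, _fake_pool("b", 10),
                                  AssemblyPolicy(background_subsample=4, seed=1))
        assert a.n_overlap_removed == 2
        assert not {m.smiles for m in a.positives} & {m.smiles for m in a.negatives}

    def test_small_background_pool_rejected(self):
        with pytest.raises(ValueError):
            assemble_training_set(
                _fake_pool("p", 5), _fake_pool("k", 5), _fake_pool("b", 3),
                AssemblyPolicy(background_subsample=10))


class TestTrainAndScore:
    def test_scores_in_unit_interval(self, kal_model, toy_library):
        scores = kal_scores(kal_model, toy_library[::29])
        assert np.all((scores >= 0) & (scores <= 1))

    def test_training_positive_scores_high(self, kal_model, toy_assembly):
        # resubstitution score of a training positive in the fitted forest
        assert kal_score(kal_model, toy_assembly.positives[0]) >= 0.5

    def test_single_class_rejected(self, toy_assembly):
        with pytest.raises(ValueError):
            train_kal(toy_assembly, labels=[1] * len(toy_assembly.molecules))

    def test_deterministic_under_seed(self, toy_assembly, toy_library):
        m1 = train_kal(toy_assembly, RfConfig(n_estimators=50, seed=9))
        m2 = train_kal(toy_assembly, RfConfig(n_estimators=50, seed=9))
        probe = toy_library[5]
        assert kal_score(m1, probe) == kal_score(m2, probe)


class TestImportances:
    def test_shape_and_normalization(self, kal_model):
        imp = feature_importances(kal_model)
        assert len(imp) == 20
        assert abs(sum(v for _, v in imp) - 1.0) < 1e-9
        assert all(imp[i][1] >= imp[i + 1][1] for i in range(19))


def _brute_force_report(y_true, y_pred):
    classes = sorted(set(y_true) | set(y_pred), key=str)
    out = {}
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[c] = (prec, rec, f1, tp + fn)
    return out


class TestMetrics:
    def test_published_f1_arithmetic(self):
        """F1 from the printed binary positive-class precision/recall."""
        precision, recall = 0.71, 0.86
        f1 = 2 * precision * recall / (precision + recall)
        assert round(f1, 2) == 0.78

    def test_all_correct(self):
        rep = classification_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert rep.accuracy == 1.0
        assert all(v["f1"] == 1.0 for v in rep.per_class.values())

    def test_three_class_toy_matches_hand_tally(self):
        y_true = ["a", "a", "b", "b", "c", "c", "a", "b"]
        y_pred = ["a", "b", "b", "b", "c", "a", "a", "c"]
        rep = classification_metrics(y_true, y_pred)
        expected = _brute_force_report(y_true, y_pred)
        for c, (prec, rec, f1, support) in expected.items():
            assert rep.per_class[c]["precision"] == pytest.approx(prec)
            assert rep.per_class[c]["recall"] == pytest.approx(rec)
            assert rep.per_class[c]["f1"] == pytest.approx(f1)
            assert rep.per_class[c]["support"] == support

    def test_macro_equals_weighted_for_equal_supports(self):
        y_true = [0, 0, 1, 1]
        y_pred = [0, 1, 1, 0]
        rep = classification_metrics(y_true, y_pred)
        for k in ("precision", "recall", "f1"):
            assert rep.macro[k] == pytest.approx(rep.weighted[k])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([], [])

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)),
                    min_size=2, max_size=60))
    @settings(deadline=None, max_examples=60)
    def test_oracle_equivalence_random_labels(self, pairs):
        y_true = [t for t, _ in pairs]
        y_pred = [p for _, p in pairs]
        rep = classification_metrics(y_true, y_pred)
        expected = _brute_force_report(y_true, y_pred)
        for c, (prec, rec, f1, support) in expected.items():
            assert rep.per_class[c]["precision"] == pytest.approx(prec)
            assert rep.per_class[c]["f1"] == pytest.approx(f1)
            assert rep.per_class[c]["support"] == support
        assert rep.accuracy == pytest.approx(
            sum(t == p for t, p in pairs) / len(pairs))

    def test_binary_accuracy_is_tp_plus_tn_over_all(self):
        y_true = [1, 1, 1, 0, 0, 0, 0, 1]
        y_pred = [1, 0, 1, 0, 1, 0, 0, 1]
        cc = confusion_counts(y_true, y_pred, positive=1)
        rep = classification_metrics(y_true, y_pred)
        assert rep.accuracy == pytest.approx((cc.tp + cc.tn) / len(y_true))


def _pairwise_auc(y, s):
    wins = ties = total = 0
    for yi, si in zip(y, s):
        for yj, sj in zip(y, s):
            if yi == 1 and yj == 0:
                total += 1
                wins += si > sj
                ties += si == sj
    return (wins + 0.5 * ties) / total


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_uninformative_scores(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_six_point_toy_matches_pair_enumeration(self):
        y = [1, 0, 1, 0, 1, 0]
        s = [0.9, 0.8, 0.8, 0.3, 0.4, 0.1]
        assert roc_auc(y, s) == pytest.approx(_pairwise_auc(y, s))

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 5)),
                    min_size=4, max_size=40))
    @settings(deadline=None, max_examples=60)
    def test_oracle_equivalence_random_scores(self, pairs):
        y = [t for t, _ in pairs]
        s = [v / 5 for _, v in pairs]
        if len(set(y)) < 2:
            with pytest.raises(ValueError):
                roc_auc(y, s)
        else:
            assert roc_auc(y, s) == pytest.approx(_pairwise_auc(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])


class TestBinaryVersusMulticlass:
    def test_binary_target_f1_exceeds_multiclass(self, toy_library):
        """With families sharing descriptor structure, target-vs-rest F1
        should exceed the same family's F1 in the multiclass model."""
        positives = [m for m in toy_library if m.family == "SRC"]
        others = [m for m in toy_library if m.family != "SRC"]
        assembly = assemble_training_set(
            positives, others, _fake_pool("bgpad", 1),
            AssemblyPolicy(background_subsample=0, seed=2))
        rf = RfConfig(n_estimators=100, seed=2)
        yb, yb_pred, _ = cross_validated_scores(assembly, rf, n_splits=3)
        binary_f1 = classification_metrics(yb, yb_pred).per_class[1]["f1"]
        families = [m.family for m in assembly.molecules]
        ym, ym_pred, _ = cross_validated_scores(assembly, rf, n_splits=3, labels=families)
        multi_f1 = classification_metrics(ym, ym_pred).per_class["SRC"]["f1"]
        assert binary_f1 > multi_f1
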