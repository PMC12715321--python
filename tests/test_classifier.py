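"""Fold assignment, training sanity, and leakage-free patient aggregation."""

import numpy as np
import pytest

import penstroke.classifier as clf
from penstroke.classifier import (
    ClassifierConfig,
    PatientScore,
    assign_folds,
    cross_validate,
    predict,
    train_fold,
)
from penstroke.errors import ConfigurationError, DatasetError
from penstroke.preprocess import InstanceDataset

from conftest import make_toy_instances


def toy_dataset(n_per_class=10, rows_per_subject=4, noise=0.05, seed=0):
    """InstanceDataset of separable toy subjects with several rows each."""
    instances, labels = [], []
    base, base_labels = make_toy_instances(
        n_per_class * rows_per_subject, noise=noise, seed=seed
    )
    # regroup: consecutive rows share a subject
    mapping = {}
    for inst, label in zip(base, base_labels):
        # subj ids from make_toy_instances are unique per instance; regroup
        idx = len(instances)
        subj = f"c{label}-s{(idx % (n_per_class * rows_per_subject)) // rows_per_subject}"
        instances.append(
            type(inst)(subj, inst.task_id, idx % rows_per_subject + 1,
                       inst.raster, inst.calibration, inst.box)
        )
        labels.append(int(label))
        mapping[subj] = int(label)
    return InstanceDataset(
        comparison="HS_vs_PD",
        instances=instances,
        labels=np.asarray(labels),
        subject_to_class=mapping,
        class_names=("HS", "PD"),
    )


class TestAssignFolds:
    def test_balanced_two_class_exact(self):
        mapping = {f"a{i}": 0 for i in range(5)} | {f"b{i}": 1 for i in range(5)}
        assignment = assign_folds(mapping, folds=5, seed=0)
        for fold in range(5):
            members = [s for s, f in assignment.items() if f == fold]
            assert len(members) == 2
            assert sorted(mapping[s] for s in members) == [0, 1]

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        mapping = {f"s{i}": int(rng.random() < 0.6) for i in range(23)}
        if len(set(mapping.values())) < 2:
            mapping["s0"] = 1 - mapping["s0"]
        assignment = assign_folds(mapping, folds=4, seed=2)
        assert set(assignment) == set(mapping)
        assert set(assignment.values()) <= set(range(4))

    def test_study_cohort_fold_sizes(self):
        """25 + 57 subjects in 5 patient-disjoint folds -> sizes 16 or 17."""
        mapping = {f"hs{i}": 0 for i in range(25)} | {f"pd{i}": 1 for i in range(57)}
        assignment = assign_folds(mapping, folds=5, seed=3)
        sizes = np.bincount(list(assignment.values()), minlength=5)
        assert set(sizes.tolist()) <= {16, 17}
        assert sizes.sum() == 82
        for cls in (0, 1):
            per_fold = np.bincount(
                [f for s, f in assignment.items() if mapping[s] == cls], minlength=5
            )
            assert per_fold.max() - per_fold.min() <= 1

    def test_class_smaller_than_folds_rejected(self):
        mapping = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 1}
        with pytest.raises(DatasetError):
            assign_folds(mapping, folds=3, seed=0)

    def test_deterministic(self):
        mapping = {f"s{i}": i % 2 for i in range(20)}
        assert assign_folds(mapping, 5, seed=7) == assign_folds(mapping, 5, seed=7)


class TestTraining:
    def test_separable_toy_reaches_full_training_accuracy(self, toy_instances):
        instances, labels = toy_instances
        model = train_fold(instances, labels, ClassifierConfig(epochs=5, seed=1))
        probs = predict(model, instances)
        assert (((probs >= 0.5).astype(int)) == labels).mean() == 1.0
        losses = [h["train_loss"] for h in model.history]
        assert losses[-1] < losses[0], "training loss must decrease"

    def test_shuffled_labels_give_chance_heldout_accuracy(self):
        instances, labels = make_toy_instances(40, seed=2)
        rng = np.random.default_rng(3)
        shuffled = rng.permutation(labels)
        train_idx = np.arange(0, len(instances), 2)
        test_idx = np.arange(1, len(instances), 2)
        model = train_fold(
            [instances[i] for i in train_idx], shuffled[train_idx],
            ClassifierConfig(epochs=4, seed=4),
        )
        probs = predict(model, [instances[i] for i in test_idx])
        acc = ((probs >= 0.5).astype(int) == shuffled[test_idx]).mean()
        assert abs(acc - 0.5) <= 0.15

    def test_identical_seed_identical_predictions(self, toy_instances):
        instances, labels = toy_instances
        cfg = ClassifierConfig(epochs=2, seed=9)
        p1 = predict(train_fold(instances, labels, cfg), instances)
        p2 = predict(train_fold(instances, labels, cfg), instances)
        assert np.array_equal(p1, p2)

    def test_single_class_training_rejected(self, toy_instances):
        instances, labels = toy_instances
        keep = labels == 0
        with pytest.raises(DatasetError):
            train_fold(
                [i for i, k in zip(instances, keep) if k], labels[keep],
                ClassifierConfig(),
            )

    def test_frozen_backbone_plugin_trains_head_only(self, toy_instances):
        instances, labels = toy_instances

        def mean_pool_features(x):  # crude frozen "backbone": 4x12 block means
            b, h, w = x.shape
            return x.reshape(b, 4, h // 4, 12, w // 12).mean(axis=(2, 4)).reshape(b, -1)

        cfg = ClassifierConfig(
            backbone="pretrained_plugin", feature_fn=mean_pool_features,
            epochs=30, learning_rate=0.5, seed=0,
        )
        model = train_fold(instances, labels, cfg)
        probs = predict(model, instances)
        assert (((probs >= 0.5).astype(int)) == labels).mean() >= 0.95

    def test_plugin_requires_feature_fn(self):
        with pytest.raises(ConfigurationError):
            ClassifierConfig(backbone="pretrained_plugin")


class TestPredict:
    def test_probabilities_complement_to_one(self, toy_instances):
        instances, labels = toy_instances
        model = train_fold(instances, labels, ClassifierConfig(epochs=1, seed=0))
        proba = model.predict_proba(np.stack([i.raster for i in instances[:8]]))
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_duplicated_instance_identical_probability(self, toy_instances):
        instances, labels = toy_instances
        model = train_fold(instances, labels, ClassifierConfig(epochs=1, seed=0))
        batch = [instances[0], instances[5], instances[0]]
        probs = predict(model, batch)
        assert probs[0] == probs[2]

    def test_size_mismatch_rejected(self, toy_instances):
        instances, labels = toy_instances
        model = train_fold(instances, labels, ClassifierConfig(epochs=1, seed=0))
        with pytest.raises(ValueError, match="input_size"):
            model.predict_proba(np.zeros((2, 16, 16)))


class TestCrossValidate:
    def test_constant_scorer_gives_half_lr(self, monkeypatch):
        dataset = toy_dataset()

        class Constant:
            def predict_proba(self, x):
                return np.full((len(x), 2), 0.5)

        monkeypatch.setattr(clf, "train_fold", lambda *a, **k: Constant())
        result = cross_validate(dataset, ClassifierConfig(folds=5, seed=0))
        assert all(s.lr == 0.5 for s in result.patient_scores)

    def test_every_instance_scored_once(self):
        dataset = toy_dataset(n_per_class=5, rows_per_subject=3)
        result = cross_validate(dataset, ClassifierConfig(folds=5, epochs=1, seed=1))
        assert not np.isnan(result.oof_probabilities).any()
        assert len(result.patient_scores) == 10
        assert all(s.n_instances == 3 for s in result.patient_scores)

    def test_lr_invariant_to_instance_order(self, monkeypatch):
        dataset = toy_dataset()

        class ContentScorer:  # deterministic function of instance content
            def predict_proba(self, x):
                p1 = np.clip(x.mean(axis=(1, 2)), 0, 1)
                return np.column_stack([1 - p1, p1])

        monkeypatch.setattr(clf, "train_fold", lambda *a, **k: ContentScorer())
        result_a = cross_validate(dataset, ClassifierConfig(folds=5, seed=0))
        rng = np.random.default_rng(4)
        order = rng.permutation(len(dataset.instances))
        shuffled = InstanceDataset(
            comparison=dataset.comparison,
            instances=[dataset.instances[i] for i in order],
            labels=dataset.labels[order],
            subject_to_class=dataset.subject_to_class,
            class_names=dataset.class_names,
        )
        result_b = cross_validate(shuffled, ClassifierConfig(folds=5, seed=0))
        lrs_a = {s.subject_id: s.lr for s in result_a.patient_scores}
        lrs_b = {s.subject_id: s.lr for s in result_b.patient_scores}
        assert lrs_a == pytest.approx(lrs_b)

    def test_fold_membership_is_leakage_free(self):
        """Each instance is validated by the fold holding its subject."""
        dataset = toy_dataset(n_per_class=5, rows_per_subject=2)
        config = ClassifierConfig(folds=5, epochs=1, seed=2)
        result = cross_validate(dataset, config)
        assignment = result.fold_assignment
        subj_folds = {}
        for inst in dataset.instances:
            subj_folds.setdefault(inst.subject_id, assignment[inst.subject_id])
        # patient-disjoint: one fold per subject, and every subject assigned
        assert set(subj_folds) == set(dataset.subject_to_class)

    def test_leave_one_subject_out_degenerate(self):
        dataset = toy_dataset(n_per_class=3, rows_per_subject=2)
        config = ClassifierConfig(folds=3, epochs=1, seed=0)
        result = cross_validate(dataset, config)
        assert len(result.patient_scores) == 6
        assert not np.isnan(result.oof_probabilities).any()

    def test_separated_cohorts_high_patient_auc(self):
        from penstroke.diagnostics import roc_curve

        dataset = toy_dataset(n_per_class=8, rows_per_subject=4, noise=0.03, seed=5)
        result = cross_validate(dataset, ClassifierConfig(folds=4, epochs=4, seed=6))
        labels = [dataset.subject_to_class[s.subject_id] for s in result.patient_scores]
        roc = roc_curve(result.patient_scores, labels)
        assert roc.auc >= 0.95
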