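"""Training loops, case aggregation and cross-validation plumbing.

Training smoke tests run a reduced feature dimension and two or three epochs
on the tiny shared dataset so the whole file stays in tens of seconds.
"""

import numpy as np
import pytest

from admil_cyto import (CaseResult, PatchSet, TrainConfig, case_max_aggregate,
                        make_cv_splits, predict_bag, run_cross_validation,
                        train_mil, train_supervised)

FAST = dict(feature_dim=32, attention_dim=8)


def _split_bags(bags):
    train = [b for b in bags[:-2]]
    val = bags[-2:]
    return train, val


class TestTrainMIL:
    def test_validation_loss_improves_on_planted_signal(self, tiny_bags):
        train, val = _split_bags(tiny_bags)
        ck = train_mil(train, val, TrainConfig(regime="admil", epochs=3, seed=0, **FAST))
        losses = [h["val_loss"] for h in ck.history]
        assert min(losses) < losses[0]

    def test_fixed_seed_reproduces_the_loss_trajectory(self, tiny_bags):
        train, val = _split_bags(tiny_bags)
        cfg = TrainConfig(regime="mean_mil", epochs=2, seed=5, **FAST)
        h1 = train_mil(train, val, cfg).history
        h2 = train_mil(train, val, cfg).history
        assert h1 == h2

    def test_wrong_regime_is_rejected(self, tiny_bags):
        train, val = _split_bags(tiny_bags)
        with pytest.raises(ValueError, match="train_mil"):
            train_mil(train, val, TrainConfig(regime="supervised", epochs=1))

    def test_single_class_training_set_is_rejected(self, tiny_bags):
        train, val = _split_bags(tiny_bags)
        mono = [b for b in train if b.label == 1]
        with pytest.raises(ValueError, match="single class"):
            train_mil(mono, val, TrainConfig(regime="admil", epochs=1, **FAST))

    def test_mil_batch_size_is_one_bag(self):
        with pytest.raises(ValueError, match="batch_size 1"):
            TrainConfig(regime="admil", batch_size=4)

    def test_prediction_contract(self, tiny_bags):
        train, val = _split_bags(tiny_bags)
        ck = train_mil(train, val, TrainConfig(regime="admil", epochs=2, seed=1, **FAST))
        model = ck.build()
        pred = predict_bag(model, val[0])
        assert 0.0 < pred.probability < 1.0
        assert pred.attention_weights.shape == (val[0].K,)
        assert pred.attention_weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert pred.predicted_label in ("benign", "malignant")


class TestTrainSupervised:
    def test_training_loss_decreases_and_softmax_normalises(self, tiny_bags):
        train, val = _split_bags(tiny_bags)
        size = train[0].instances[0].pixels.shape[0]
        tr = PatchSet.from_bags(train, size)
        va = PatchSet.from_bags(val, size)
        cfg = TrainConfig(regime="supervised", backbone="alexnet_like", epochs=2,
                          seed=0, **FAST)
        ck = train_supervised(tr, va, cfg)
        losses = [h["train_loss"] for h in ck.history]
        assert min(losses) < losses[0]
        model = ck.build()
        probs = model.forward_batch(va.X[:4])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_patch_size_mismatch_is_an_input_error(self, tiny_bags, rng):
        train, val = _split_bags(tiny_bags)
        size = train[0].instances[0].pixels.shape[0]
        cfg = TrainConfig(regime="supervised", epochs=1, seed=0, **FAST)
        ck = train_supervised(PatchSet.from_bags(train, size),
                              PatchSet.from_bags(val, size), cfg)
        with pytest.raises(ValueError, match="input size"):
            ck.build().forward_batch(rng.random((2, 3, 96, 96)).astype(np.float32))


class TestCaseMaxAggregate:
    def test_max_rules(self):
        assert case_max_aggregate([0.2, 0.9, 0.4]) == 0.9
        assert case_max_aggregate([0.1, 0.3]) < 0.5  # all sub-threshold -> benign
        assert case_max_aggregate([0.42]) == 0.42

    def test_empty_input_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            case_max_aggregate([])


class TestCrossValidation:
    def test_every_case_gets_exactly_one_out_of_fold_result(self, tiny_bags):
        splits = make_cv_splits(tiny_bags, n_folds=4, seed=2)
        cfg = TrainConfig(regime="admil", epochs=2, seed=2, **FAST)
        results = run_cross_validation(tiny_bags, splits, cfg)
        assert sorted(r.case_id for r in results) == sorted(b.case_id for b in tiny_bags)
        assert len({r.case_id for r in results}) == len(results)
        for r in results:
            assert 0.0 < r.probability < 1.0

    def test_supervised_regime_aggregates_cases_by_max(self, tiny_bags):
        splits = make_cv_splits(tiny_bags, n_folds=3, seed=1)
        cfg = TrainConfig(regime="supervised", backbone="alexnet_like", epochs=1,
                          seed=1, **FAST)
        results = run_cross_validation(tiny_bags, splits, cfg)
        assert sorted(r.case_id for r in results) == sorted(b.case_id for b in tiny_bags)
        for r in results:
            assert 0.0 < r.probability < 1.0

    def test_splits_must_cover_the_bags(self, tiny_bags):
        splits = make_cv_splits(tiny_bags[:-1], n_folds=3, seed=0)
        with pytest.raises(ValueError, match="cover"):
            run_cross_validation(tiny_bags, splits,
                                 TrainConfig(regime="admil", epochs=1, **FAST))
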