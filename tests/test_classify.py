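"""Classifier training, voting, metric suite and model persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgstream.classify import (
    LabeledDataset,
    evaluate,
    labels_from_scores,
    load_model,
    model_select,
    predict,
    save_model,
    train,
)
from ecgstream.errors import (
    DegenerateTrainingError,
    ModelLoadError,
    SpecificationError,
)
from ecgstream.study import CLASS_ORDER


def _clusters(rng, n_per_class=40, sigma=0.05):
    """Three well-separated Gaussian clusters in 25-D."""
    centers = np.zeros((3, 25))
    centers[0, 0] = 5.0
    centers[1, 5] = 5.0
    centers[2, 10] = 5.0
    X = np.vstack(
        [c + sigma * rng.normal(size=(n_per_class, 25)) for c in centers]
    )
    y = np.repeat(list(CLASS_ORDER), n_per_class)
    return LabeledDataset(X, y)


class TestTrain:
    @pytest.mark.parametrize(
        "kind", ["decision_tree", "logistic_regression", "random_forest"]
    )
    def test_separable_clusters_fit_perfectly(self, kind, rng):
        ds = _clusters(rng)
        model = train(ds, kind, seed=0)
        labels, _ = predict(model, ds.features)
        assert np.mean(labels == ds.labels) == 1.0

    def test_identical_seed_identical_predictions(self, rng):
        ds = _clusters(rng, sigma=1.5)
        probe = rng.normal(size=(20, 25))
        m1 = train(ds, "random_forest", seed=7)
        m2 = train(ds, "random_forest", seed=7)
        np.testing.assert_array_equal(
            predict(m1, probe)[0], predict(m2, probe)[0]
        )

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 25))
        ds = LabeledDataset(X, ["NORMAL"] * 10)
        with pytest.raises(DegenerateTrainingError):
            train(ds, "decision_tree")

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(SpecificationError):
            train(_clusters(rng), "svm")


class TestPredict:
    def test_wrong_feature_width_rejected(self, rng):
        model = train(_clusters(rng), "decision_tree")
        with pytest.raises(SpecificationError):
            predict(model, np.zeros((3, 24)))

    def test_scores_sum_to_one(self, rng):
        ds = _clusters(rng, sigma=2.0)
        model = train(ds, "random_forest", seed=1)
        _, scores = predict(model, ds.features)
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-12)

    def test_unanimous_forest_returns_that_class(self, rng):
        ds = _clusters(rng, sigma=0.01)
        model = train(ds, "random_forest", seed=1)
        # probe exactly at the cluster centres: every tree must agree
        probe = np.zeros((3, 25))
        probe[0, 0] = probe[1, 5] = probe[2, 10] = 5.0
        labels, scores = predict(model, probe)
        assert np.all(scores.max(axis=1) == 1.0)  # all 10 trees agree
        assert list(labels) == list(CLASS_ORDER)

    def test_vote_tie_breaks_to_first_in_class_order(self):
        # constructed 5-vs-5 tie between the first two classes
        scores = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.2, 0.2, 0.2]])
        labels = labels_from_scores(scores)
        assert list(labels) == [CLASS_ORDER[0], CLASS_ORDER[1], CLASS_ORDER[0]]


class TestEvaluate:
    def test_perfect_predictions(self):
        y = ["NORMAL"] * 5 + ["RBBB"] * 5 + ["AF"] * 5
        rep = evaluate(y, y)
        assert rep.accuracy == 100.0
        assert rep.sensitivity == 100.0
        assert rep.specificity == 100.0
        assert rep.fpr == 0.0

    def test_hand_counted_confusion(self):
        # truth -> prediction counts: A:[5,0,0]  B:[1,4,0]  C:[0,0,5]
        a, b, c = CLASS_ORDER
        y_true = [a] * 5 + [b] * 5 + [c] * 5
        y_pred = [a] * 5 + [a] + [b] * 4 + [c] * 5
        rep = evaluate(y_true, y_pred)
        assert rep.accuracy == pytest.approx(100 * 14 / 15)
        assert rep.sensitivity == pytest.approx((100 + 80 + 100) / 3)

    def test_constant_predictor_on_balanced_truth(self):
        a = CLASS_ORDER[0]
        y_true = list(CLASS_ORDER) * 5
        y_pred = [a] * 15
        rep = evaluate(y_true, y_pred)
        assert rep.accuracy == pytest.approx(100 / 3)
        assert rep.per_class[a]["specificity_pct"] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(SpecificationError):
            evaluate(["NORMAL", "AF"], ["NORMAL"])

    @settings(max_examples=100, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from(CLASS_ORDER), st.sampled_from(CLASS_ORDER)
            ),
            min_size=2,
            max_size=1000,
        ).filter(lambda d: len({t for t, _ in d}) >= 2)
    )
    def test_matches_brute_force_confusion_oracle(self, data):
        y_true = [t for t, _ in data]
        y_pred = [p for _, p in data]
        rep = evaluate(y_true, y_pred)
        m = len(data)
        for cls in CLASS_ORDER:
            tp = sum(1 for t, p in data if t == cls and p == cls)
            fp = sum(1 for t, p in data if t != cls and p == cls)
            fn = sum(1 for t, p in data if t == cls and p != cls)
            tn = m - tp - fp - fn
            pc = rep.per_class[cls]
            assert (pc["tp"], pc["fp"], pc["tn"], pc["fn"]) == (tp, fp, tn, fn)
            assert pc["tp"] + pc["fp"] + pc["tn"] + pc["fn"] == m
            # exact complement identity, per class
            assert pc["specificity_pct"] == 100.0 * (1.0 - pc["fpr"])
        assert rep.accuracy == pytest.approx(
            100.0 * sum(1 for t, p in data if t == p) / m
        )
        # identity holds for the macro average too
        assert rep.specificity == 100.0 * (1.0 - rep.fpr)

    def test_auc_is_100_for_perfectly_ranked_scores(self):
        y = ["NORMAL", "NORMAL", "RBBB", "RBBB", "AF", "AF"]
        scores = np.array(
            [
                [0.8, 0.1, 0.1],
                [0.9, 0.05, 0.05],
                [0.1, 0.8, 0.1],
                [0.2, 0.7, 0.1],
                [0.1, 0.1, 0.8],
                [0.05, 0.05, 0.9],
            ]
        )
        rep = evaluate(y, y, scores)
        assert rep.auc == pytest.approx(100.0)


class TestModelSelect:
    def test_perfect_beats_constant(self, rng):
        ds = _clusters(rng)
        good = train(ds, "random_forest", seed=0)
        # degrade a decision tree by training it on shuffled labels
        shuffled = LabeledDataset(
            ds.features, rng.permutation(ds.labels.astype(str))
        )
        bad = train(shuffled, "decision_tree", seed=0)
        best, table = model_select([bad, good], ds)
        assert best is good
        assert len(table) == 2

    def test_exact_tie_selects_first_declared(self, rng):
        ds = _clusters(rng)
        m1 = train(ds, "random_forest", seed=0)
        m2 = train(ds, "random_forest", seed=0)
        best, _ = model_select([m1, m2], ds)
        assert best is m1

    def test_needs_two_candidates(self, rng):
        ds = _clusters(rng)
        with pytest.raises(SpecificationError):
            model_select([train(ds, "decision_tree")], ds)


class TestPersistence:
    def test_save_load_round_trip(self, rng, tmp_path):
        ds = _clusters(rng, sigma=1.0)
        model = train(ds, "random_forest", seed=3)
        probe = rng.normal(size=(30, 25))
        before, _ = predict(model, probe)
        save_model(model, tmp_path / "m.bin")
        loaded = load_model(tmp_path / "m.bin")
        after, _ = predict(loaded, probe)
        np.testing.assert_array_equal(before, after)
        assert loaded.kind == "random_forest"
        assert loaded.hyperparams == {"n_trees": 10}

    def test_corrupt_file_raises_load_error(self, tmp_path):
        path = tmp_path / "bad.bin"
        path.write_bytes(b"ECGSMODL" + b"\xff" * 40)
        with pytest.raises(ModelLoadError):
            load_model(path)

    def test_wrong_magic_raises_load_error(self, tmp_path):
        path = tmp_path / "not.bin"
        path.write_bytes(b"NOTAMODL" + b"\x00" * 40)
        with pytest.raises(ModelLoadError):
            load_model(path)

    def test_version_mismatch_raises_load_error(self, rng, tmp_path):
        import json
        import struct

        ds = _clusters(rng)
        model = train(ds, "decision_tree", seed=0)
        path = tmp_path / "m.bin"
        save_model(model, path)
        raw = bytearray(path.read_bytes())
        (hlen,) = struct.unpack_from("<I", raw, 8)
        header = json.loads(bytes(raw[12 : 12 + hlen]))
        header["version"] = 99
        new_header = json.dumps(header).encode()
        out = raw[:8] + struct.pack("<I", len(new_header)) + new_header + raw[12 + hlen :]
        path.write_bytes(bytes(out))
        with pytest.raises(ModelLoadError):
            load_model(path)
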