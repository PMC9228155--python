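"""Cascade wiring, pair selection, label codec, training and persistence."""

import numpy as np
import pytest

from cascadefis.anfis import Anfis
from cascadefis.cascade import (
    CascadeConfig,
    CascadedAnfis,
    CascadeResults,
    LabelCodec,
    build_modified_architecture,
    load_cascade,
    select_pairs,
    train_cascade,
)
from cascadefis.cascade import _chain_forward, _fit_chain  # internal surface

from conftest import make_separable_groups


class TestArchitecture:
    def test_seven_groups_give_seven_level1_modules_and_seven_levels(self):
        arch = build_modified_architecture(7, 9)
        assert len(arch.levels[0]) == 7
        assert len(arch.levels) == 7

    def test_two_groups_give_two_levels(self):
        arch = build_modified_architecture(2, 9)
        assert len(arch.levels) == 2
        assert len(arch.levels[0]) == 2
        assert len(arch.levels[1]) == 1

    def test_one_group_is_a_single_level(self):
        arch = build_modified_architecture(1, 9)
        assert len(arch.levels) == 1

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_modified_architecture(0, 9)
        with pytest.raises(ValueError):
            build_modified_architecture(3, 0)

    def test_final_level_single_module(self):
        arch = build_modified_architecture(5, 9)
        assert len(arch.levels[-1]) == 1


class TestLabelCodec:
    def test_classes_sorted_and_indexed(self):
        codec = LabelCodec.from_labels(["b", "a", "c", "a"])
        assert codec.classes == ["a", "b", "c"]
        assert list(codec.encode(["a", "b", "c"])) == [0.0, 1.0, 2.0]

    def test_decode_rounds_to_nearest_and_clamps(self):
        codec = LabelCodec(classes=["a", "b", "c"])
        assert codec.decode([0.49])[0] == "a"
        assert codec.decode([0.51])[0] == "b"
        assert codec.decode([-3.0])[0] == "a"
        assert codec.decode([9.0])[0] == "c"

    def test_encode_decode_identity_on_exact_targets(self):
        codec = LabelCodec.from_labels(["x", "y", "z"])
        labels = ["z", "x", "y", "y"]
        assert codec.decode(codec.encode(labels)) == labels

    def test_decode_nan_rejected(self):
        codec = LabelCodec(classes=["a", "b"])
        with pytest.raises(ValueError):
            codec.decode([float("nan")])

    def test_unknown_label_rejected(self):
        codec = LabelCodec(classes=["a"])
        with pytest.raises(ValueError, match="unknown label"):
            codec.encode(["zz"])


class TestPairSelection:
    def test_target_like_candidate_ranks_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (60, 4))
        y = X[:, 2].copy()
        ranked = select_pairs(range(4), X, y)
        assert 2 in ranked[0]
        # exhaustive check: every pair containing column 2 beats the rest
        scores = {p: i for i, p in enumerate(ranked)}
        best_without = min(i for p, i in scores.items() if 2 not in p)
        worst_with = max(i for p, i in scores.items() if 2 in p)
        assert worst_with < best_without

    def test_single_pair_returned_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (30, 2))
        assert select_pairs([0, 1], X, X[:, 0]) == [(0, 1)]

    def test_ranking_is_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 5))
        y = X @ rng.normal(0, 1, 5)
        assert select_pairs(range(5), X, y) == select_pairs(range(5), X, y)

    def test_fewer_than_two_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_pairs([0], np.zeros((10, 3)), np.zeros(10))


class TestTraining:
    def test_separable_classes_learned_to_high_accuracy(self, separable_groups):
        tables, labels = separable_groups
        res, rmse_per_level, _ = train_cascade(tables, labels)
        pred = res.predict(tables)
        acc = np.mean([p == t for p, t in zip(pred, labels)])
        # nearest-centroid oracle on the concatenated features
        X = np.hstack(tables)
        classes = sorted(set(labels))
        y = np.array([classes.index(l) for l in labels])
        cents = np.stack([X[y == c].mean(0) for c in range(len(classes))])
        oracle = np.argmin(
            ((X[:, None, :] - cents[None]) ** 2).sum(-1), axis=1)
        assert np.mean(oracle == y) >= 0.99  # separability by construction
        assert acc >= 0.99

    def test_level_rmse_non_increasing(self, separable_groups):
        tables, labels = separable_groups
        _, rmse_per_level, _ = train_cascade(
            tables, labels, CascadeConfig(strategy="index-regression"))
        assert np.all(np.diff(rmse_per_level) <= 1e-12)

    def test_training_is_deterministic(self, separable_groups):
        tables, labels = separable_groups
        r1, l1, _ = train_cascade(tables, labels)
        r2, l2, _ = train_cascade(tables, labels)
        assert np.array_equal(l1, l2)
        assert r1.predict(tables) == r2.predict(tables)

    def test_single_class_rejected(self):
        tables = [np.random.default_rng(0).normal(0, 1, (10, 4))]
        with pytest.raises(ValueError, match="2 classes"):
            train_cascade(tables, ["a"] * 10)

    def test_non_finite_features_rejected_naming_group(self):
        rng = np.random.default_rng(0)
        tables = [rng.normal(0, 1, (10, 3)), rng.normal(0, 1, (10, 3))]
        tables[1][3, 1] = np.nan
        with pytest.raises(ValueError, match="group 1"):
            train_cascade(tables, ["a", "b"] * 5)

    def test_duplicated_rows_predict_identically(self, separable_groups):
        tables, labels = separable_groups
        res, _, _ = train_cascade(tables, labels)
        dup = [np.vstack([T[:5], T[:5]]) for T in tables]
        pred = res.predict(dup)
        assert pred[:5] == pred[5:]

    def test_empty_input_gives_empty_labels(self, separable_groups):
        tables, labels = separable_groups
        res, _, _ = train_cascade(tables, labels)
        assert res.predict([T[:0] for T in tables]) == []

    def test_missing_group_rejected(self, separable_groups):
        tables, labels = separable_groups
        res, _, _ = train_cascade(tables, labels)
        with pytest.raises(ValueError, match="groups"):
            res.predict(tables[:-1])


class TestChainEquivalence:
    def test_one_group_cascade_equals_plain_chain(self):
        tables, labels = make_separable_groups(n_groups=1, seed=3)
        config = CascadeConfig(strategy="index-regression")
        res, _, _ = train_cascade(tables, labels, config)
        codec = res.codec
        target = codec.encode(labels)
        steps, _, _, _ = _fit_chain(tables[0], target, config)
        direct = _chain_forward(steps, tables[0])
        assert codec.decode(direct) == res.predict(tables)


class TestCascadeVsPlainAnfis:
    def test_cascade_beats_plain_two_input_unit_at_epoch_one(self):
        """A single level of the cascade sees all features; a plain 2-input
        unit sees two.  On a fixed nonlinear regression fixture the cascade's
        epoch-1 training RMSE must not exceed the plain unit's."""
        rng = np.random.default_rng(12)
        n = 150
        X = rng.uniform(-1, 1, (n, 6))
        target = (np.sin(2 * X[:, 0]) + X[:, 1] * X[:, 2]
                  + 0.5 * X[:, 3] ** 2 + 0.3 * X[:, 4] - 0.2 * X[:, 5])
        labels = np.digitize(target, np.quantile(target, [0.25, 0.5, 0.75]))
        config = CascadeConfig(strategy="index-regression", epochs=1)
        _, rmse_per_level, _ = train_cascade([X], list(labels), config)
        codec = LabelCodec.from_labels(list(labels))
        y = codec.encode(list(labels))
        plain = Anfis(y, X[:, :2]).fit(epochs=1)
        assert rmse_per_level[-1] <= plain.rmse + 1e-12


class TestPersistence:
    def test_save_load_round_trip_predicts_identically(self, tmp_path,
                                                       separable_groups):
        tables, labels = separable_groups
        res, _, _ = train_cascade(tables, labels)
        path = tmp_path / "cascade.json"
        res.save(path)
        clone = load_cascade(path)
        assert clone.predict(tables) == res.predict(tables)
        assert clone.codec.classes == res.codec.classes

    def test_serialization_round_trips_bit_exactly(self, tmp_path,
                                                   separable_groups):
        tables, labels = separable_groups
        res, _, _ = train_cascade(tables, labels)
        d1 = res.to_dict()
        d2 = CascadeResults.from_dict(d1).to_dict()
        assert d1 == d2

    def test_truncated_file_rejected(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"schema_version": 1, "kind": "casc')
        with pytest.raises(ValueError, match="corrupt"):
            load_cascade(path)

    def test_schema_version_mismatch_rejected(self, tmp_path,
                                              separable_groups):
        tables, labels = separable_groups
        res, _, _ = train_cascade(tables, labels)
        d = res.to_dict()
        d["schema_version"] = 99
        with pytest.raises(ValueError, match="schema version"):
            CascadeResults.from_dict(d)


class TestModelSurface:
    def test_fit_summary_and_frame_constructor(self, separable_groups):
        import pandas as pd

        tables, labels = separable_groups
        res = CascadedAnfis(labels, tables).fit()
        text = res.summary()
        assert "levels" in text.lower()
        # grouped-frame round trip
        data = {"label": labels}
        for g, T in enumerate(tables):
            for k in range(T.shape[1]):
                data[f"g{g + 1}_c{k + 1}"] = T[:, k]
        df = pd.DataFrame(data)
        model = CascadedAnfis.from_frame(df)
        res2 = model.fit()
        assert res2.predict(tables) == res.predict(tables)
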