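"""Tests for the four-branch classifier, attention variant and training API."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_xy, split
from m6aconvkit.evaluation import auroc
from m6aconvkit.network import (
    ArchitectureConfig,
    attention_profile,
    build_attention_model,
    build_classifier,
    build_single_branch,
    default_input_shapes,
    feature_confidences,
    fine_tune,
    load_model,
    predict,
    save_model,
    train,
)

L_SMALL = 21
SMALL_SHAPES = default_input_shapes(L_SMALL, n_dpp=5)


def random_inputs(rng, n, shapes=SMALL_SHAPES):
    return {name: rng.standard_normal((n, t, c)) for name, (t, c) in shapes.items()}


@pytest.fixture(scope="module")
def small_table():
    from m6aconvkit.data_synth_io import generate_dpp_table
    from m6aconvkit.sequence_features import znorm_dpp

    return znorm_dpp(generate_dpp_table(20, seed=31))


@pytest.fixture(scope="module")
def small_selected(small_table):
    return list(small_table.names[:5])


@pytest.fixture(scope="module")
def motif_task(small_table, small_selected):
    """300 per class, planted motif in every positive, length 21."""
    data, X, y = make_xy(
        300, small_table, small_selected, seed=41, motif_rate_pos=1.0, length=L_SMALL
    )
    return data, X, y


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"conv_filters": (16, 32)},
            {"conv_kernels": (5, 5, 5, 5)},
            {"conv_filters": (0, 1, 1)},
            {"attention_hidden": 33},
            {"learning_rate": 0.0},
            {"epochs": -1},
            {"loss": "hinge"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ArchitectureConfig(**kwargs)


class TestBuildAndForward:
    def test_default_input_shapes_match_contract(self):
        shapes = default_input_shapes()
        assert shapes == {
            "monomer": (41, 4),
            "dimer": (40, 16),
            "dpp": (40, 9),
            "pse": (41, 4),
        }

    def test_untrained_forward_is_sigmoid_scalar(self, tiny_config):
        model = build_classifier(tiny_config, SMALL_SHAPES)
        X = random_inputs(np.random.default_rng(0), 1)
        prob, conf = model.forward(X)
        assert prob.shape == (1,)
        assert 0.0 < prob.data[0] < 1.0
        assert conf.shape == (1, 4)  # Feature Learner concatenation is a 4-vector

    def test_default_config_accepts_41bp_shapes(self):
        model = build_classifier(ArchitectureConfig())
        X = random_inputs(np.random.default_rng(1), 2, default_input_shapes())
        prob, _ = model.forward(X)
        assert prob.shape == (2,)

    def test_kernel_too_large_names_branch(self, tiny_config):
        with pytest.raises(ValueError, match="branch .* kernel size"):
            build_classifier(tiny_config, default_input_shapes(5))

    def test_shape_mismatch_names_branch(self, tiny_config):
        model = build_classifier(tiny_config, SMALL_SHAPES)
        X = random_inputs(np.random.default_rng(2), 3)
        X["dimer"] = X["dimer"][:, :-1, :]
        with pytest.raises(ValueError, match="'dimer'"):
            model.forward(X)

    def test_n_params_positive_and_consistent(self, tiny_config):
        model = build_classifier(tiny_config, SMALL_SHAPES)
        assert model.n_params == sum(p.data.size for p in model.params) > 0


class TestPredict:
    def test_probability_exactly_half_is_negative(self, tiny_config):
        model = build_classifier(tiny_config, SMALL_SHAPES)
        model.coordinator.w.data[:] = 0.0
        model.coordinator.b.data[:] = 0.0
        probs, labels = predict(model, random_inputs(np.random.default_rng(3), 4))
        np.testing.assert_array_equal(probs, 0.5)
        np.testing.assert_array_equal(labels, 0)

    def test_duplicate_rows_identical_and_order_preserved(self, tiny_config):
        model = build_classifier(tiny_config, SMALL_SHAPES)
        X = random_inputs(np.random.default_rng(4), 5)
        X2 = {k: np.concatenate([v, v[[0]]]) for k, v in X.items()}
        probs, _ = predict(model, X2)
        assert probs[5] == probs[0]
        perm = [3, 1, 4, 0, 2]
        probs_perm, _ = predict(model, {k: v[perm] for k, v in X.items()})
        np.testing.assert_array_equal(probs_perm, probs[:5][perm])


class TestTraining:
    def test_planted_signal_learnable(self, tiny_config, motif_task):
        _, X, y = motif_task
        X_tr, y_tr, X_te, y_te = split(X, y, 150, seed=0)
        model = train(build_classifier(tiny_config, SMALL_SHAPES), X_tr, y_tr, epochs=20)
        probs, _ = predict(model, X_te)
        assert auroc(y_te, probs) > 0.9

    def test_loss_history_decreases_on_separable_data(self, tiny_config, motif_task):
        _, X, y = motif_task
        model = train(build_classifier(tiny_config, SMALL_SHAPES), X, y, epochs=6)
        hist = model.meta["loss_history"]
        assert np.mean(hist[-2:]) < np.mean(hist[:2])

    def test_permuted_labels_chance_level(self, tiny_config, small_table, small_selected):
        _, X, y = make_xy(
            500, small_table, small_selected, seed=42, motif_rate_pos=1.0, length=L_SMALL
        )
        y = np.random.default_rng(5).permutation(y)
        X_tr, y_tr, X_te, y_te = split(X, y, 300, seed=1)
        model = train(build_classifier(tiny_config, SMALL_SHAPES), X_tr, y_tr, epochs=3)
        probs, _ = predict(model, X_te)
        assert 0.4 < auroc(y_te, probs) < 0.6

    def test_single_batch_overfit(self, tiny_config, motif_task):
        _, X, y = motif_task
        idx = np.r_[0:16, 300:316]  # 16 positives + 16 negatives
        Xs = {k: v[idx] for k, v in X.items()}
        model = train(
            build_classifier(tiny_config, SMALL_SHAPES), Xs, y[idx], epochs=120
        )
        _, labels = predict(model, Xs)
        assert (labels == y[idx]).mean() == 1.0

    def test_single_class_rejected(self, tiny_config):
        X = random_inputs(np.random.default_rng(6), 8)
        with pytest.raises(ValueError, match="both classes"):
            train(build_classifier(tiny_config, SMALL_SHAPES), X, np.ones(8))

    def test_train_leaves_original_untouched(self, tiny_config, motif_task):
        _, X, y = motif_task
        model = build_classifier(tiny_config, SMALL_SHAPES)
        before = [p.data.copy() for p in model.params]
        train(model, X, y, epochs=1)
        for old, p in zip(before, model.params):
            np.testing.assert_array_equal(old, p.data)
        assert not model.trained

    def test_zero_epochs_leaves_parameters_unchanged(self, tiny_config, motif_task):
        _, X, y = motif_task
        model = build_classifier(tiny_config, SMALL_SHAPES)
        out = train(model, X, y, epochs=0, init_output_bias=False)
        for a, b in zip(model.params, out.params):
            np.testing.assert_array_equal(a.data, b.data)

    def test_seeded_training_reproducible(self, tiny_config, motif_task):
        _, X, y = motif_task
        a = train(build_classifier(tiny_config, SMALL_SHAPES), X, y, epochs=2)
        b = train(build_classifier(tiny_config, SMALL_SHAPES), X, y, epochs=2)
        pa, _ = predict(a, X)
        pb, _ = predict(b, X)
        assert pa.tobytes() == pb.tobytes()


class TestFeatureConfidences:
    def test_untrained_model_rejected(self, tiny_config):
        model = build_classifier(tiny_config, SMALL_SHAPES)
        with pytest.raises(ValueError, match="trained"):
            feature_confidences(model, random_inputs(np.random.default_rng(7), 2))

    def test_values_in_unit_interval_and_deterministic(self, tiny_config, motif_task):
        _, X, y = motif_task
        model = train(build_classifier(tiny_config, SMALL_SHAPES), X, y, epochs=1)
        conf = feature_confidences(model, X)
        assert conf.shape == (600, 4)
        assert (conf >= 0).all() and (conf <= 1).all()
        assert conf.tobytes() == feature_confidences(model, X).tobytes()

    def test_planted_single_branch_signal(
        self, tiny_config, motif_task, small_table, small_selected
    ):
        # only the monomer branch receives class signal; other branches get
        # class-independent noise; separation is measured on held-out data so
        # noise branches cannot look informative through memorization
        rng = np.random.default_rng(8)
        _, X_real, y = motif_task
        noisy = lambda arr: rng.standard_normal(arr.shape)  # noqa: E731
        X = {k: (v if k == "monomer" else noisy(v)) for k, v in X_real.items()}
        model = train(build_classifier(tiny_config, SMALL_SHAPES), X, y, epochs=15)
        _, X_fresh, y_fresh = make_xy(
            200, small_table, small_selected, seed=99, motif_rate_pos=1.0, length=L_SMALL
        )
        X_eval = {k: (v if k == "monomer" else noisy(v)) for k, v in X_fresh.items()}
        conf = feature_confidences(model, X_eval)
        # the confidence separates the classes; its orientation is free (the
        # coordinator may weight a branch negatively), so measure |AUC - 0.5|
        assert abs(auroc(y_fresh, conf[:, 0]) - 0.5) > 0.4
        for j in (1, 2, 3):
            assert abs(auroc(y_fresh, conf[:, j]) - 0.5) < 0.1

    def test_coordinator_depends_only_on_confidence_vector(self, tiny_config, motif_task):
        _, X, y = motif_task
        model = train(build_classifier(tiny_config, SMALL_SHAPES), X, y, epochs=2)
        probs, _ = predict(model, X)
        conf = feature_confidences(model, X)
        np.testing.assert_allclose(model.coordinate(conf), probs, atol=1e-12)

    def test_no_branch_sees_another_branchs_input(self, tiny_config, motif_task):
        _, X, y = motif_task
        model = train(build_classifier(tiny_config, SMALL_SHAPES), X, y, epochs=1)
        conf = feature_confidences(model, X)
        X_perturbed = dict(X)
        X_perturbed["dimer"] = np.random.default_rng(9).standard_normal(X["dimer"].shape)
        conf2 = feature_confidences(model, X_perturbed)
        for j, name in enumerate(("monomer", "dimer", "dpp", "pse")):
            if name == "dimer":
                assert not np.allclose(conf[:, j], conf2[:, j])
            else:
                np.testing.assert_array_equal(conf[:, j], conf2[:, j])


class TestAttentionModel:
    def test_paper_scale_shapes(self):
        config = ArchitectureConfig(attention_hidden=256)
        model = build_attention_model(config)
        X = random_inputs(np.random.default_rng(10), 1, default_input_shapes())
        prob, s = model.forward(X)
        assert s.shape == (1, 41)
        assert s.data.sum() == pytest.approx(1.0, abs=1e-6)
        assert 0.0 < prob.data[0] < 1.0

    def test_profile_requires_training(self, tiny_config):
        model = build_attention_model(tiny_config, SMALL_SHAPES)
        with pytest.raises(ValueError, match="trained"):
            attention_profile(model, random_inputs(np.random.default_rng(11), 1))

    def test_profile_deterministic_and_simplex(self, tiny_config, motif_task):
        _, X, y = motif_task
        model = train(build_attention_model(tiny_config, SMALL_SHAPES), X, y, epochs=1)
        s = attention_profile(model, X)
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-6)
        assert (s >= 0).all()
        assert s.tobytes() == attention_profile(model, X).tobytes()

    def test_attention_concentrates_on_planted_motif(
        self, tiny_config, small_table, small_selected
    ):
        data, X, y = make_xy(
            250, small_table, small_selected, seed=41, motif_rate_pos=1.0, length=41
        )
        shapes = default_input_shapes(41, n_dpp=5)
        model = train(build_attention_model(tiny_config, shapes), X, y, epochs=8)
        positives = [(i, s) for i, s in enumerate(data) if s.label == 1][:250]
        S = attention_profile(model, {k: v[[i for i, _ in positives]] for k, v in X.items()})
        wins = 0
        for row, (_, seq) in zip(S, positives):
            start = seq.bases.index("TCGT")
            span = np.zeros(len(seq), dtype=bool)
            span[start : start + 4] = True
            wins += row[span].mean() > row[~span].mean()
        p = stats.binomtest(wins, len(positives), alternative="greater").pvalue
        assert p < 0.01


class TestFineTune:
    def test_requires_trained_model(self, tiny_config, motif_task):
        _, X, y = motif_task
        model = build_classifier(tiny_config, SMALL_SHAPES)
        with pytest.raises(ValueError, match="trained"):
            fine_tune(model, X, y)

    def test_zero_epochs_is_identity(self, tiny_config, motif_task):
        _, X, y = motif_task
        model = train(build_classifier(tiny_config, SMALL_SHAPES), X, y, epochs=1)
        tuned = fine_tune(model, X, y, epochs=0)
        for a, b in zip(model.params, tuned.params):
            np.testing.assert_array_equal(a.data, b.data)

    def test_matched_distribution_stability(
        self, tiny_config, small_table, small_selected, motif_task
    ):
        _, X, y = motif_task
        X_tr, y_tr, X_te, y_te = split(X, y, 150, seed=2)
        model = train(build_classifier(tiny_config, SMALL_SHAPES), X_tr, y_tr, epochs=15)
        base_auc = auroc(y_te, predict(model, X_te)[0])
        _, X_small, y_small = make_xy(
            40, small_table, small_selected, seed=77, motif_rate_pos=1.0, length=L_SMALL
        )
        tuned = fine_tune(model, X_small, y_small, epochs=2)
        tuned_auc = auroc(y_te, predict(tuned, X_te)[0])
        assert tuned_auc >= base_auc - 0.05

    def test_transfer_to_shifted_motif_position(self, tiny_config, small_table, small_selected):
        # pre-train with the motif confined to the left flank, fine-tune on a
        # tenth of the data with the motif confined to the right flank
        from m6aconvkit.data_synth_io import labels_array
        from m6aconvkit.sequence_features import DnaSequence, encode_bundle, stack_bundles

        def offset_task(n, lo, hi, seed):
            rng = np.random.default_rng(seed)
            seqs = []
            for label in (1, 0):
                for i in range(n):
                    arr = rng.choice(list("ACGT"), size=L_SMALL)
                    arr[L_SMALL // 2] = "A"
                    if label:
                        off = int(rng.integers(lo, hi))
                        arr[off : off + 4] = list("TCGT")
                    seqs.append(
                        DnaSequence(f"{label}_{i}", "".join(arr), label=label)
                    )
            bundles = [encode_bundle(s, small_table, small_selected) for s in seqs]
            return stack_bundles(bundles), labels_array(seqs)

        X_pre, y_pre = offset_task(250, 0, 6, seed=50)
        X_small, y_small = offset_task(25, 13, 17, seed=51)
        X_test, y_test = offset_task(150, 13, 17, seed=52)
        model = train(build_classifier(tiny_config, SMALL_SHAPES), X_pre, y_pre, epochs=15)
        tuned = fine_tune(model, X_small, y_small, epochs=50, lr_factor=0.5)
        assert auroc(y_test, predict(tuned, X_test)[0]) > 0.8


class TestSingleBranch:
    def test_unknown_feature_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="unknown feature"):
            build_single_branch("kmer", tiny_config)

    def test_default_monomer_shape(self):
        model = build_single_branch("monomer", ArchitectureConfig())
        assert model.input_shapes == {"monomer": (41, 4)}

    def test_learnable_on_separable_data(self, tiny_config, motif_task):
        _, X, y = motif_task
        X_tr, y_tr, X_te, y_te = split(X, y, 150, seed=3)
        model = build_single_branch("monomer", tiny_config, SMALL_SHAPES["monomer"])
        trained = train(model, X_tr["monomer"], y_tr, epochs=15)
        assert auroc(y_te, predict(trained, X_te["monomer"])[0]) > 0.85

    def test_coordination_beats_every_single_branch(self, tiny_config):
        # conjunctive signal: the class is the AND of a monomer-level flag and
        # a property-level flag, so no single feature suffices
        rng = np.random.default_rng(60)
        n = 600
        flag_m = rng.random(n) < np.sqrt(0.5)
        flag_d = rng.random(n) < np.sqrt(0.5)
        y = (flag_m & flag_d).astype(int)
        X = random_inputs(rng, n)
        motif = np.zeros((4, 4))
        motif[:, 1] = 5.0
        X["monomer"][flag_m, 3:7, :] = motif
        X["dpp"][flag_d, 8:12, :] += 2.5
        X_tr = {k: v[:400] for k, v in X.items()}
        X_te = {k: v[400:] for k, v in X.items()}
        y_tr, y_te = y[:400], y[400:]
        full = train(build_classifier(tiny_config, SMALL_SHAPES), X_tr, y_tr, epochs=15)
        full_auc = auroc(y_te, predict(full, X_te)[0])
        for feature in ("monomer", "dimer", "dpp", "pse"):
            single = train(
                build_single_branch(feature, tiny_config, SMALL_SHAPES[feature]),
                X_tr[feature],
                y_tr,
                epochs=12,
            )
            single_auc = auroc(y_te, predict(single, X_te[feature])[0])
            assert full_auc >= single_auc + 0.1, (feature, full_auc, single_auc)


class TestPersistence:
    def test_roundtrip_four_branch(self, tmp_path, tiny_config, motif_task):
        _, X, y = motif_task
        model = train(build_classifier(tiny_config, SMALL_SHAPES), X, y, epochs=1)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.kind == "four_branch" and loaded.trained
        np.testing.assert_array_equal(predict(loaded, X)[0], predict(model, X)[0])

    def test_roundtrip_attention_and_single(self, tmp_path, tiny_config, motif_task):
        _, X, y = motif_task
        att = train(build_attention_model(tiny_config, SMALL_SHAPES), X, y, epochs=1)
        save_model(att, tmp_path / "att.npz")
        loaded = load_model(tmp_path / "att.npz")
        np.testing.assert_array_equal(
            attention_profile(loaded, X), attention_profile(att, X)
        )
        single = train(
            build_single_branch("dpp", tiny_config, SMALL_SHAPES["dpp"]),
            X["dpp"],
            y,
            epochs=1,
        )
        save_model(single, tmp_path / "single.npz")
        loaded_single = load_model(tmp_path / "single.npz")
        np.testing.assert_array_equal(
            predict(loaded_single, X["dpp"])[0], predict(single, X["dpp"])[0]
        )
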