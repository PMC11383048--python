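"""Network forward pass, focal loss, training behavior, prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snprecover import (
    ModelConfig,
    SimulationConfig,
    TrainedGenotyper,
    encode_dataset,
    evaluate_agreement,
    filter_complete_records,
    focal_loss,
    forward,
    grid_search,
    partition_no_calls,
    predict,
    simulate_panel,
    split_train_val_test,
    train,
)
from snprecover.errors import UnknownSnpError
from snprecover.genotyper import PredictionResult, _init_model, softmax


def _tiny_model(weights, embedding, hidden=(1,)):
    cfg = ModelConfig(embedding_dim=embedding.shape[1], hidden_units=hidden, seed=0)
    return TrainedGenotyper({"snp0": 0}, embedding, weights, cfg)


def _train_on_panel(cfg_sim, cfg_model, split_seed=0):
    panel = simulate_panel(cfg_sim)
    kept, _ = filter_complete_records(panel.records)
    valid, _ = partition_no_calls(kept)
    tr, va, te = split_train_val_test(valid, seed=split_seed)
    enc_tr = encode_dataset(tr)
    enc_va = encode_dataset(va, vocabulary=enc_tr.vocabulary)
    model = train(enc_tr, enc_va, cfg_model)
    return model, te


class TestForward:
    def test_zero_weights_give_uniform_output(self):
        emb = np.zeros((1, 2))
        weights = [(np.zeros((4, 3)), np.zeros(3)), (np.zeros((3, 3)), np.zeros(3))]
        m = _tiny_model(weights, emb, hidden=(3,))
        np.testing.assert_allclose(forward(m, 0, 1.0, 0.5), [1 / 3] * 3, atol=1e-12)

    def test_output_is_simplex(self):
        m = _init_model({"a": 0, "b": 1}, ModelConfig(embedding_dim=3, hidden_units=(4,), seed=9))
        p = forward(m, 1, 2.0, 0.3)
        assert p.shape == (3,)
        assert p.min() >= 0
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_matches_pencil_and_paper_chain(self):
        # 1 SNP, embedding dim 1, one hidden unit: the full affine/relu/
        # softmax chain is computable by hand.
        emb = np.array([[0.5]])
        W1 = np.array([[0.2], [-0.3], [0.4]])  # input (e, r, theta) -> 1 unit
        b1 = np.array([0.1])
        W2 = np.array([[1.0, -1.0, 0.5]])
        b2 = np.array([0.0, 0.1, -0.2])
        m = _tiny_model([(W1, b1), (W2, b2)], emb)
        r, theta = 0.8, 0.6
        h = max(0.0, 0.5 * 0.2 + r * -0.3 + theta * 0.4 + 0.1)
        z = [h * 1.0 + 0.0, h * -1.0 + 0.1, h * 0.5 - 0.2]
        exps = [math.exp(v - max(z)) for v in z]
        expected = [e / sum(exps) for e in exps]
        np.testing.assert_allclose(forward(m, 0, r, theta), expected, atol=1e-9)

    def test_out_of_range_snp_index_rejected(self):
        m = _init_model({"a": 0}, ModelConfig(embedding_dim=2, hidden_units=(2,)))
        with pytest.raises(UnknownSnpError):
            forward(m, 5, 1.0, 0.5)


class TestFocalLoss:
    def test_closed_form_value(self):
        # p_t = 0.5, gamma = 2, alpha = 0.25: 0.25 * 0.25 * ln 2
        p = np.array([[0.5, 0.3, 0.2]])
        t = np.array([[1.0, 0.0, 0.0]])
        assert focal_loss(p, t, gamma=2.0, alpha=0.25) == pytest.approx(
            0.25 * 0.25 * math.log(2.0), abs=1e-12
        )

    def test_vanishes_as_p_true_approaches_one(self):
        p = np.array([[1.0 - 1e-9, 5e-10, 5e-10]])
        t = np.array([[1.0, 0.0, 0.0]])
        assert focal_loss(p, t) == pytest.approx(0.0, abs=1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0.01, 0.98), st.floats(0.0, 1.0))
    def test_gamma_zero_alpha_one_is_cross_entropy(self, p_true, split):
        rest = 1.0 - p_true
        p = np.array([[p_true, rest * split, rest * (1 - split)]])
        t = np.array([[1.0, 0.0, 0.0]])
        assert focal_loss(p, t, gamma=0.0, alpha=1.0) == pytest.approx(
            -math.log(p_true), rel=1e-9
        )

    def test_strictly_decreasing_in_p_true(self):
        grid = np.linspace(0.01, 0.99, 50)
        losses = [
            focal_loss(np.array([[pt, 1 - pt, 0.0]]), np.array([[1.0, 0.0, 0.0]]),
                       gamma=2.0, alpha=0.25)
            for pt in grid
        ]
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestTraining:
    def test_separable_clusters_reach_high_validation_accuracy(self):
        cfg_sim = SimulationConfig(n_snps=2, n_strata=1, samples_per_stratum=600,
                                   theta_noise_sd=0.02, nc_probability=0.0,
                                   missingness_rate=0.0, maf_range=(0.4, 0.5), seed=1)
        model, _ = _train_on_panel(
            cfg_sim, ModelConfig(max_epochs=30, learning_rate=0.01, seed=1)
        )
        assert model.history["val_accuracy"][-1] >= 0.99

    def test_history_length_bounded_by_max_epochs(self):
        cfg_sim = SimulationConfig(n_snps=2, n_strata=1, samples_per_stratum=100, seed=2)
        model, _ = _train_on_panel(
            cfg_sim, ModelConfig(max_epochs=3, hidden_units=(8, 8), embedding_dim=4, seed=2)
        )
        assert len(model.history["loss"]) <= 3
        assert len(model.history["val_loss"]) == len(model.history["loss"])

    def test_patience_zero_stops_on_first_rise(self):
        cfg_sim = SimulationConfig(n_snps=3, n_strata=1, samples_per_stratum=150, seed=3)
        model, _ = _train_on_panel(
            cfg_sim,
            ModelConfig(max_epochs=30, early_stop_patience=0, hidden_units=(4,),
                        embedding_dim=2, learning_rate=0.05, seed=3),
        )
        vl = model.history["val_loss"]
        # every epoch but the last improved on the best so far
        best = math.inf
        for loss in vl[:-1]:
            assert loss < best
            best = min(best, loss)

    def test_same_seed_reproduces_history(self):
        cfg_sim = SimulationConfig(n_snps=2, n_strata=1, samples_per_stratum=120, seed=4)
        cfg_model = ModelConfig(max_epochs=2, hidden_units=(6,), embedding_dim=3, seed=4)
        m1, _ = _train_on_panel(cfg_sim, cfg_model)
        m2, _ = _train_on_panel(cfg_sim, cfg_model)
        assert m1.history == m2.history

    def test_empty_training_set_rejected(self):
        enc = encode_dataset([], vocabulary={"a": 0})
        with pytest.raises(ValueError):
            train(enc, enc, ModelConfig())

    def test_accuracy_within_one_point_of_bayes_oracle(self):
        # Overlapping Gaussian clusters: the Bayes classifier from the
        # known generating densities is the ceiling; the trained network
        # should come within one percentage point of it.
        cfg_sim = SimulationConfig(
            n_snps=30, n_strata=2, samples_per_stratum=250,
            centroid_template=(0.2, 0.5, 0.8), theta_noise_sd=0.08,
            centroid_jitter_sd=0.0, nc_probability=0.0, missingness_rate=0.0,
            maf_range=(0.3, 0.5), seed=5,
        )
        panel = simulate_panel(cfg_sim)
        valid, _ = partition_no_calls(filter_complete_records(panel.records)[0])
        tr, va, te = split_train_val_test(valid, seed=5)
        enc_tr = encode_dataset(tr)
        enc_va = encode_dataset(va, vocabulary=enc_tr.vocabulary)
        model = train(enc_tr, enc_va,
                      ModelConfig(max_epochs=25, learning_rate=0.01, seed=5))
        result = predict(model, te)
        acc, _ = evaluate_agreement(result, [r.genotype for r in te])

        params = panel.snp_params.set_index("snp_id")
        centroids = {sid: np.array([row.centroid_AA, row.centroid_AB, row.centroid_BB])
                     for sid, row in params.iterrows()}
        priors = {sid: np.array([(1 - row.maf) ** 2, 2 * row.maf * (1 - row.maf),
                                 row.maf ** 2])
                  for sid, row in params.iterrows()}
        sd = cfg_sim.theta_noise_sd
        classes = ("AA", "AB", "BB")
        bayes_correct = 0
        for rec in te:
            dens = priors[rec.snp_id] * np.exp(
                -((rec.theta - centroids[rec.snp_id]) ** 2) / (2 * sd * sd)
            )
            bayes_correct += classes[int(dens.argmax())] == rec.genotype
        bayes_acc = bayes_correct / len(te)
        assert acc >= bayes_acc - 0.01


class TestGridSearch:
    def test_enumerates_all_pairs_and_degenerate_grid(self):
        cfg_sim = SimulationConfig(n_snps=2, n_strata=1, samples_per_stratum=80, seed=6)
        panel = simulate_panel(cfg_sim)
        valid, _ = partition_no_calls(filter_complete_records(panel.records)[0])
        tr, va, _ = split_train_val_test(valid, seed=6)
        enc_tr = encode_dataset(tr)
        enc_va = encode_dataset(va, vocabulary=enc_tr.vocabulary)
        base = ModelConfig(embedding_dim=2, seed=6)
        best, results = grid_search(enc_tr, enc_va, [8, 16], base_config=base,
                                    search_epochs=1)
        assert len(results) == 4
        assert best in [r[0] for r in results]
        best1, results1 = grid_search(enc_tr, enc_va, [8], base_config=base,
                                      search_epochs=1)
        assert best1 == (8, 8) and len(results1) == 1

    def test_default_grid_covers_25_pairs(self):
        import inspect

        default = inspect.signature(grid_search).parameters["layer_size_grid"].default
        assert list(default) == [32, 64, 96, 128, 160]


class TestPredictEvaluate:
    def test_prediction_at_cluster_centroid_recovers_class(self):
        cfg_sim = SimulationConfig(n_snps=2, n_strata=1, samples_per_stratum=600,
                                   theta_noise_sd=0.02, nc_probability=0.0,
                                   missingness_rate=0.0, maf_range=(0.4, 0.5), seed=7)
        model, te = _train_on_panel(
            cfg_sim, ModelConfig(max_epochs=30, learning_rate=0.01, seed=7)
        )
        snp_id = next(iter(model.vocabulary))
        rec = next(r for r in te if r.snp_id == snp_id)
        probe = [
            type(rec)(sample_id="probe", snp_id=snp_id, variant=rec.variant,
                      r=1.0, theta=t, gentrain=0.9, genotype="NC")
            for t in (0.05, 0.50, 0.95)
        ]
        result = predict(model, probe)
        assert result.predicted_genotype == ["AA", "AB", "BB"]

    def test_unknown_snp_ids_excluded_with_count(self, make_record):
        m = _init_model({"a": 0}, ModelConfig(embedding_dim=2, hidden_units=(2,)))
        records = [make_record(snp_id="a"), make_record(snp_id="zzz")]
        result = predict(m, records)
        assert len(result) == 1 and result.n_excluded == 1
        assert result.kept_indices.tolist() == [0]

    def test_empty_input_empty_result(self):
        m = _init_model({"a": 0}, ModelConfig(embedding_dim=2, hidden_units=(2,)))
        result = predict(m, [])
        assert len(result) == 0 and result.probabilities.shape == (0, 3)

    def test_argmax_and_tie_breaking(self):
        res = PredictionResult(
            probabilities=np.array([[0.2, 0.5, 0.3]]),
            predicted_genotype=["AB"], max_probability=np.array([0.5]),
        )
        assert res.predicted_genotype == ["AB"]
        # fixed class order breaks exact ties toward AA < AB < BB
        tie = softmax(np.zeros((1, 3)))
        assert tie.argmax() == 0

    def test_evaluate_agreement_confusion_counts(self):
        res = PredictionResult(
            probabilities=np.zeros((2, 3)),
            predicted_genotype=["AA", "BB"], max_probability=np.zeros(2),
        )
        acc, conf = evaluate_agreement(res, ["AA", "AA"])
        assert acc == 0.5
        assert conf[0, 0] == 1 and conf[0, 2] == 1 and conf.sum() == 2
        with pytest.raises(ValueError):
            evaluate_agreement(res, ["AA"])


class TestPersistence:
    def test_save_load_round_trip_identical_predictions(self, tmp_path):
        cfg_sim = SimulationConfig(n_snps=3, n_strata=1, samples_per_stratum=100, seed=8)
        model, te = _train_on_panel(
            cfg_sim, ModelConfig(max_epochs=2, hidden_units=(8,), embedding_dim=4, seed=8)
        )
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedGenotyper.load(path)
        assert loaded.vocabulary == model.vocabulary
        assert loaded.config == model.config
        p1 = predict(model, te).probabilities
        p2 = predict(loaded, te).probabilities
        np.testing.assert_allclose(p1, p2, atol=1e-6)
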