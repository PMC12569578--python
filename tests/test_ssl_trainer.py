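"""Pseudo-labeling loop contracts and supervised-training behaviour."""

import numpy as np
import pytest

from pathoftt import (
    TrainConfig,
    predict,
    run_semisupervised,
    select_pseudo_labels,
    train_supervised,
)
from pathoftt.ftt_core import FTTConfig, bce_with_logits, init_model
from pathoftt.ssl_trainer import ConfigurationError, ContractError
from tests.conftest import build_ssl_problem, compact_model_config

FAST_TRAIN = dict(learning_rate=3e-3, batch_size=256, max_epochs=60, patience=8)


class TestSelectPseudoLabels:
    def test_confident_pathogenic_promoted(self):
        ids, labels, confs = select_pseudo_labels(np.array([0.97]), 0.95)
        assert list(ids) == [0]
        assert list(labels) == [1]
        assert confs[0] == pytest.approx(0.97)

    def test_confident_benign_promoted_by_symmetry(self):
        ids, labels, confs = select_pseudo_labels(np.array([0.03]), 0.95)
        assert list(labels) == [0]
        assert confs[0] == pytest.approx(0.97)

    def test_exactly_at_threshold_not_promoted(self):
        ids, _, _ = select_pseudo_labels(np.array([0.95, 0.05]), 0.95)
        assert ids.size == 0

    def test_row_ids_carried_through(self):
        ids, labels, _ = select_pseudo_labels(
            np.array([0.99, 0.5, 0.01]), 0.95, row_ids=[10, 20, 30]
        )
        assert list(ids) == [10, 30]
        assert list(labels) == [1, 0]


class TestTrainConfig:
    def test_threshold_at_or_below_half_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(confidence_threshold=0.5)

    def test_threshold_one_allowed(self):
        assert TrainConfig(confidence_threshold=1.0).confidence_threshold == 1.0


class TestTrainSupervised:
    def test_initial_loss_near_ln2_for_balanced_targets(self):
        cfg = FTTConfig(
            n_numerical=4, categorical_cardinalities=(), token_dim=8,
            n_layers=1, n_heads=2, ffn_hidden=8,
        )
        model = init_model(cfg, seed=0)
        rng = np.random.default_rng(1)
        Xn = rng.standard_normal((64, 4)).astype(np.float32)
        y = np.tile([0.0, 1.0], 32)
        logits = model.predict_logits(Xn, np.zeros((64, 0), dtype=int))
        loss, _ = bce_with_logits(logits, y)
        assert loss == pytest.approx(np.log(2), abs=0.2)

    def test_separable_data_reaches_high_validation_accuracy(self):
        # strong planted signal: a linear baseline separates it, so the
        # transformer must too
        (tr, va, te), table, truth, idx, fitted = build_ssl_problem(
            seed=31, n_variants=1200, signal_strength=3.0
        )
        from sklearn.linear_model import LogisticRegression

        lin = LogisticRegression(max_iter=1000).fit(
            tr.X_num, truth.true_class[tr.row_ids]
        )
        assert lin.score(va.X_num, truth.true_class[va.row_ids]) > 0.95

        mcfg = compact_model_config(tr, fitted)
        tcfg = TrainConfig(**FAST_TRAIN, seed=3)
        y_tr = truth.true_class[tr.row_ids].astype(float)
        y_va = truth.true_class[va.row_ids].astype(float)
        model = init_model(mcfg, seed=5)
        model, info = train_supervised(
            model,
            (tr.X_num, tr.X_cat, y_tr, np.ones(tr.n_rows)),
            (va.X_num, va.X_cat, y_va, np.ones(va.n_rows)),
            tcfg,
        )
        calls = (model.predict_logits(va.X_num, va.X_cat) > 0).astype(int)
        assert (calls == truth.true_class[va.row_ids]).mean() > 0.95

    def test_label_smoothing_caps_optimal_logit(self):
        # all-pathogenic toy batch: with smoothing the optimal logit is the
        # finite ln((1-a/2)/(a/2)); without it the logit keeps growing
        cfg = FTTConfig(
            n_numerical=1, categorical_cardinalities=(), token_dim=8,
            n_layers=1, n_heads=2, ffn_hidden=8,
            dropout_attention=0, dropout_ffn=0, dropout_residual=0,
        )
        Xn = np.ones((16, 1), dtype=np.float32)
        Xc = np.zeros((16, 0), dtype=int)
        y = np.ones(16)
        out = {}
        for alpha in (0.0, 0.05):
            model = init_model(cfg, seed=9)
            tcfg = TrainConfig(
                learning_rate=0.05, batch_size=None, max_epochs=400,
                patience=400, label_smoothing=alpha, seed=9,
            )
            model, _ = train_supervised(
                model, (Xn, Xc, y, np.ones(16)), (Xn, Xc, y, np.ones(16)), tcfg
            )
            out[alpha] = model.predict_logits(Xn, Xc).mean()
        optimum = np.log((1 - 0.025) / 0.025)  # ~3.66 for alpha=0.05
        assert out[0.05] == pytest.approx(optimum, abs=0.8)
        assert out[0.0] > out[0.05] + 1.0

    def test_empty_training_set_rejected(self):
        cfg = FTTConfig(n_numerical=1, token_dim=8, n_heads=2, ffn_hidden=4)
        model = init_model(cfg, seed=0)
        empty = (np.zeros((0, 1)), np.zeros((0, 0), dtype=int), np.zeros(0),
                 np.zeros(0))
        with pytest.raises(ContractError):
            train_supervised(model, empty, empty, TrainConfig())


@pytest.fixture(scope="module")
def ssl_problem():
    return build_ssl_problem(seed=77, n_variants=1500)


class TestRunSemisupervised:
    def test_threshold_one_equals_warm_start(self, ssl_problem):
        (tr, va, _), _, _, _, fitted = ssl_problem
        mcfg = compact_model_config(tr, fitted)
        base = TrainConfig(**FAST_TRAIN, seed=13)
        warm, hist_warm = run_semisupervised(
            tr, va, mcfg, TrainConfig(**FAST_TRAIN, seed=13, max_ssl_iterations=0)
        )
        capped, hist = run_semisupervised(
            tr, va, mcfg,
            TrainConfig(**FAST_TRAIN, seed=13, confidence_threshold=1.0),
        )
        assert hist.termination_reason == "no_new_promotions"
        assert all(rec.n_promoted == 0 for rec in hist.iterations)
        for k in warm.params:
            np.testing.assert_array_equal(warm.params[k], capped.params[k])

    def test_history_contracts(self, ssl_problem):
        (tr, va, _), _, _, _, fitted = ssl_problem
        mcfg = compact_model_config(tr, fitted)
        model, hist = run_semisupervised(
            tr, va, mcfg, TrainConfig(**FAST_TRAIN, seed=21)
        )
        assert len(hist.iterations) <= 10
        assert hist.termination_reason in ("no_new_promotions", "max_iterations")
        # monotone pool growth, strictly until termination
        sizes = [rec.train_pool_size + rec.val_pool_size for rec in hist.iterations]
        for a, b in zip(sizes, sizes[1:]):
            assert b >= a
        for rec in hist.iterations[1:-1]:
            assert rec.n_promoted >= 0
        # promoted ids disjoint across iterations
        all_ids = hist.promoted_ids()
        assert len(all_ids) == len(set(all_ids))
        # n_promoted <= n_candidates
        for rec in hist.iterations:
            assert rec.n_promoted <= rec.n_candidates

    def test_pseudo_labels_frozen_across_iterations(self, ssl_problem):
        (tr, va, _), _, _, _, fitted = ssl_problem
        mcfg = compact_model_config(tr, fitted)
        _, hist = run_semisupervised(
            tr, va, mcfg, TrainConfig(**FAST_TRAIN, seed=22)
        )
        seen: dict[int, int] = {}
        for rec in hist.iterations:
            for rid, lab in rec.labels.items():
                assert rid not in seen  # never reassigned
                seen[rid] = lab

    def test_zero_pseudo_weight_matches_hard_only_schedule(self, ssl_problem):
        # with pseudo losses weighted 0, deterministic training (no dropout,
        # full batch) must follow the exact trajectory of retraining on the
        # hard rows alone for the same schedule
        (tr, va, _), _, _, _, fitted = ssl_problem
        base = compact_model_config(tr, fitted)
        mcfg = FTTConfig(
            n_numerical=base.n_numerical,
            categorical_cardinalities=base.categorical_cardinalities,
            token_dim=16, n_layers=2, n_heads=2, ffn_hidden=32,
            dropout_attention=0, dropout_ffn=0, dropout_residual=0,
        )
        kwargs = dict(
            learning_rate=3e-3, batch_size=None, max_epochs=5, patience=5,
            seed=33, max_ssl_iterations=3,
        )
        zero_w, hist = run_semisupervised(
            tr, va, mcfg, TrainConfig(**kwargs, pseudo_loss_weight=0.0),
            dtype=np.float64,
        )
        n_fits = 1 + sum(1 for rec in hist.iterations if rec.n_promoted > 0)

        # replay: same seeds, same number of retraining rounds, hard rows only
        from pathoftt.ssl_trainer import train_supervised as ts

        seeds = np.random.SeedSequence(33).spawn(5)
        ref = init_model(
            mcfg, seed=int(seeds[0].generate_state(1)[0]) % 2**31,
            dtype=np.float64,
        )
        hard_tr = (
            tr.X_num[tr.hard_mask], tr.X_cat[tr.hard_mask],
            tr.binary[tr.hard_mask], np.ones(int(tr.hard_mask.sum())),
        )
        hard_va = (
            va.X_num[va.hard_mask], va.X_cat[va.hard_mask],
            va.binary[va.hard_mask], np.ones(int(va.hard_mask.sum())),
        )
        cfg = TrainConfig(**kwargs, pseudo_loss_weight=0.0)
        for i in range(n_fits):
            rng = np.random.default_rng(seeds[i + 1])
            ts(ref, hard_tr, hard_va, cfg, rng=rng)
        for k in ref.params:
            np.testing.assert_allclose(
                zero_w.params[k], ref.params[k], atol=1e-5,
                err_msg=f"parameter {k} diverged",
            )

    def test_predict_covers_all_categories(self, ssl_problem):
        (tr, va, te), table, _, idx, fitted = ssl_problem
        mcfg = compact_model_config(tr, fitted)
        model, _ = run_semisupervised(
            tr, va, mcfg, TrainConfig(**FAST_TRAIN, seed=44, max_ssl_iterations=1)
        )
        test_table = table.subset_rows(idx["test"])
        logits, probs, calls = predict(model, fitted, test_table)
        assert logits.shape[0] == test_table.n_rows  # VUS rows included
        # strict monotonicity of the logit -> probability map
        order = np.argsort(logits)
        assert (np.diff(probs[order]) >= 0).all()
        assert set(np.unique(calls)).issubset({0, 1})
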