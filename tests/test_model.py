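"""Reference trainer: parameter counts, gradients, training protocol."""

import numpy as np
import pytest

from afedge import (ConfigError, DegenerateDataError, ModelSpec, TrainConfig,
                    WindowSet, build_model, confusion_from_pairs,
                    count_parameters, predict, predict_proba, train)
from afedge.model import (_backward_full, _forward_full, bce_loss_and_dlogits,
                          write_history_csv)

from conftest import build_corpus


class TestCountParameters:
    def test_unit_size_closed_form(self):
        counts = count_parameters(ModelSpec(lstm_units=1, input_features=1,
                                            dense_units=1))
        assert counts["lstm_forward"] == 12  # 4*(1*(1+1)+1)

    @pytest.mark.parametrize("U,D", [(1, 1), (3, 7), (12, 5), (40, 50),
                                     (64, 64), (17, 33), (5, 64), (64, 1)])
    def test_closed_form_equals_introspection(self, U, D):
        """Closed forms must match the sizes of the actually built tensors."""
        spec = ModelSpec(lstm_units=U, dense_units=D)
        closed = count_parameters(spec)
        introspected = build_model(spec, seed=0).parameter_counts()
        assert closed == introspected

    def test_bundle_total_matches(self):
        spec = ModelSpec(lstm_units=6, dense_units=9)
        bundle = build_model(spec, seed=1).to_bundle()
        assert bundle.total_parameters() == count_parameters(spec)["total"]


class TestForwardPass:
    def test_batch_maps_to_probabilities(self, rng):
        bundle = build_model(ModelSpec(), seed=2).to_bundle()
        probs = predict_proba(bundle, rng.uniform(0.4, 1.2, (3, 40)))
        assert probs.shape == (3,)
        assert np.all((probs > 0) & (probs < 1))

    def test_constant_input_deterministic_across_calls(self):
        bundle = build_model(ModelSpec(), seed=3).to_bundle()
        w = np.full((1, 40), 0.8)
        assert predict_proba(bundle, w) == predict_proba(bundle, w)

    def test_gradients_match_finite_differences(self, rng):
        """BPTT gradients vs a central-difference oracle on a tiny network."""
        spec = ModelSpec(input_len=6, lstm_units=3, dense_units=4,
                         dropout_rate=0.0)
        model = build_model(spec, seed=4)
        X = rng.normal(0.8, 0.1, (5, 6, 1))
        y = np.array([0, 1, 1, 0, 1])
        z, caches = _forward_full(X, model.params)
        _, dz = bce_loss_and_dlogits(z, y)
        grads = _backward_full(dz, model.params, caches)

        def loss_at(params):
            zz, _ = _forward_full(X, params)
            return bce_loss_and_dlogits(zz, y)[0]

        eps = 1e-6
        for name, tensor in model.params.items():
            for _ in range(3):  # spot-check entries of every tensor
                idx = tuple(rng.integers(0, s) for s in tensor.shape)
                trial = {k: v.copy() for k, v in model.params.items()}
                trial[name][idx] += eps
                up = loss_at(trial)
                trial[name][idx] -= 2 * eps
                down = loss_at(trial)
                numeric = (up - down) / (2 * eps)
                assert grads[name][idx] == pytest.approx(numeric, rel=1e-3,
                                                         abs=1e-9), name


class TestTrain:
    def _small(self, n=100, seed=0):
        return build_corpus(n, seed=seed)

    def _spec(self):
        return ModelSpec(lstm_units=8, dense_units=8)

    def test_single_epoch_history(self):
        ws = self._small()
        bundle, hist = train(build_model(self._spec(), seed=5), ws,
                             TrainConfig(max_epochs=1, patience=0, seed=5))
        assert hist["epoch"] == [1]
        assert all(np.isfinite(hist[k][0]) for k in ("loss", "val_loss"))

    def test_rerun_reproduces_weights_exactly(self):
        ws = self._small()
        cfg = TrainConfig(max_epochs=2, patience=1, seed=6)
        b1, _ = train(build_model(self._spec(), seed=6), ws, cfg)
        b2, _ = train(build_model(self._spec(), seed=6), ws, cfg)
        for k in b1.tensors:
            assert b1.tensors[k].tobytes() == b2.tensors[k].tobytes()

    def test_single_class_is_degenerate(self):
        ws = self._small()
        only_af = ws.subset(np.nonzero(ws.labels == 1)[0])
        with pytest.raises(DegenerateDataError):
            train(build_model(self._spec()), only_af, TrainConfig())

    def test_best_checkpoint_not_worse_than_final_epoch(self):
        ws = self._small(150, seed=1)
        _, hist = train(build_model(self._spec(), seed=7), ws,
                        TrainConfig(max_epochs=5, patience=4, seed=7))
        assert all(np.isfinite(v) for v in hist["loss"])
        assert min(hist["val_loss"]) <= hist["val_loss"][-1]

    def test_class_swap_symmetry(self):
        """Flipping every label of a balanced corpus trains to statistically
        indistinguishable held-out accuracy (fixed seeds)."""
        ws = self._small(200, seed=2)
        flipped = WindowSet(ws.windows, 1 - ws.labels, ws.record_ids,
                            ws.start_indices)
        accs = []
        for corpus in (ws, flipped):
            cfg = TrainConfig(max_epochs=4, patience=3, seed=8)
            bundle, _ = train(build_model(self._spec(), seed=8), corpus, cfg)
            preds, _ = predict(bundle, corpus)
            accs.append((preds == corpus.labels).mean())
        assert abs(accs[0] - accs[1]) <= 0.02

    def test_history_csv(self, tmp_path):
        ws = self._small()
        _, hist = train(build_model(self._spec(), seed=5), ws,
                        TrainConfig(max_epochs=1, patience=0, seed=5))
        p = tmp_path / "history.csv"
        write_history_csv(hist, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "epoch,loss,acc,val_loss,val_acc"
        assert len(lines) == 2

    def test_config_invariants(self):
        with pytest.raises(ConfigError):
            TrainConfig(loss="categorical_crossentropy").validate()
        with pytest.raises(ConfigError):
            TrainConfig(max_epochs=5, patience=5).validate()


class TestPredict:
    def test_threshold_rule(self, rng):
        bundle = build_model(ModelSpec(), seed=9).to_bundle()
        W = rng.uniform(0.4, 1.2, (20, 40))
        preds, probs = predict(bundle, W, threshold=0.5)
        assert np.array_equal(preds, (probs >= 0.5).astype(int))
        all_one, _ = predict(bundle, W, threshold=0.0)
        assert np.all(all_one == 1)

    def test_feeds_confusion_counts_consistently(self, rng):
        bundle = build_model(ModelSpec(), seed=10).to_bundle()
        W = rng.uniform(0.4, 1.2, (20, 40))
        truth = rng.integers(0, 2, 20)
        preds, _ = predict(bundle, W)
        c = confusion_from_pairs(truth, preds)
        # hand-counted quadrants
        assert c.tp == int(np.sum((truth == 1) & (preds == 1)))
        assert c.total == 20

    def test_shape_mismatch_rejected(self, rng):
        bundle = build_model(ModelSpec(), seed=11).to_bundle()
        with pytest.raises(Exception):
            predict(bundle, rng.uniform(0.4, 1.2, (3, 39)))
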