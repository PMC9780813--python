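"""Network architecture: shapes, closed-form parameter counts, exact
gradients (finite-difference oracle), persistence, and metric arithmetic."""

import numpy as np
import pytest

from ecgspect import ModelSpec, SmallCnn, build_model, count_parameters, evaluate_model


class TestParameterCount:
    def test_first_conv_block(self):
        spec = ModelSpec(conv_filters=(64,), dropout_rates=(0.25,))
        # 3*3*1*64 + 64 kernel+bias, then the dense path on 31*31*64
        assert count_parameters(spec) == 640 + (31 * 31 * 64) * 8 + 8 + 9

    def test_output_layer_is_nine_parameters(self):
        a = count_parameters(ModelSpec(dense_units=8))
        b = count_parameters(ModelSpec(dense_units=8, conv_filters=(), dropout_rates=()))
        assert b == 64 * 64 * 8 + 8 + 9
        assert a - b > 0  # conv stack adds the rest

    def test_default_spec_is_519249(self):
        assert count_parameters(ModelSpec()) == 519_249

    def test_same_padding_is_525393(self):
        assert count_parameters(ModelSpec(padding="same")) == 525_393

    def test_dense_only_path(self):
        spec = ModelSpec(conv_filters=(), dropout_rates=())
        assert count_parameters(spec) == 4096 * 8 + 8 + 9 == 32_785

    @pytest.mark.parametrize(
        "filters,padding",
        [((4,), "valid"), ((4, 8), "valid"), ((4, 8), "same"), ((2, 2, 2, 2), "valid")],
    )
    def test_closed_form_equals_realized_total(self, filters, padding):
        spec = ModelSpec(
            conv_filters=filters,
            dropout_rates=(0.0,) * len(filters),
            padding=padding,
            input_size=(46, 46),
        )
        model, n = build_model(spec, seed=0)
        assert n == count_parameters(spec) == model.n_parameters()

    def test_feature_shapes_valid_padding(self):
        shapes = ModelSpec().feature_shapes()
        assert shapes == [(31, 31, 64), (14, 14, 128), (6, 6, 256), (2, 2, 64)]
        assert ModelSpec().flatten_width == 256

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build_model(ModelSpec(input_size=(16, 16)))


class TestGradients:
    def _check(self, spec, seed=1, n_probe=6):
        model = SmallCnn(spec, seed=seed, dtype=np.float64)
        rng = np.random.default_rng(seed + 1)
        x = rng.normal(size=(4, *spec.input_size))
        y = rng.integers(0, 2, 4).astype(float)
        _, grads = model.loss_and_gradients(x, y, training=False)
        params = model.parameters
        eps = 1e-6
        for pi, p in enumerate(params):
            flat = p.ravel()
            for j in rng.choice(flat.size, size=min(n_probe, flat.size), replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                model.set_parameters(params)
                lp, _ = model.loss_and_gradients(x, y, training=False)
                flat[j] = orig - eps
                model.set_parameters(params)
                lm, _ = model.loss_and_gradients(x, y, training=False)
                flat[j] = orig
                model.set_parameters(params)
                num = (lp - lm) / (2 * eps)
                ana = grads[pi].ravel()[j]
                assert abs(num - ana) <= 1e-6 + 1e-4 * (abs(num) + abs(ana))

    def test_valid_padding_gradients_match_finite_differences(self):
        self._check(
            ModelSpec(
                input_size=(14, 14),
                conv_filters=(3, 4),
                dropout_rates=(0.0, 0.0),
                dense_units=5,
                l1_activity=1e-3,
            )
        )

    def test_same_padding_gradients_match_finite_differences(self):
        self._check(
            ModelSpec(
                input_size=(12, 12),
                conv_filters=(3,),
                dropout_rates=(0.0,),
                dense_units=4,
                padding="same",
            )
        )


class TestForward:
    def test_logit_shape_and_determinism(self):
        spec = ModelSpec(input_size=(46, 46), conv_filters=(2, 2, 2, 2),
                         dropout_rates=(0.25, 0.0, 0.25, 0.25), dense_units=3)
        model = SmallCnn(spec, seed=0)
        x = np.random.default_rng(0).normal(size=(5, 46, 46))
        a = model.forward(x)
        b = model.forward(x)
        assert a.shape == (5,)
        np.testing.assert_array_equal(a, b)

    def test_dropout_draws_require_rng(self):
        spec = ModelSpec(input_size=(46, 46), conv_filters=(2, 2, 2, 2),
                         dropout_rates=(0.25, 0.0, 0.25, 0.25))
        model = SmallCnn(spec, seed=0)
        x = np.zeros((1, 46, 46))
        with pytest.raises(ValueError, match="rng"):
            model.forward(x, training=True)

    def test_save_load_round_trip(self, tmp_path):
        spec = ModelSpec(input_size=(46, 46), conv_filters=(2, 3, 2, 2),
                         dropout_rates=(0.0,) * 4, dense_units=3)
        model = SmallCnn(spec, seed=5)
        x = np.random.default_rng(1).normal(size=(3, 46, 46))
        expected = model.predict_proba(x)
        model.save_weights(tmp_path / "w.npz")
        loaded = SmallCnn.load_weights(tmp_path / "w.npz")
        np.testing.assert_allclose(loaded.predict_proba(x), expected, atol=1e-7)


class TestEvalMetrics:
    def test_perfect_predictions(self):
        labels = np.array([0, 1, 1, 0, 1])
        m = evaluate_model(labels.astype(float), labels)
        assert m.accuracy == 1.0
        assert m.precision == m.sensitivity == m.specificity == 1.0

    def test_ratio_arithmetic(self):
        preds = np.concatenate([np.ones(99), [0.0], np.zeros(100)])
        labels = np.concatenate([np.ones(100), np.zeros(100)])
        m = evaluate_model(preds, labels)
        assert (m.tp, m.fn, m.tn, m.fp) == (99, 1, 100, 0)
        assert m.sensitivity == pytest.approx(0.99)
        assert m.specificity == 1.0
        assert m.precision == 1.0
        assert m.accuracy == (m.tp + m.tn) / 200

    def test_undefined_precision_reported_absent(self):
        m = evaluate_model(np.zeros(4), np.array([1, 1, 0, 0]))
        assert m.sensitivity == 0.0
        assert m.precision is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="predictions"):
            evaluate_model(np.zeros(3), np.zeros(4))

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            evaluate_model(np.zeros(2), np.array([0.5, 1.0]))
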