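"""Model construction, loss/metric definitions, and the training loop."""

import math

import numpy as np
import pytest

from specband import _nn, models, pipeline as pl, synthcube
from specband.models import (ModelSpec, TrainConfig, build_cnn, build_fnn,
                             lr_schedule, mae, preset_spec, r_squared, rmsle,
                             train)


def _fnn_param_count_oracle(n_in, widths):
    """Σ(in·out + out) for dense layers plus 2 BN terms per hidden block."""
    total = 0
    for w in widths[:-1]:
        total += n_in * w + w      # dense
        total += 2 * w             # batch-norm gamma/beta
        n_in = w
    total += n_in * 1 + 1          # scalar head
    return total


class TestBuilders:
    def test_fnn_published_layer_widths(self):
        spec, _ = preset_spec("fnn_multi", "VIS", (261,))
        assert spec.fc_units == (256, 128, 64, 32, 1)
        model = build_fnn(spec)
        widths = [l.params[0].shape[1] for l in model.layers
                  if isinstance(l, _nn.Dense)]
        assert widths == [256, 128, 64, 32, 1]

    def test_fnn_parameter_count_matches_closed_form(self):
        spec, _ = preset_spec("fnn_multi", "VISWIR", (261,))
        model = build_fnn(spec)
        got = sum(p.size for p in model.params)
        assert got == _fnn_param_count_oracle(261, spec.fc_units)

    def test_fnn_signature_has_no_dropout(self):
        spec, _ = preset_spec("fnn_signature", "VISWIR", (6,))
        model = build_fnn(spec)
        assert not any(isinstance(l, _nn.Dropout) for l in model.layers)
        assert spec.fc_units == (512, 256, 128, 64, 1)

    def test_fnn_forward_finite_on_zeros(self):
        spec, _ = preset_spec("fnn_multi", "VIS", (30,))
        out = build_fnn(spec).predict(np.zeros((5, 30)))
        assert out.shape == (5, 1)
        assert np.isfinite(out).all()

    def test_fc_units_must_end_in_one(self):
        with pytest.raises(ValueError, match="1"):
            ModelSpec(family="fnn_multi", input_shape=(10,),
                      fc_units=(64, 32))

    def test_cnn_viswir_flattened_feature_length(self):
        # shape oracle: 20x20 'same' convs, two 1x2 pools -> 20x5x64
        spec, _ = preset_spec("cnn_multi", "VISWIR", (20, 20, 261))
        assert spec.conv_kernel == (1, 5)
        assert spec.fc_units == (2048, 512, 1)
        model = build_cnn(spec)
        first_dense = next(l for l in model.layers
                           if isinstance(l, _nn.Dense))
        assert first_dense.params[0].shape[0] == 20 * 5 * 64

    def test_cnn_signature_architecture_accepted(self):
        spec, _ = preset_spec("cnn_signature", "VISWIR", (20, 20, 6))
        assert spec.conv_kernel == (4, 1)
        assert spec.pool_sizes == ((2, 2),)
        model = build_cnn(spec)
        convs = [l for l in model.layers if isinstance(l, _nn.Conv2D)]
        pools = [l for l in model.layers if isinstance(l, _nn.AvgPool2D)]
        assert len(convs) == 4 and len(pools) == 1
        out = model.predict(np.zeros((2, 20, 20, 6)))
        assert out.shape == (2, 1)
        assert np.isfinite(out).all() and (out >= 0).all()

    def test_cnn_forward_nonnegative_relu_head(self, rng):
        spec, _ = preset_spec("cnn_multi", "VIS", (8, 8, 15))
        out = build_cnn(spec).predict(rng.uniform(size=(3, 8, 8, 15)))
        assert (out >= 0).all()

    def test_pooling_collapse_raises_with_layer_named(self):
        spec, _ = preset_spec("cnn_multi", "VIS", (1, 1, 15))
        with pytest.raises(ValueError, match="pool"):
            build_cnn(spec)


class TestLossAndMetrics:
    def test_rmsle_zero_iff_equal(self, rng):
        y = rng.uniform(1, 10, size=20)
        assert rmsle(y, y) == 0.0
        assert rmsle(y + 0.1, y) > 0.0

    def test_rmsle_closed_form_example(self):
        assert rmsle([math.e - 1.0], [0.0]) == pytest.approx(1.0, abs=1e-12)

    def test_rmsle_two_term_hand_computation(self):
        expect = math.sqrt(((math.log(2) - math.log(3)) ** 2
                            + (math.log(4) - math.log(3)) ** 2) / 2)
        assert rmsle([1.0, 3.0], [2.0, 2.0]) == pytest.approx(expect,
                                                              abs=1e-12)

    def test_rmsle_rejects_negative(self):
        with pytest.raises(ValueError, match="nonnegative"):
            rmsle([-0.5], [1.0])

    def test_lr_schedule(self):
        assert lr_schedule(0.0006, 1e-6, 0) == 0.0006
        assert lr_schedule(0.0006, 1e-6, 10 ** 6) == pytest.approx(
            0.0006 / math.e, rel=1e-12)
        assert lr_schedule(0.0006, 1e-6, 10 ** 6) == pytest.approx(
            2.2073e-4, rel=1e-4)
        with pytest.raises(ValueError):
            lr_schedule(-1.0, 1e-6, 0)

    def test_mae_examples_and_invariances(self, rng):
        assert mae([1.0, 2.0], [2.0, 4.0]) == 1.5
        a, b = rng.uniform(size=10), rng.uniform(size=10)
        assert mae(a, b) == mae(b, a)
        assert mae(a + 3.0, b + 3.0) == pytest.approx(mae(a, b), abs=1e-12)

    def test_r_squared_definition_limits(self, rng):
        y = rng.uniform(5, 15, size=30)
        assert r_squared(y, y) == 1.0
        assert r_squared(np.full_like(y, y.mean()), y) == pytest.approx(
            0.0, abs=1e-12)
        with pytest.raises(ValueError, match="variance"):
            r_squared(y[:3], np.full(3, 7.0))

    def test_r_squared_literal_ybar_mode_differs(self, rng):
        y = rng.uniform(5, 15, size=30)
        p = y + rng.normal(0, 2, size=30)
        assert r_squared(p, y) != r_squared(p, y, literal_ybar=True)


def _toy_task(n=60, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, size=(n, 8))
    y = 8.0 + 4.0 * x[:, 2] + 0.05 * rng.normal(size=n)
    return (x[:40], y[:40]), (x[40:], y[40:])


class TestTraining:
    def test_zero_epochs_returns_initial_weights(self):
        spec, _ = preset_spec("fnn_multi", "VIS", (8,))
        model = models.build_model(spec, seed=1)
        before = [p.copy() for p in model.params]
        tr, va = _toy_task()
        model, metrics = train(model, tr, va, TrainConfig(max_epochs=0))
        assert metrics.train_loss == [] and metrics.valid_loss == []
        # every weight untouched except the documented head-bias
        # warm-start at the training-label mean
        head_bias = model.layers[-2].params[1]
        assert head_bias[0] == pytest.approx(np.mean(tr[1]))
        for p, q in zip(model.params[:-1], before[:-1]):
            assert np.array_equal(p, q)

    def test_checkpoint_achieves_min_of_validation_history(self):
        spec, _ = preset_spec("fnn_multi", "VIS", (8,))
        model = models.build_model(spec, seed=1)
        tr, va = _toy_task()
        cfg = TrainConfig(max_epochs=30, batch_size=16, seed=2)
        model, metrics = train(model, tr, va, cfg)
        final = rmsle(model.predict(va[0]), va[1])
        assert final == pytest.approx(min(metrics.valid_loss), abs=1e-9)

    def test_histories_length_and_reproducibility(self):
        tr, va = _toy_task()
        cfg = TrainConfig(max_epochs=12, patience=100, batch_size=16, seed=5)
        runs = []
        for _ in range(2):
            spec, _ = preset_spec("fnn_multi", "VIS", (8,))
            model = models.build_model(spec, seed=3)
            _, metrics = train(model, tr, va, cfg)
            runs.append(metrics)
        assert runs[0].epochs_run == 12
        assert len(runs[0].valid_loss) == 12
        assert runs[0].valid_loss == runs[1].valid_loss  # bitwise identical

    def test_validation_mae_near_noise_floor_on_linear_task(self):
        """With reflectance noise σ the best achievable absolute error of a
        Gaussian residual is σ·sqrt(2/π); a trained FNN should approach it
        on a synthetic linear task (2 of 3 seeds within 1.25×)."""
        sigma = 0.3
        bound = 1.25 * sigma * math.sqrt(2 / math.pi)
        hits = 0
        for seed in (0, 1, 2):
            params = synthcube.small_params(noise_sd=sigma,
                                            group_sizes=(60,) * 5, seed=seed)
            samples, _ = synthcube.generate_dataset(params)
            cfg = pl.PipelineConfig(ranges_block_a=("VISWIR",),
                                    half_bandwidths_block_a=(10.0,),
                                    families=("fnn",), seed=seed,
                                    max_epochs=200, patience=60)
            cells, _ = pl.run_block_a(samples, cfg)
            cell = cells[("fnn", "VISWIR", 10.0)]
            val_pred = None  # validation MAE via the recorded split
            idx = {s.sample_id: i for i, s in enumerate(samples)}
            x3, x1, y = pl._resample_samples(
                pl.prepare_samples(samples, cfg), cell.grid)
            va = np.array([idx[i] for i in cell.split.valid_ids])
            val_mae = mae(cell.model.predict(x1[va]).ravel(), y[va])
            hits += val_mae <= bound
        assert hits >= 2

    def test_checkpoint_round_trip(self, tmp_path):
        spec, _ = preset_spec("fnn_multi", "VIS", (8,))
        model = models.build_model(spec, seed=1)
        tr, va = _toy_task()
        model, _ = train(model, tr, va, TrainConfig(max_epochs=5,
                                                    batch_size=16))
        path = str(tmp_path / "ckpt.npz")
        models.save_checkpoint(model, spec, path)
        back, back_spec = models.load_checkpoint(path)
        assert back_spec.fc_units == spec.fc_units
        x = np.random.default_rng(0).uniform(size=(4, 8))
        assert np.allclose(back.predict(x), model.predict(x), atol=1e-12)
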