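"""Schedule, training step, collapse metric, checkpointing, export."""

import numpy as np
import pytest

import fpsiam as fp
from fpsiam.trainer import (CollapseMetrics, TrainConfig, apply_schedule,
                            build_optimizer, collapse_metric, cosine_lr,
                            export_backbone, load_exported_backbone)

from conftest import make_tiny_model


class TestCosineSchedule:
    CFG = TrainConfig(batch_size=2, epochs=200, base_lr=0.05)

    def test_initial_rate(self):
        assert cosine_lr(0, self.CFG) == pytest.approx(0.05)

    def test_final_rate_is_zero(self):
        assert cosine_lr(200, self.CFG) == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_is_half(self):
        assert cosine_lr(100, self.CFG) == pytest.approx(0.025)

    def test_beyond_schedule_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            assert cosine_lr(250, self.CFG) == pytest.approx(0.0, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(-1, self.CFG)

    def test_prediction_head_rate_stays_fixed(self, small_corpus):
        """At every schedule position the prediction head's group keeps the
        base rate while the encoder groups follow the cosine curve."""
        model = make_tiny_model(small_corpus, epochs=10, batch_size=8)
        for epoch in [0, 2.5, 5, 7.5, 10]:
            lr = apply_schedule(model.optimizer, epoch, model.train_config)
            for group in model.optimizer.param_groups:
                if group["fixed_lr"]:
                    assert group["lr"] == model.train_config.base_lr
                else:
                    assert group["lr"] == lr == cosine_lr(
                        epoch, model.train_config)

    def test_weight_decay_spares_bn_and_biases(self, small_corpus):
        model = make_tiny_model(small_corpus)
        for group in model.optimizer.param_groups:
            wd = group["weight_decay"]
            for p in group["params"]:
                if p.data.ndim == 1:
                    assert wd == 0.0
                else:
                    assert wd == model.train_config.weight_decay


class TestTrainingStep:
    def test_single_step_loss_finite_and_bounded(self, small_corpus):
        model = make_tiny_model(small_corpus, batch_size=8)
        res = model.fit(max_steps=1)
        b = res.history[-1]
        assert np.isfinite(b.L_total)
        assert -1.0 <= b.L_local <= 1.0 and -1.0 <= b.L_global <= 1.0

    def test_identical_seeds_give_identical_trajectories(self, small_corpus):
        r1 = make_tiny_model(small_corpus, seed=4, batch_size=8).fit(max_steps=4)
        r2 = make_tiny_model(small_corpus, seed=4, batch_size=8).fit(max_steps=4)
        assert np.array_equal(r1.losses, r2.losses)

    def test_different_seeds_differ(self, small_corpus):
        r1 = make_tiny_model(small_corpus, seed=1, batch_size=8).fit(max_steps=2)
        r2 = make_tiny_model(small_corpus, seed=2, batch_size=8).fit(max_steps=2)
        assert not np.array_equal(r1.losses, r2.losses)

    def test_parameters_change_after_step(self, small_corpus):
        model = make_tiny_model(small_corpus, batch_size=8)
        before = {k: v.copy() for k, v in model.network.state_dict().items()}
        model.fit(max_steps=1)
        after = model.network.state_dict()
        changed = [k for k in before
                   if not np.array_equal(before[k], after[k])]
        assert changed


class TestCollapseMetric:
    def test_identical_rows_give_zero(self):
        z = np.tile(np.array([1.0, 2.0, 3.0]), (16, 1))
        assert collapse_metric(z).per_channel_std == pytest.approx(0.0)

    def test_uniform_sphere_matches_reference(self):
        """Rows uniform on the unit sphere in dimension d have per-channel
        std ~ 1/sqrt(d) (Monte-Carlo oracle, 10% tolerance at batch 1024)."""
        d = 32
        rng = np.random.default_rng(0)
        z = rng.normal(size=(1024, d))
        m = collapse_metric(z)
        assert m.per_channel_std == pytest.approx(1 / np.sqrt(d), rel=0.1)
        assert m.expected_nocollapse == pytest.approx(1 / np.sqrt(d))

    def test_one_hot_rows_closed_form(self):
        """One-hot rows uniformly over d channels: each channel is
        Bernoulli(1/d), std sqrt(p(1-p)) with p = 1/d."""
        d, n = 8, 8000
        rng = np.random.default_rng(1)
        z = np.eye(d)[rng.integers(0, d, n)]
        p = 1 / d
        expected = np.sqrt(p * (1 - p))
        assert collapse_metric(z).per_channel_std == pytest.approx(
            expected, rel=0.05)

    def test_small_batch_rejected(self):
        with pytest.raises(ValueError, match="batch"):
            collapse_metric(np.ones((4, 8)))

    def test_ratio_property(self):
        m = CollapseMetrics(per_channel_std=0.05, expected_nocollapse=0.1)
        assert m.ratio == pytest.approx(0.5)


class TestCheckpointing:
    def test_resume_reproduces_uninterrupted_trajectory(self, small_corpus,
                                                        tmp_path):
        full = make_tiny_model(small_corpus, seed=3, batch_size=8)
        r_full = full.fit(max_steps=6)

        part = make_tiny_model(small_corpus, seed=3, batch_size=8)
        part.fit(max_steps=3)
        ckpt = part.save(tmp_path / "mid.npz")

        resumed = make_tiny_model(small_corpus, seed=3, batch_size=8)
        resumed.load(ckpt)
        r_resumed = resumed.fit(max_steps=3)
        assert np.allclose(r_full.losses[3:], r_resumed.losses, atol=1e-6)

    def test_save_load_round_trip_is_exact(self, small_corpus, tmp_path):
        model = make_tiny_model(small_corpus, batch_size=8)
        model.fit(max_steps=2)
        path = model.save(tmp_path / "ckpt.npz")
        other = make_tiny_model(small_corpus, seed=77, batch_size=8)
        other.load(path)
        for (ka, va), (kb, vb) in zip(
                sorted(model.network.state_dict().items()),
                sorted(other.network.state_dict().items())):
            assert ka == kb and np.array_equal(va, vb)
        assert other.global_step == 2


class TestExportBackbone:
    def test_round_trip_bit_exact(self, small_corpus, tmp_path):
        model = make_tiny_model(small_corpus, batch_size=8)
        model.fit(max_steps=1)
        path = export_backbone(model.network, tmp_path / "bb.npz")
        fresh = fp.load_backbone(fp.tiny_backbone_spec(seed=123))
        load_exported_backbone(path, fresh)
        for (ka, va), (kb, vb) in zip(
                sorted(model.network.backbone.state_dict().items()),
                sorted(fresh.state_dict().items())):
            assert ka == kb and np.array_equal(va, vb)

    def test_excludes_head_and_pyramid_keys(self, small_corpus, tmp_path):
        model = make_tiny_model(small_corpus, batch_size=8)
        path = export_backbone(model.network, tmp_path / "bb.npz")
        with np.load(path) as data:
            keys = set(data.files)
        assert not any(k.startswith(("pyramid", "projection", "prediction"))
                       for k in keys)

    def test_keys_load_into_backbone_spec_slot(self, small_corpus, tmp_path):
        """The exported layout is exactly what BackboneSpec(init="checkpoint")
        consumes — the hand-off contract to a downstream detector."""
        model = make_tiny_model(small_corpus, batch_size=8)
        path = export_backbone(model.network, tmp_path / "bb.npz")
        spec = fp.BackboneSpec(name="convstage", stage_channels=(8, 16, 32),
                               stage_strides=(2, 4, 8), init="checkpoint",
                               weights_path=str(path))
        net = fp.load_backbone(spec)
        feats = fp.extract_multiscale(
            net, np.zeros((2, 3, 64, 64), np.float32))
        assert feats.channels == (8, 16, 32)


class TestResultsSummary:
    def test_summary_reports_key_quantities(self, small_corpus):
        model = make_tiny_model(small_corpus, batch_size=8)
        res = model.fit(max_steps=2)
        text = res.summary()
        assert "L_total" in text and "collapse metric" in text
        assert "lambda" in text

    def test_history_frame_columns(self, small_corpus):
        model = make_tiny_model(small_corpus, batch_size=8)
        res = model.fit(max_steps=2)
        df = res.history_frame()
        assert list(df.columns) == ["step", "epoch", "lr", "L_local",
                                    "L_global", "L_total"]
        assert len(df) == 2


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [{"batch_size": 1}, {"epochs": 0},
                                    {"base_lr": 0.0}])
    def test_invalid_train_config(self, kw):
        with pytest.raises(ValueError):
            TrainConfig(**kw)

    def test_from_config_dict(self, small_corpus):
        model = fp.FPSiamModel.from_config({
            "backbone": {"name": "convstage", "stage_channels": [8, 16, 32],
                         "stage_strides": [2, 4, 8]},
            "augment": {"crop_size": 64},
            "pyramid": {"d": 16, "n_levels": 3},
            "heads": {"proj_in": 16, "proj_hidden": 64, "proj_out": 32,
                      "pred_hidden": 16},
            "train": {"batch_size": 8, "epochs": 5},
            "loss": {"lambda_weight": 0.25},
        }, frames=small_corpus)
        assert model.lambda_weight == 0.25
        assert model.train_config.batch_size == 8
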