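"""Conditional GAN: architecture rules, augmentation, training dynamics,
inference and the cross-scanner/ensemble regimes."""

import numpy as np
import pytest

from spectac import cgan, nn
from spectac.volume import ValidationError, Volume3D


def _pairs(n, size=16, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        x = rng.random((size, size, size)).astype(np.float32)
        y = (0.2 * x + 0.05 * rng.random((size, size, size))).astype(np.float32)
        out.append((x, y))
    return out


class TestConfig:
    def test_mode_rules_fix_depth_and_skips(self):
        ind = cgan.CganConfig(mode="indirect")
        dir_ = cgan.CganConfig(mode="direct")
        assert (ind.encoder_depth, ind.use_skip) == (3, False)
        assert (dir_.encoder_depth, dir_.use_skip) == (2, True)
        assert ind.base_features == 48
        assert ind.lambda_l1 == 20.0
        assert ind.lr_init == pytest.approx(1e-3)
        assert ind.max_epochs == 400
        assert ind.dropout_rate == 0.5

    def test_overriding_skip_rule_warns(self):
        with pytest.warns(UserWarning):
            cgan.CganConfig(mode="indirect", use_skip=True)

    @pytest.mark.parametrize(
        "kwargs", [{"mode": "sideways"}, {"lambda_l1": 0.0}, {"dropout_rate": 1.0}]
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            cgan.CganConfig(**kwargs)


class TestBuildNetworks:
    def test_indirect_generator_has_no_skip_connections(self):
        gen = cgan.build_generator(cgan.CganConfig.desk("indirect"))
        desc = gen.describe()
        assert desc["skip_connections"] is False
        assert desc["encoder_depth"] == 3
        assert not any("concat" in b for b in desc["blocks"])

    def test_direct_generator_has_skips_and_depth_two(self):
        gen = cgan.build_generator(cgan.CganConfig.desk("direct"))
        desc = gen.describe()
        assert desc["skip_connections"] is True
        assert desc["encoder_depth"] == 2
        assert any("concat" in b for b in desc["blocks"])

    def test_build_is_deterministic(self):
        cfg = cgan.CganConfig.desk("indirect", seed=9)
        g1, g2 = cgan.build_generator(cfg), cgan.build_generator(cfg)
        assert g1.n_parameters() == g2.n_parameters()
        for p1, p2 in zip(g1.parameters(), g2.parameters()):
            assert np.array_equal(p1.data, p2.data)

    def test_depth_incompatible_with_matrix_rejected(self):
        gen = cgan.build_generator(cgan.CganConfig.desk("indirect"))
        with pytest.raises(ValidationError):
            gen(nn.Tensor(np.zeros((1, 1, 12, 12, 12), np.float32)))

    def test_discriminator_probability_range_and_determinism(self, rng):
        cfg = cgan.CganConfig.desk("direct", base_features=4)
        disc = cgan.build_discriminator(cfg)
        c = nn.Tensor(rng.random((2, 1, 16, 16, 16)).astype(np.float32))
        cand = nn.Tensor(rng.random((2, 1, 16, 16, 16)).astype(np.float32))
        p1 = disc(c, cand).data
        p2 = disc(c, cand).data
        assert np.all((p1 > 0) & (p1 < 1))
        assert np.array_equal(p1, p2)

    def test_discriminator_loss_gradient_nonzero(self, rng):
        disc = cgan.build_discriminator(cgan.CganConfig.desk("direct", base_features=4))
        c = nn.Tensor(rng.random((2, 1, 16, 16, 16)).astype(np.float32))
        cand = nn.Tensor(rng.random((2, 1, 16, 16, 16)).astype(np.float32))
        loss = nn.bce_with_logits(disc.logits(c, cand), 1.0)
        loss.backward()
        grads = [p.grad for p in disc.parameters() if p.grad is not None]
        assert any(np.abs(g).max() > 0 for g in grads)


class TestNormalizeUnit:
    def test_range_maps_to_unit_interval(self, rng):
        v = rng.random((8, 8, 8)) * 7 + 2
        out, rec = cgan.normalize_unit(v)
        assert out.min() == 0.0 and out.max() == pytest.approx(1.0)
        assert not rec.constant

    def test_constant_volume_flagged_and_zeroed(self):
        out, rec = cgan.normalize_unit(np.full((4, 4, 4), 3.0))
        assert not out.any()
        assert rec.constant

    def test_roundtrip(self, rng):
        v = rng.random((8, 8, 8)) * 5
        out, rec = cgan.normalize_unit(v)
        assert np.allclose(rec.invert(out), v, atol=1e-7)


class TestAugmentFlips:
    def test_ninety_pairs_become_270(self):
        assert len(cgan.augment_flips(_pairs(90, size=4))) == 270

    def test_double_flip_is_identity(self):
        (x, y), = _pairs(1, size=6)
        once = cgan.augment_flips([(x, y)])
        h_x = once[1][0]
        again = cgan.augment_flips([(h_x, once[1][1])])
        assert np.array_equal(again[1][0], x)

    def test_single_asymmetric_pair_gives_three_distinct(self):
        x = np.zeros((4, 4, 4), np.float32)
        x[0, 1, 2] = 1.0
        aug = cgan.augment_flips([(x, x.copy())])
        assert len(aug) == 3
        flat = [a[0].tobytes() for a in aug]
        assert len(set(flat)) == 3

    def test_inputs_and_targets_flip_together(self):
        x = np.zeros((4, 4, 4), np.float32)
        x[0, 0, 0] = 1.0
        aug = cgan.augment_flips([(x, x.copy())])
        for xa, ya in aug:
            assert np.array_equal(xa, ya)


class TestTraining:
    @pytest.fixture(scope="class")
    def trained(self):
        cfg = cgan.CganConfig.desk("indirect", seed=2)
        cfg.max_epochs = 200  # 2 pairs -> 1 step/epoch -> 200 steps
        cfg.early_stop_patience = 200
        return cgan.train_cgan(_pairs(2), cfg), cfg

    def test_overfit_sanity_l1_halves(self, trained):
        model, _ = trained
        h = model.step_history
        assert h.g_l1.iloc[-1] < 0.5 * h.g_l1.iloc[0]

    def test_lambda_appears_in_loss_decomposition(self, trained):
        model, cfg = trained
        h = model.step_history
        assert np.all(h.lambda_l1 == 20.0)
        recon = (h.adv_weight.to_numpy(np.float32) * h.g_adv.to_numpy(np.float32)
                 + np.float32(20.0) * h.g_l1.to_numpy(np.float32))
        assert np.allclose(h.g_total, recon, atol=2e-5)
        assert (h.adv_weight.to_numpy()[-1]) == 1.0  # warm-up has ended

    def test_history_covers_every_epoch(self, trained):
        model, cfg = trained
        assert len(model.history) <= cfg.max_epochs
        assert np.isfinite(model.history[["g_total", "g_adv", "g_l1", "d_loss"]]).all().all()

    def test_same_seed_gives_identical_training(self):
        cfg = cgan.CganConfig.desk("direct", seed=5)
        cfg.max_epochs = 5
        a = cgan.train_cgan(_pairs(2), cfg)
        b = cgan.train_cgan(_pairs(2), cfg)
        assert a.history.g_l1.iloc[-1] == pytest.approx(b.history.g_l1.iloc[-1], abs=1e-6)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            cgan.train_cgan([], cgan.CganConfig.desk("indirect"))


class TestPredict:
    @pytest.fixture(scope="class")
    def model(self):
        cfg = cgan.CganConfig.desk("indirect", seed=1)
        cfg.max_epochs = 3
        return cgan.train_cgan(_pairs(4), cfg)

    def test_output_nonnegative_and_tagged(self, model):
        nac = Volume3D(np.random.default_rng(0).random((16, 16, 16)), 0.9, "counts")
        out = cgan.predict(model, nac)
        assert out.data.min() >= 0
        assert out.unit == "cm^-1"

    def test_inference_deterministic(self, model):
        nac = Volume3D(np.random.default_rng(1).random((16, 16, 16)), 0.9, "counts")
        a = cgan.predict(model, nac)
        b = cgan.predict(model, nac)
        assert np.array_equal(a.data, b.data)

    def test_grid_mismatch_rejected(self, model):
        with pytest.raises(ValidationError):
            cgan.predict(model, Volume3D(np.zeros((8, 8, 8)), 0.9, "counts"))

    def test_checkpoint_roundtrip(self, model, tmp_path):
        model.save(tmp_path / "gen.npz")
        back = cgan.TrainedGenerator.load(tmp_path / "gen.npz")
        nac = Volume3D(np.random.default_rng(2).random((16, 16, 16)), 0.9, "counts")
        assert np.allclose(cgan.predict(back, nac).data,
                           cgan.predict(model, nac).data, atol=1e-6)


class TestRegimes:
    def test_clinical_split_sizes(self):
        ds = cgan.split_dataset("A", _pairs(130, size=4))
        assert (len(ds.train), len(ds.val), len(ds.test)) == (90, 10, 30)

    def test_ensemble_training_size_after_augmentation(self):
        merged = _pairs(90, size=4) + _pairs(90, size=4, seed=1)
        assert len(cgan.augment_flips(merged)) == 540

    def test_overlapping_split_indices_rejected(self):
        p = _pairs(4, size=4)
        with pytest.raises(ValidationError):
            cgan.ScannerDataset("A", p[:2], p[2:3], p[3:],
                                train_idx=[0, 1], val_idx=[1], test_idx=[3])

    @pytest.fixture(scope="class")
    def datasets(self):
        def mk(name, seed):
            return cgan.split_dataset(name, _pairs(6, seed=seed), sizes=(4, 1, 1))
        return {"A": mk("A", 0), "B": mk("B", 1)}

    def test_cross_scanner_swaps_models(self, datasets):
        cfg = cgan.CganConfig.desk("direct", seed=0)
        cfg.max_epochs = 1
        res = cgan.run_training_regime(datasets, "cross_scanner", cfg)
        assert res.assignment == {"A": "B", "B": "A"}
        assert set(res.models) == {"A", "B"}

    def test_ensemble_merges_and_serves_both(self, datasets):
        cfg = cgan.CganConfig.desk("direct", seed=0)
        cfg.max_epochs = 1
        res = cgan.run_training_regime(datasets, "ensemble", cfg)
        assert res.assignment == {"A": "ensemble", "B": "ensemble"}
        assert res.train_sizes["ensemble"] == 3 * 8

    def test_unknown_regime_rejected(self, datasets):
        with pytest.raises(ValidationError):
            cgan.run_training_regime(datasets, "federated", cgan.CganConfig.desk("direct"))
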