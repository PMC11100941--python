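"""Latent fitting and surface reconstruction against the overfit tiny model."""

import numpy as np
import pytest

from kneeshape.decoders import MLPConfig, make_decoder
from kneeshape.geometry import apply_transform_pair, assd
from kneeshape.nn import Tensor
from kneeshape.reconstruction import (
    FitConfig,
    decode_grid,
    fit_latent,
    mean_shape,
    reconstruct,
)

from conftest import GRID_RES, SPACING, refit_config as _fit_config


class TestFitLatent:
    def test_refit_bone_within_two_grid_spacings(self, refit):
        pair, recon, result = refit["pair"], refit["recon"], refit["result"]
        spacing_mm = SPACING / result.transform.scale
        assert recon.bone is not None and recon.cartilage is not None
        assert assd(recon.bone, pair.bone) <= 2 * spacing_mm
        assert assd(recon.cartilage, pair.cartilage) <= 2 * spacing_mm

    def test_frame_round_trip_centroid_and_scale(self, refit):
        pair, recon = refit["pair"], refit["recon"]
        c_in = pair.bone.vertices.mean(axis=0)
        c_out = recon.bone.vertices.mean(axis=0)
        r_in = np.linalg.norm(pair.bone.vertices - c_in, axis=1).mean()
        r_out = np.linalg.norm(recon.bone.vertices - c_out, axis=1).mean()
        assert np.linalg.norm(c_out - c_in) < 0.02 * r_in
        assert abs(r_out - r_in) / r_in < 0.02

    def test_early_stop_best_loss_never_increases(self, refit):
        trace = refit["result"].trace
        running_best = trace.loss.cummin()
        assert refit["result"].best_loss == pytest.approx(trace.loss.min())
        assert (running_best.diff().dropna() <= 1e-12).all()

    def test_same_seed_identical_latent(self, trained_tiny, refit):
        decoder = trained_tiny["decoder"]
        params = trained_tiny["result"].params
        result2 = fit_latent(decoder, params, refit["pair"], _fit_config(), seed=4)
        np.testing.assert_array_equal(refit["result"].latent, result2.latent)

    def test_codebook_warm_start_begins_near_converged_floor(self, trained_tiny, refit):
        decoder = trained_tiny["decoder"]
        params = trained_tiny["result"].params
        z0 = trained_tiny["result"].codebook[refit["sid"]].data
        cfg = _fit_config(epochs=60)
        warm = fit_latent(decoder, params, refit["pair"], cfg, seed=4, z_init=z0)
        cold_start = refit["result"].trace.loss.iloc[0]
        cold_floor = refit["result"].best_loss
        assert warm.trace.loss.iloc[0] < 5 * cold_floor
        assert warm.trace.loss.iloc[0] < 0.5 * cold_start

    def test_early_stop_triggers_after_patience_without_improvement(self, trained_tiny, refit):
        decoder = trained_tiny["decoder"]
        params = trained_tiny["result"].params
        z0 = trained_tiny["result"].codebook[refit["sid"]].data
        cfg = _fit_config(epochs=300)
        cfg.lr0 = 0.0  # frozen latent: the loss can never improve
        stalled = fit_latent(decoder, params, refit["pair"], cfg, seed=4, z_init=z0)
        assert len(stalled.trace) == cfg.patience + 1


class TestReconstruct:
    def test_fitted_latents_beat_mean_shape_on_every_training_shape(self, trained_tiny):
        decoder = trained_tiny["decoder"]
        result = trained_tiny["result"]
        mean_bone = mean_shape(decoder, result.params, GRID_RES)
        for sid, z in result.codebook.items():
            pair_norm = apply_transform_pair(
                trained_tiny["pairs"][sid], trained_tiny["transforms"][sid]
            )
            recon = reconstruct(decoder, result.params, z.data, None, resolution=GRID_RES)
            a_fit = assd(recon.bone, pair_norm.bone)
            a_mean = assd(mean_bone, pair_norm.bone)
            assert a_fit <= 2 * SPACING
            assert a_fit < a_mean

    def test_identity_transform_stays_normalized(self, trained_tiny):
        decoder = trained_tiny["decoder"]
        result = trained_tiny["result"]
        z = next(iter(result.codebook.values())).data
        recon = reconstruct(decoder, result.params, z, None, resolution=48)
        assert recon.frame_id == "normalized"
        assert np.abs(recon.bone.vertices).max() <= 1.0 + 1e-6

    def test_resolution_refinement_does_not_worsen_assd(self, trained_tiny):
        decoder = trained_tiny["decoder"]
        result = trained_tiny["result"]
        sid = sorted(result.codebook)[0]
        pair_norm = apply_transform_pair(
            trained_tiny["pairs"][sid], trained_tiny["transforms"][sid]
        )
        z = result.codebook[sid].data
        coarse = reconstruct(decoder, result.params, z, None, resolution=32)
        fine = reconstruct(decoder, result.params, z, None, resolution=64)
        a_coarse = assd(coarse.bone, pair_norm.bone)
        a_fine = assd(fine.bone, pair_norm.bone)
        assert a_fine <= a_coarse * 1.1

    def test_degenerate_decoder_reports_empty_surfaces(self):
        cfg = MLPConfig.tiny()
        decoder = make_decoder(cfg)
        params = decoder.init_params(np.random.default_rng(0))
        for name, t in params.items():
            t.data[...] = 0.0
            if name.endswith("head_b"):
                t.data[...] = 5.0  # tanh(5) > 0 everywhere: no zero crossing
        with pytest.warns(UserWarning):
            recon = reconstruct(decoder, params, np.zeros(cfg.latent_len), None, resolution=16)
        assert recon.bone is None and recon.cartilage is None

    def test_heldout_latents_carry_disease_signal(self, trained_tiny):
        """Latents fitted to a held-out cohort predict planted OA and
        osteophyte labels above the prevalence baseline (pooled 3-fold CV).

        Full-thickness holes are too subtle for a 10-shape model's latent
        space and are deliberately not asserted here.
        """
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import average_precision_score
        from sklearn.model_selection import StratifiedKFold

        from kneeshape.reconstruction import encode_population
        from kneeshape.synthetic import SynthConfig, generate_population

        from conftest import TRAIN_SEED

        decoder = trained_tiny["decoder"]
        result = trained_tiny["result"]
        cohort = generate_population(SynthConfig(seed=TRAIN_SEED + 10_000, population=36))
        cfg = _fit_config(epochs=80)
        cfg.n_surface_points = 1500
        cfg.patience = 30
        Z, _ = encode_population(decoder, result.params, [s.pair for s in cohort], cfg, seed=5)
        tasks = {
            "oa": np.array([s.labels.oa for s in cohort]),
            "osteophyte_severe": np.array(
                [int(max(s.labels.osteophyte_binned.values()) == 2) for s in cohort]
            ),
        }
        for name, y in tasks.items():
            probs = np.empty(len(y))
            for tr, te in StratifiedKFold(3, shuffle=True, random_state=0).split(Z, y):
                clf = LogisticRegression(max_iter=2000).fit(Z[tr], y[tr])
                probs[te] = clf.predict_proba(Z[te])[:, 1]
            auprc = average_precision_score(y, probs)
            assert auprc > y.mean() + 0.05, (name, auprc, y.mean())

    def test_decode_grid_matches_forward(self, trained_tiny):
        decoder = trained_tiny["decoder"]
        params = trained_tiny["result"].params
        z = np.zeros(decoder.cfg.latent_len, dtype=np.float32)
        grid_b, grid_c = decode_grid(decoder, params, z, 8)
        from kneeshape.geometry import grid_coordinates

        coords = grid_coordinates(8)
        sb, sc = decoder.forward(params, Tensor(z), coords)
        np.testing.assert_allclose(grid_b.values.ravel(), sb.data, atol=1e-6)
        np.testing.assert_allclose(grid_c.values.ravel(), sc.data, atol=1e-6)
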