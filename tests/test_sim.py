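"""Forward-model physics: trajectories, rendering, datasets."""

import numpy as np
import pytest
from scipy import stats

import blurmap as bm


class TestTrajectories:
    def test_zero_diffusion_stays_put(self, sim_config, rng):
        traj = bm.simulate_trajectory(0.0, sim_config, rng)
        assert len(traj) == sim_config.n_micro_steps + 1
        assert np.allclose(traj.positions, traj.positions[0])

    def test_negative_D_rejected(self, sim_config, rng):
        with pytest.raises(ValueError):
            bm.simulate_trajectory(-1.0, sim_config, rng)

    def test_fixed_micro_step_length(self, sim_config, rng):
        # sqrt(4*5*9e-6) um = 13.4164 nm per micro-step at D=5, 9 ms/1000
        traj = bm.simulate_trajectory(5.0, sim_config, rng)
        L = np.linalg.norm(np.diff(traj.positions.astype(float), axis=0), axis=1)
        assert np.allclose(L, 13.416407864998737, rtol=1e-5)

    def test_msd_law_4Dt(self, sim_config, rng):
        # end-to-end MSD over 10^4 trajectories = 4*D*exposure within 3 SE
        D = 1.0
        trajs = bm.simulate_trajectories(D, 10_000, sim_config, rng)
        disp = (trajs[:, -1] - trajs[:, 0]).astype(float) / 1e3
        sq = (disp**2).sum(axis=1)
        expected = 4.0 * D * sim_config.exposure_time
        se = sq.std(ddof=1) / np.sqrt(len(sq))
        assert abs(sq.mean() - expected) < 3.0 * se

    def test_msd_law_at_intermediate_time(self, sim_config, rng):
        # MSD(tau) = 4*D*tau also holds mid-exposure (tau = exposure/2)
        D = 2.0
        trajs = bm.simulate_trajectories(D, 10_000, sim_config, rng)
        half = sim_config.n_micro_steps // 2
        disp = (trajs[:, half] - trajs[:, 0]).astype(float) / 1e3
        sq = (disp**2).sum(axis=1)
        expected = 4.0 * D * sim_config.exposure_time / 2.0
        se = sq.std(ddof=1) / np.sqrt(len(sq))
        assert abs(sq.mean() - expected) < 3.0 * se

    def test_gaussian_scheme_same_msd(self, rng):
        cfg = bm.SimConfig(step_scheme="gaussian")
        trajs = bm.simulate_trajectories(1.0, 10_000, cfg, rng)
        disp = (trajs[:, -1] - trajs[:, 0]).astype(float) / 1e3
        sq = (disp**2).sum(axis=1)
        se = sq.std(ddof=1) / np.sqrt(len(sq))
        assert abs(sq.mean() - 0.036) < 3.0 * se

    def test_seed_determinism(self, sim_config):
        a = bm.simulate_trajectories(2.0, 5, sim_config, np.random.default_rng(3))
        b = bm.simulate_trajectories(2.0, 5, sim_config, np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestFieldTrajectories:
    def test_uniform_field_matches_fixed_D(self, sim_config):
        field = bm.DiffusivityField.uniform(2.0)
        starts = np.full((5000, 2), 5000.0)
        pos, true_D = bm.simulate_trajectories_in_field(
            field, starts, sim_config, np.random.default_rng(0))
        assert np.all(true_D == 2.0)
        disp = (pos[:, -1] - pos[:, 0]).astype(float) / 1e3
        sq = (disp**2).sum(axis=1)
        se = sq.std(ddof=1) / np.sqrt(len(sq))
        assert abs(sq.mean() - 4 * 2.0 * 0.009) < 3 * se

    def test_zero_D_inclusion_freezes(self, sim_config, rng):
        field = bm.DiffusivityField.square_inclusion(
            2.0, 0.0, center=(5000, 5000), size=2000,
            domain_bounds=(0, 0, 10_000, 10_000))
        traj = bm.simulate_trajectory_in_field(field, (5000, 5000), sim_config, rng)
        assert traj.true_D == 0.0
        assert np.allclose(traj.positions, traj.positions[0])

    def test_start_outside_domain_rejected(self, sim_config, rng):
        field = bm.DiffusivityField.uniform(1.0, (0, 0, 1000, 1000))
        with pytest.raises(ValueError):
            bm.simulate_trajectory_in_field(field, (2000, 500), sim_config, rng)

    def test_per_region_msd_in_two_level_field(self, sim_config):
        # starts placed deep inside each region (margin >> rms excursion,
        # so boundary crossings are negligible) obey that region's 4*D*t
        field = bm.DiffusivityField.square_inclusion(
            2.0, 4.0, center=(3000, 3000), size=4000,
            domain_bounds=(0, 0, 12_000, 12_000))
        rng = np.random.default_rng(11)
        centers = {4.0: (3000, 3000), 2.0: (9000, 9000)}
        for D, c in centers.items():
            starts = np.asarray(c) + rng.uniform(-500, 500, size=(5000, 2))
            pos, true_D = bm.simulate_trajectories_in_field(
                field, starts, sim_config, rng)
            assert np.all(true_D == D)
            disp = (pos[:, -1] - pos[:, 0]).astype(float) / 1e3
            sq = (disp**2).sum(axis=1)
            se = sq.std(ddof=1) / np.sqrt(len(sq))
            assert abs(sq.mean() - 4 * D * 0.009) < 3 * se


class TestRendering:
    def test_photon_conservation_static_emitter(self, sim_config, rng):
        # D=0, no background: mean total counts = rate x exposure_ms (3 SE)
        rate = 90.0
        trajs = bm.simulate_trajectories(0.0, 3000, sim_config, rng)
        imgs, _ = bm.render_images(trajs, sim_config, rate, rng,
                                   add_background=False)
        totals = imgs.sum(axis=(1, 2))
        lam = rate * sim_config.exposure_ms
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - lam) < 3 * se

    def test_static_average_is_centered_and_symmetric(self, sim_config, rng):
        # D=0 average image: brightest central pixel, centroid at the ROI
        # center, fourfold-symmetric (distributional identity with a true
        # static PSF is covered by the oracle KS test below)
        trajs = bm.simulate_trajectories(0.0, 4000, sim_config, rng)
        imgs, _ = bm.render_images(trajs, sim_config, 90.0, rng,
                                   add_background=False)
        avg = imgs.mean(axis=0)
        assert avg[3, 3] == avg.max()
        yy, xx = np.mgrid[0:7, 0:7]
        cx = (avg * xx).sum() / avg.sum()
        cy = (avg * yy).sum() / avg.sum()
        assert abs(cx - 3.0) < 0.05 and abs(cy - 3.0) < 0.05
        # mirror symmetry within Monte-Carlo noise
        assert np.allclose(avg, avg[::-1, :], rtol=0.15, atol=0.3)
        assert np.allclose(avg, avg[:, ::-1], rtol=0.15, atol=0.3)

    def test_static_matches_independent_psf_oracle(self, sim_config):
        # D=0 rendering is statistically identical to a direct static-PSF
        # sampler (KS test on per-image radial second moments, alpha=0.01)
        n = 10_000
        rng = np.random.default_rng(21)
        trajs = bm.simulate_trajectories(0.0, n, sim_config, rng)
        imgs, _ = bm.render_images(trajs, sim_config, 90.0, rng,
                                   add_background=False)

        # oracle: photons at a fixed point + Gaussian PSF, binned directly
        oracle_rng = np.random.default_rng(22)
        px, sig = sim_config.pixel_size, sim_config.psf_sigma
        counts = oracle_rng.poisson(90.0 * 9.0, size=n)
        oracle = np.zeros((n, 7, 7), dtype=np.float32)
        for i, c in enumerate(counts):
            pts = oracle_rng.normal(0.0, sig, size=(c, 2))
            cent = pts.mean(axis=0) if c else np.zeros(2)
            origin = (np.floor(cent / px) - 3) * px
            ij = np.floor((pts - origin) / px).astype(int)
            ok = (ij >= 0).all(axis=1) & (ij < 7).all(axis=1)
            np.add.at(oracle[i], (ij[ok, 1], ij[ok, 0]), 1.0)

        def second_moment(stack):
            yy, xx = np.mgrid[0:7, 0:7]
            tot = stack.sum(axis=(1, 2))
            cx = (stack * xx).sum(axis=(1, 2)) / tot
            cy = (stack * yy).sum(axis=(1, 2)) / tot
            return ((stack * ((xx - cx[:, None, None]) ** 2
                              + (yy - cy[:, None, None]) ** 2)).sum(axis=(1, 2))
                    / tot)

        p = stats.ks_2samp(second_moment(imgs), second_moment(oracle)).pvalue
        assert p > 0.01

    def test_blur_monotone_in_D(self, sim_config):
        # mean radial second moment grows monotonically over D = 0..5
        rng = np.random.default_rng(31)
        yy, xx = np.mgrid[0:7, 0:7]
        means = []
        for D in (0.0, 1.0, 2.0, 3.0, 4.0, 5.0):
            trajs = bm.simulate_trajectories(D, 1500, sim_config, rng)
            imgs, _ = bm.render_images(trajs, sim_config, 90.0, rng,
                                       add_background=False)
            tot = imgs.sum(axis=(1, 2))
            cx = (imgs * xx).sum(axis=(1, 2)) / tot
            cy = (imgs * yy).sum(axis=(1, 2)) / tot
            m2 = ((imgs * ((xx - cx[:, None, None]) ** 2
                           + (yy - cy[:, None, None]) ** 2)).sum(axis=(1, 2)) / tot)
            means.append(m2.mean())
        assert np.all(np.diff(means) > 0)

    def test_zero_photon_rate_gives_background_only(self, sim_config, rng):
        trajs = bm.simulate_trajectories(1.0, 200, sim_config, rng)
        imgs, _ = bm.render_images(trajs, sim_config, 0.0, rng)
        # counts consistent with the background model alone
        assert abs(imgs.mean() - sim_config.background_mean) < 1.0

    def test_pixels_nonnegative(self, sim_config, rng):
        trajs = bm.simulate_trajectories(3.0, 500, sim_config, rng)
        imgs, _ = bm.render_images(trajs, sim_config, 60.0, rng)
        assert imgs.min() >= 0

    def test_roi_too_small_for_psf(self):
        with pytest.raises(ValueError, match="ROI too small"):
            bm.SimConfig(roi_size=1)

    def test_expected_photon_budget_matches_experiment_range(self, sim_config):
        # 60-120 photons/ms over 9 ms -> 540-1080 expected photons,
        # inside the experimentally typical 500-1200 window
        lo, hi = sim_config.photon_rate_range
        assert (lo * sim_config.exposure_ms, hi * sim_config.exposure_ms) == (540.0, 1080.0)
        assert 500 <= lo * sim_config.exposure_ms and hi * sim_config.exposure_ms <= 1200


class TestFrameSequence:
    def test_zero_density_background_only(self, sim_config, rng):
        field = bm.DiffusivityField.uniform(3.0, (0, 0, 3200, 3200))
        seq = bm.render_frame_sequence(field, 1e-12, 5, sim_config, rng)
        assert len(seq.truth) == 0
        assert abs(seq.frames.mean() - sim_config.background_mean) < 2.0

    def test_poisson_molecule_count(self, sim_config, rng):
        # density 0.1 /um^2/frame on a 20x20 um field -> mean 40/frame
        field = bm.DiffusivityField.uniform(0.5, (0, 0, 20_000, 20_000))
        cfg = bm.SimConfig(n_micro_steps=20)  # count statistics only
        seq = bm.render_frame_sequence(field, 0.1, 150, cfg, rng)
        per_frame = seq.truth.groupby("frame").size().reindex(range(150), fill_value=0)
        se = np.sqrt(40.0 / 150)
        assert abs(per_frame.mean() - 40.0) < 3 * se

    def test_frames_are_uint16(self, sim_config, rng):
        field = bm.DiffusivityField.uniform(1.0, (0, 0, 3200, 3200))
        seq = bm.render_frame_sequence(field, 0.1, 3, sim_config, rng)
        assert seq.frames.dtype == np.uint16


class TestDatasets:
    def test_counts_and_shape(self, rng):
        cfg = bm.SimConfig(n_micro_steps=50)
        labels = bm.default_label_grid(step=1.0, hi=3.0)  # 4 labels
        ds = bm.build_training_dataset(cfg, labels, [(60, 5), (120, 15)], 5,
                                       seed=3, n_ch=8)
        assert ds.stacks.shape == (4 * 2 * 5, 8, 7, 7)
        assert np.all(np.isin(ds.labels, labels))

    def test_full_scale_arithmetic(self):
        # 121 labels x 100 stacks x 20 combos = 242,000; x1 combo = 12,100
        grid = bm.default_label_grid()
        assert len(grid) == 121
        assert grid[1] - grid[0] == pytest.approx(0.05)
        combos = bm.default_augmentation_grid()
        assert len(combos) == 20
        assert len(grid) * 100 * 1 == 12_100
        assert len(grid) * 100 * len(combos) == 242_000

    def test_dataset_bit_identical_across_runs(self):
        cfg = bm.SimConfig(n_micro_steps=50)
        kw = dict(label_grid=[1.0, 2.0], augmentation_grid=[(90.0, 10.0)],
                  stacks_per_label=4, seed=5, n_ch=6)
        a = bm.build_training_dataset(cfg, **kw)
        b = bm.build_training_dataset(cfg, **kw)
        assert np.array_equal(a.stacks, b.stacks)

    def test_hdf5_round_trip(self, tmp_path):
        cfg = bm.SimConfig(n_micro_steps=50)
        ds = bm.build_training_dataset(cfg, [0.5, 1.5], [(90.0, 10.0)], 3,
                                       seed=5, n_ch=6)
        path = tmp_path / "ds.h5"
        bm.save_dataset(ds, path)
        back = bm.load_dataset(path)
        assert np.array_equal(back.stacks, ds.stacks)
        assert np.array_equal(back.labels, ds.labels)
        assert back.config == ds.config

    def test_invalid_grids_rejected(self, rng):
        cfg = bm.SimConfig(n_micro_steps=50)
        with pytest.raises(ValueError):
            bm.build_training_dataset(cfg, [], [(90, 10)], 5, seed=0)
        with pytest.raises(ValueError):
            bm.build_training_dataset(cfg, [1.0, 7.0], [(90, 10)], 5, seed=0)
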