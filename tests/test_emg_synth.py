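"""Generator tests: montage geometry, lead-field structure, planted
tuning and noise calibration are all recoverable from the output."""

import numpy as np
import pytest

from synergyemg import emg_synth as es
from synergyemg.synergy_analysis import cosine_tune, direction_means


class TestMontage:
    def test_default_montage_has_96_channels_with_hand_ground(self):
        m = es.build_montage()
        assert m.n_channels == 96
        assert 0 <= m.ground_index < m.n_channels
        pos = np.column_stack([m.axial_mm, m.circ_deg])
        assert len(np.unique(pos, axis=0)) == m.n_channels

    def test_axial_ring_spacing_is_constant(self):
        m = es.build_montage()
        ax = np.unique(m.axial_mm[m.grid_mask()])
        assert np.allclose(np.diff(np.sort(ax)), 20.0)

    def test_rejects_non_positive_counts(self):
        with pytest.raises(ValueError):
            es.build_montage(n_rings=0, per_ring=8)
        with pytest.raises(ValueError):
            es.build_montage(n_rings=12, per_ring=-1)

    def test_single_channel_montage_rejected_downstream(self):
        m = es.build_montage(n_rings=1, per_ring=1, n_channels=1)
        assert m.n_channels == 1
        from synergyemg.preprocess import select_ground_reference
        with pytest.raises(ValueError):
            select_ground_reference(np.zeros((1, 100)))


class TestLeadfield:
    def test_superficial_column_peaks_under_the_source(self):
        m = es.build_montage()
        src = es.SourceSpec("superficial", float(m.axial_mm[10]),
                            float(m.circ_deg[10]), 0.0, 0.5, 0.3, 0.0)
        A = es.make_leadfield(m, [src])
        assert np.argmax(A[:, 0]) == 10

    def test_entries_normalized_to_unit_maximum(self):
        m = es.build_montage()
        A = es.make_leadfield(m, es.default_sources())
        assert A.min() >= 0
        assert np.allclose(A.max(axis=0), 1.0)

    def test_deep_source_spreads_more_over_the_ring_than_superficial(self):
        m = es.build_montage()
        sup = es.SourceSpec("superficial", 100.0, 45.0, 0.0, 0.5, 0.3, 0.0)
        deep = es.SourceSpec("deep", 100.0, 45.0, 15.0, 0.5, 0.3, 0.0)
        A = es.make_leadfield(m, [sup, deep])
        ring = m.grid_mask() & (m.axial_mm == 100.0)
        assert ring.sum() >= 4
        cov = [A[ring, k].std() / A[ring, k].mean() for k in (0, 1)]
        assert cov[1] < cov[0]

    def test_empty_source_list_rejected(self):
        with pytest.raises(ValueError):
            es.make_leadfield(es.build_montage(), [])


class TestSourceSpec:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            es.SourceSpec("deep", 0, 0, 0.0, 0.5, 0.3, 0.0)  # depth 0
        with pytest.raises(ValueError):
            es.SourceSpec("noise", 0, 0, 10.0, 0.5, 0.3, 0.0)  # tuned noise
        with pytest.raises(ValueError):
            es.SourceSpec("superficial", 0, 0, 0.0, 0.5, -0.1, 0.0)


class TestSimulateTrial:
    @pytest.fixture(scope="class")
    def setup(self):
        m = es.build_montage()
        sources = es.default_sources()
        A = es.make_leadfield(m, sources)
        cfg = es.SimConfig.reduced(seed=2)
        return m, sources, A, cfg

    def test_fixed_seed_reproduces_arrays(self, setup):
        m, sources, A, cfg = setup
        out1 = es.simulate_trial(45.0, 0.0, sources, A, cfg,
                                 rng=np.random.default_rng(9), montage=m)
        out2 = es.simulate_trial(45.0, 0.0, sources, A, cfg,
                                 rng=np.random.default_rng(9), montage=m)
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])

    def test_unknown_direction_rejected(self, setup):
        m, sources, A, cfg = setup
        with pytest.raises(ValueError):
            es.simulate_trial(30.0, 0.0, sources, A, cfg, montage=m)

    def test_source_amplitude_maximal_at_preferred_direction(self, setup):
        m, sources, A, cfg = setup
        cfg = es.SimConfig.reduced(seed=2, snr_db=None,
                                   baseline_snr_db=None)
        src = sources[0]  # superficial, PD 0, intrinsic
        means = []
        for ang in es.DIRECTION_ANGLES_DEG:
            rng = np.random.default_rng(3)
            _, _, sigs, _ = es.simulate_trial(
                float(ang), 0.0, sources, A, cfg, rng=rng, montage=m,
                return_truth=True)
            means.append(np.abs(sigs[0]).mean())
        assert np.argmax(means) == list(es.DIRECTION_ANGLES_DEG).index(
            src.pd_deg)

    def test_rectified_amplitude_follows_cosine_tuning(self, setup):
        """Noise off: per-direction mean rectified source amplitude is
        proportional to a0 + W cos(theta - PD) within 2 %."""
        m, sources, A, _ = setup
        cfg = es.SimConfig.reduced(seed=2, snr_db=None,
                                   baseline_snr_db=None)
        src = sources[1]
        rng = np.random.default_rng(12)
        meas = []
        for ang in es.DIRECTION_ANGLES_DEG:
            vals = [np.abs(es.simulate_trial(
                float(ang), 0.0, sources, A, cfg, rng=rng, montage=m,
                return_truth=True)[2][1]).mean() for _ in range(4)]
            meas.append(np.mean(vals))
        meas = np.asarray(meas)
        expected = src.a0 + src.w * np.cos(
            np.deg2rad(es.DIRECTION_ANGLES_DEG - src.pd_deg))
        ratio = (meas / meas.mean()) / (expected / expected.mean())
        assert np.all(np.abs(ratio - 1) < 0.02)


class TestSimulateDataset:
    def test_trial_count_and_balanced_design(self, small_dataset):
        ds = small_dataset
        assert ds.n_trials == 8 * 2 * 3
        cells = {}
        for d, p in zip(ds.direction, ds.posture):
            cells[(int(d), float(p))] = cells.get((int(d), float(p)), 0) + 1
        assert len(cells) == 16
        assert set(cells.values()) == {3}

    def test_seed_determinism_byte_identical(self):
        cfg = es.SimConfig.reduced(n_reps=1, seed=21)
        a = es.simulate_dataset(cfg)
        b = es.simulate_dataset(cfg)
        assert a.emg.tobytes() == b.emg.tobytes()
        assert a.cursor.tobytes() == b.cursor.tobytes()
        assert np.array_equal(a.direction, b.direction)

    def test_snr_calibration_within_half_db(self, small_dataset):
        ds = small_dataset
        clean_cfg = es.SimConfig.reduced(n_reps=3, seed=11, snr_db=None,
                                         baseline_snr_db=None)
        clean = es.simulate_dataset(clean_cfg)
        noise = ds.emg.astype(float) - clean.emg.astype(float)
        snr = 10 * np.log10(np.mean(clean.emg.astype(float) ** 2)
                            / np.mean(noise**2))
        # white + baseline noise powers add (both calibrated to the
        # clean mixed-signal power)
        expected = -10 * np.log10(
            10 ** (-ds.config.snr_db / 10)
            + 10 ** (-ds.config.baseline_snr_db / 10))
        assert abs(snr - expected) < 0.5

    def test_leadfield_recoverable_from_noise_free_trial(self):
        """With noise off the recording is exactly A @ sources, so least
        squares on the true source signals returns the lead field."""
        m = es.build_montage()
        sources = es.default_sources()
        A = es.make_leadfield(m, sources)
        cfg = es.SimConfig.reduced(seed=6, snr_db=None,
                                   baseline_snr_db=None)
        emg, _, sigs, _ = es.simulate_trial(
            90.0, 0.0, sources, A, cfg, rng=np.random.default_rng(8),
            montage=m, return_truth=True)
        coef, *_ = np.linalg.lstsq(sigs.T, emg.T, rcond=None)
        assert np.allclose(coef.T, A, atol=1e-8)

    def test_planted_tuning_recovered_from_true_envelopes(
            self, noiseless_dataset):
        """Closed loop: cosine tuning on the true source envelopes gives
        back the planted PD within 1 degree and modulation ratio within
        2 %."""
        ds = noiseless_dataset
        fs = ds.fs_emg
        n_tr = int(round(ds.config.trial_duration_s * fs))
        elbow0 = ds.posture == 0
        for k, src in enumerate(ds.sources):
            if src.kind == "noise":
                continue
            amps = []
            for t0 in ds.trial_start_s[elbow0]:
                s0 = int(round(t0 * fs))
                amps.append(ds.envelopes[k, s0:s0 + n_tr].mean())
            m = direction_means(np.asarray(amps), ds.direction[elbow0])
            fit = cosine_tune(m, normalize=None)
            err = (fit.pd_deg - src.pd_deg + 180) % 360 - 180
            assert abs(err) < 1.0
            assert abs((fit.w / fit.a0) / (src.w / src.a0) - 1) < 0.02
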