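"""Normal-equation assembly, Wiener-Hopf solve, prediction and subtraction."""

import numpy as np
import pytest

from artifact.signals import (
    MICROAMP,
    MICROVOLT,
    AlignmentError,
    FilterBank,
    InsufficientDataError,
    MultichannelSignal,
    UnitsError,
)
from artifact.wiener import (
    RankDeficiencyError,
    WienerConfig,
    build_normal_equations,
    clean,
    fit_and_clean,
    predict_artifacts,
    solve_wiener,
    template_baseline,
)

FS = 12000.0


def lagged_design(x: np.ndarray, L: int, lag0: int) -> np.ndarray:
    """Independent brute-force oracle: explicit K x NL lagged design matrix."""
    K, N = x.shape
    Z = np.zeros((K, N * L))
    for k in range(K):
        for n in range(N):
            for i in range(L):
                j = k - (i - lag0)
                if 0 <= j < K:
                    Z[k, n * L + i] = x[j, n]
    return Z


def pulse_inputs(rng, K=64, N=2):
    x = np.zeros((K, N))
    for n in range(N):
        idx = rng.choice(K, size=6, replace=False)
        x[idx, n] = rng.standard_normal(6)
    return x


class TestBuildNormalEquations:
    @pytest.mark.parametrize("lag0", [0, 2])
    def test_matches_design_matrix_oracle(self, rng, lag0):
        K, N, M, L = 64, 2, 2, 3
        x = pulse_inputs(rng, K, N)
        y = rng.standard_normal((K, M))
        cfg = WienerConfig(L=L, lag0=lag0)
        corr = build_normal_equations(
            MultichannelSignal(x, fs=FS), MultichannelSignal(y, fs=FS), cfg
        )
        Z = lagged_design(x, L, lag0)
        ref_cxx = Z.T @ Z / K
        ref_ryx = Z.T @ y / K
        np.testing.assert_allclose(corr.cxx, ref_cxx, rtol=1e-12, atol=1e-12 * np.abs(ref_cxx).max())
        np.testing.assert_allclose(corr.ryx, ref_ryx, rtol=1e-12, atol=1e-12 * np.abs(ref_ryx).max())

    def test_white_noise_near_identity(self, rng):
        x = rng.standard_normal((200000, 1))
        X = MultichannelSignal(x, fs=FS)
        cfg = WienerConfig(L=4)
        corr = build_normal_equations(X, X, cfg)
        diag = np.diag(corr.cxx)
        off = corr.cxx - np.diag(diag)
        assert np.allclose(diag, 1.0, atol=0.02)
        assert np.abs(off).max() < 0.02

    def test_identity_coupling_ryx_equals_first_cxx_column(self, rng):
        x = rng.standard_normal((500, 1))
        X = MultichannelSignal(x, fs=FS)
        cfg = WienerConfig(L=6)
        corr = build_normal_equations(X, X, cfg)
        np.testing.assert_allclose(
            corr.ryx[:, 0], corr.cxx[:, 0], rtol=1e-12, atol=1e-14
        )

    def test_alignment_and_length_errors(self, rng):
        X = MultichannelSignal(rng.standard_normal((100, 1)), fs=FS)
        cfg = WienerConfig(L=8)
        with pytest.raises(AlignmentError):
            build_normal_equations(
                X, MultichannelSignal(rng.standard_normal((99, 1)), fs=FS), cfg
            )
        with pytest.raises(AlignmentError):
            build_normal_equations(
                X, MultichannelSignal(rng.standard_normal((100, 1)), fs=FS / 2), cfg
            )
        short = MultichannelSignal(rng.standard_normal((5, 1)), fs=FS)
        with pytest.raises(InsufficientDataError):
            build_normal_equations(short, short, cfg)

    def test_crossed_units_refused(self, rng):
        a = rng.standard_normal((100, 1))
        stim = MultichannelSignal(a, fs=FS, units=MICROAMP)
        rec = MultichannelSignal(a, fs=FS, units=MICROVOLT)
        cfg = WienerConfig(L=4)
        with pytest.raises(UnitsError):
            build_normal_equations(rec, stim, cfg)  # swapped slots


class TestSolveWiener:
    def test_scaled_delay_recovery(self, rng):
        K = 20000
        x = rng.standard_normal(K)
        y = 2.5 * np.concatenate([np.zeros(3), x[:-3]])
        cfg = WienerConfig(L=8)
        corr = build_normal_equations(
            MultichannelSignal(x, fs=FS), MultichannelSignal(y, fs=FS), cfg
        )
        H = solve_wiener(corr, cfg)
        taps = H.taps[0, 0]
        assert taps[3] == pytest.approx(2.5, rel=1e-6)
        assert np.abs(np.delete(taps, 3)).max() < 1e-6 * 2.5

    def test_noise_free_identifiability(self, rng):
        h_true = FilterBank(rng.standard_normal((2, 1, 8)), lag0=0, fs=FS)
        X = MultichannelSignal(rng.standard_normal((8000, 2)), fs=FS)
        Y = predict_artifacts(X, h_true)
        cfg = WienerConfig(L=12)
        H = solve_wiener(build_normal_equations(X, Y, cfg), cfg)
        err = H.taps[:, :, :8] - h_true.taps
        rel_rms = np.sqrt((err**2).mean()) / np.sqrt((h_true.taps**2).mean())
        assert rel_rms < 1e-8
        assert np.abs(H.taps[:, :, 8:]).max() < 1e-8

    def test_per_output_equals_joint_solve(self, rng):
        X = MultichannelSignal(rng.standard_normal((3000, 2)), fs=FS)
        Y = MultichannelSignal(rng.standard_normal((3000, 3)), fs=FS)
        cfg = WienerConfig(L=5)
        corr = build_normal_equations(X, Y, cfg)
        joint = solve_wiener(corr, cfg)
        scale = np.abs(joint.taps).max()
        for m in range(3):
            corr_m = build_normal_equations(
                X, MultichannelSignal(Y.samples[:, m], fs=FS), cfg
            )
            single = solve_wiener(corr_m, cfg)
            assert np.abs(single.taps[:, 0] - joint.taps[:, m]).max() < 1e-12 * scale

    def test_estimation_linear_in_y(self, rng):
        X = MultichannelSignal(rng.standard_normal((2000, 1)), fs=FS)
        y1 = rng.standard_normal((2000, 1))
        y2 = rng.standard_normal((2000, 1))
        a, b = 1.7, -0.4
        cfg = WienerConfig(L=6)

        def solve_for(y):
            return solve_wiener(
                build_normal_equations(X, MultichannelSignal(y, fs=FS), cfg), cfg
            ).taps

        combo = solve_for(a * y1 + b * y2)
        ref = a * solve_for(y1) + b * solve_for(y2)
        np.testing.assert_allclose(combo, ref, rtol=1e-10, atol=1e-10 * np.abs(ref).max())

    def test_orthogonality_of_residuals(self, rng):
        # the MMSE residual must be uncorrelated with every lagged regressor
        K, N, L = 5000, 2, 6
        x = rng.standard_normal((K, N))
        y = rng.standard_normal((K, 1))
        X = MultichannelSignal(x, fs=FS)
        Y = MultichannelSignal(y, fs=FS)
        cfg = WienerConfig(L=L, ridge=0.0)
        corr = build_normal_equations(X, Y, cfg)
        H = solve_wiener(corr, cfg)
        resid = y - predict_artifacts(X, H).samples
        Z = lagged_design(x, L, cfg.lag0)
        num = Z.T @ resid[:, 0]
        denom = np.linalg.norm(Z, axis=0) * np.linalg.norm(resid)
        assert np.abs(num / denom).max() < 1e-8

    def test_ridge_continuity(self, rng):
        X = MultichannelSignal(rng.standard_normal((4000, 1)), fs=FS)
        Y = MultichannelSignal(rng.standard_normal((4000, 1)), fs=FS)
        base = WienerConfig(L=6, ridge=0.0)
        corr = build_normal_equations(X, Y, base)
        h0 = solve_wiener(corr, base).taps
        h_eps = solve_wiener(corr, WienerConfig(L=6, ridge=1e-12)).taps
        np.testing.assert_allclose(h_eps, h0, rtol=1e-6, atol=1e-9 * np.abs(h0).max())

    def test_rank_deficiency_names_channels(self, rng):
        x = rng.standard_normal((1000, 1))
        X = MultichannelSignal(np.hstack([x, x]), fs=FS)  # duplicated input
        Y = MultichannelSignal(rng.standard_normal((1000, 1)), fs=FS)
        cfg = WienerConfig(L=4, fallback=False)
        corr = build_normal_equations(X, Y, cfg)
        with pytest.raises(RankDeficiencyError, match=r"channels"):
            solve_wiener(corr, cfg)
        # with fallback enabled the solve must go through (with a warning)
        cfg_fb = WienerConfig(L=4, fallback=True)
        with pytest.warns(RuntimeWarning):
            H = solve_wiener(corr, cfg_fb)
        assert np.all(np.isfinite(H.taps))


class TestPredictAndClean:
    def test_zero_input_zero_prediction(self):
        H = FilterBank(np.ones((1, 1, 4)), fs=FS)
        X = MultichannelSignal(np.zeros((50, 1)), fs=FS)
        assert not np.any(predict_artifacts(X, H).samples)

    @pytest.mark.parametrize("lag0", [0, 2])
    def test_impulse_reads_out_kernel(self, rng, lag0):
        h = rng.standard_normal((1, 1, 5))
        H = FilterBank(h, lag0=lag0, fs=FS)
        x = np.zeros((40, 1))
        k0 = 17
        x[k0] = 1.0
        y = predict_artifacts(MultichannelSignal(x, fs=FS), H).samples[:, 0]
        expect = np.zeros(40)
        expect[k0 - lag0:k0 - lag0 + 5] = h[0, 0]
        np.testing.assert_allclose(y, expect, atol=1e-14)

    def test_superposition(self, rng):
        H = FilterBank(rng.standard_normal((2, 2, 6)), lag0=1, fs=FS)
        Xa = MultichannelSignal(rng.standard_normal((300, 2)), fs=FS)
        Xb = MultichannelSignal(rng.standard_normal((300, 2)), fs=FS)
        lhs = predict_artifacts(Xa.with_samples(Xa.samples + Xb.samples), H).samples
        rhs = predict_artifacts(Xa, H).samples + predict_artifacts(Xb, H).samples
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-12 * np.abs(rhs).max())

    def test_channel_count_mismatch(self, rng):
        H = FilterBank(np.ones((2, 1, 3)), fs=FS)
        X = MultichannelSignal(rng.standard_normal((10, 1)), fs=FS)
        with pytest.raises(ValueError):
            predict_artifacts(X, H)

    def test_clean_identities_and_known_decomposition(self, rng):
        artifact = rng.standard_normal((100, 1))
        spikes = rng.standard_normal((100, 1))
        Y = MultichannelSignal(artifact + spikes, fs=FS)
        Yhat = MultichannelSignal(artifact, fs=FS)
        np.testing.assert_array_equal(clean(Y, Y).samples, 0.0)
        np.testing.assert_array_equal(
            clean(Y, Y.with_samples(np.zeros((100, 1)))).samples, Y.samples
        )
        np.testing.assert_allclose(clean(Y, Yhat).samples, spikes, atol=1e-15)


class TestFitAndClean:
    def test_all_train_noise_free(self, rng, siso_coupling):
        X = MultichannelSignal(rng.standard_normal((6000, 1)), fs=FS, units=MICROAMP)
        Y = predict_artifacts(X, siso_coupling)
        fit = fit_and_clean(X, Y, WienerConfig(L=40), split="none")
        assert fit.test_segments == [] and not fit.cross_validated
        res_power = np.mean(fit.cleaned.samples**2)
        assert res_power < 1e-16 * np.mean(Y.samples**2)

    def test_even_odd_split_arr_within_3db(self, rng, siso_coupling):
        from artifact.bench import oracle_arr_band_db
        from artifact.stimgen import rqp_sequence
        from artifact.bench import simulate_recording

        stim = rqp_sequence(n_channels=1, n_active=1, interval=0.01,
                            duration=20.0, dynamic=False, fs=FS, seed=3)
        ds = simulate_recording(stim, siso_coupling, neural=None,
                                noise_sigma_uv=1.0, n_trials=1, seed=4)
        trial_len = int(2.0 * FS)
        fit = fit_and_clean(stim.signal, ds.composite[0], WienerConfig(L=40),
                            split="even-odd", trial_len=trial_len)
        assert fit.cross_validated

        def seg_arr(segs):
            vals = []
            for a, b in segs:
                art = ds.artifact.segment(a, b)
                pred = fit.predicted.segment(a, b)
                resid = art.with_samples(art.samples - pred.samples)
                vals.append(oracle_arr_band_db(art, resid, (300.0, 6000.0)))
            return np.mean(vals)

        assert abs(seg_arr(fit.train_segments) - seg_arr(fit.test_segments)) < 3.0

    def test_subthreshold_fit_generalizes_to_high_amplitude(self, rng, siso_coupling):
        # train on a few low-amplitude pulses only; clean strong test pulses
        from artifact.spectral import WelchConfig, welch_psd

        K = int(8.0 * FS)
        x = np.zeros((K, 1))
        pulse_idx = np.arange(0, K - 200, int(0.2 * FS))
        amps = np.where(np.arange(pulse_idx.size) < 10, 1.0, 50.0)  # first 10 weak
        x[pulse_idx, 0] = amps
        x[pulse_idx + 1, 0] = -amps
        X = MultichannelSignal(x, fs=FS, units=MICROAMP)
        art = predict_artifacts(X, siso_coupling)
        noise = 0.01 * rng.standard_normal((K, 1))
        Y = art.with_samples(art.samples + noise)
        train_end = int(pulse_idx[10])  # only the weak pulses
        fit = fit_and_clean(X, Y, WienerConfig(L=40), split=([(0, train_end)], [(train_end, K)]))
        test = slice(train_end, K)
        resid_art = art.samples[test] - fit.predicted.samples[test]
        cfg = WelchConfig()
        p_before = welch_psd(art.segment(train_end, K), cfg)
        p_after = welch_psd(
            art.segment(train_end, K).with_samples(resid_art), cfg
        )
        for lo, hi in [(300, 1000), (1000, 3000), (3000, 6000)]:
            sel = (p_before.freqs >= lo) & (p_before.freqs <= hi)
            assert p_after.values[sel].sum() < p_before.values[sel].sum()

    def test_empty_train_partition(self, rng):
        X = MultichannelSignal(rng.standard_normal((100, 1)), fs=FS)
        with pytest.raises(ValueError):
            fit_and_clean(X, X, WienerConfig(L=4), split=([], [(0, 100)]))


class TestTemplateBaseline:
    def test_identical_trials_cancel(self, rng):
        base = MultichannelSignal(rng.standard_normal((100, 1)), fs=FS)
        trials = [base, base.with_samples(base.samples.copy())]
        tmpl = template_baseline(trials, holdout_index=0)
        np.testing.assert_array_equal(trials[0].samples - tmpl.samples, 0.0)

    def test_residual_variance_oracles(self, rng):
        K, T, sigma = 200000, 5, 1.0
        artifact = rng.standard_normal(K)
        trials = [
            MultichannelSignal(artifact + sigma * rng.standard_normal(K), fs=FS)
            for _ in range(T)
        ]
        single = template_baseline(trials, holdout_index=0, mode="single", template_index=1)
        var_single = np.var(trials[0].samples - single.samples)
        assert var_single == pytest.approx(2 * sigma**2, rel=0.05)
        mean_t = template_baseline(trials, holdout_index=0, mode="mean")
        var_mean = np.var(trials[0].samples - mean_t.samples)
        assert var_mean == pytest.approx(sigma**2 * (1 + 1 / (T - 1)), rel=0.05)

    def test_needs_two_trials(self, rng):
        only = [MultichannelSignal(rng.standard_normal((10, 1)), fs=FS)]
        with pytest.raises(ValueError):
            template_baseline(only, holdout_index=0)
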