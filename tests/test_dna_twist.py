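import numpy as np
import pytest

from aotsim.constants import KBT_ROOM_PNNM
from aotsim.dna_twist import (TwistConfig, TwistTrace, analyze_twist_trace,
                              generate_twist_trace, torque_snr)

from _oracles import ou_boxcar_variance


class TestTorqueSnr:
    def test_drag_reduction_gives_1p7_fold_noise_reduction(self):
        ratio = torque_snr(10.0, 3.2, 1.0) / torque_snr(10.0, 9.4, 1.0)
        assert ratio == pytest.approx(np.sqrt(9.4 / 3.2), rel=1e-12)
        assert ratio == pytest.approx(1.7, abs=0.05)

    def test_quadrupling_bandwidth_halves_snr(self):
        assert torque_snr(10.0, 3.2, 4.0) == pytest.approx(
            0.5 * torque_snr(10.0, 3.2, 1.0), rel=1e-12)

    def test_quartz_snr_near_two_at_stall_torque(self):
        # 10 pN·nm DNA torque, quartz drag, 1 Hz bandwidth
        assert torque_snr(10.0, 9.4, 1.0) == pytest.approx(2.0, abs=0.1)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            torque_snr(-1.0, 3.2, 1.0)


class TestGenerator:
    def test_noiseless_trace_is_exact_backbone(self):
        cfg = TwistConfig(turns_end=25.0)
        tr = generate_twist_trace(cfg, noise=False)
        tq, ext = cfg.backbone(tr.turns)
        np.testing.assert_array_equal(tr.torque, tq)
        np.testing.assert_array_equal(tr.extension, ext)
        # linear then clamped at the buckling plateau
        assert tq.max() == cfg.buckling_plateau
        assert np.all(np.diff(tr.turns) > 0)

    def test_same_seed_bitwise_identical(self):
        cfg = TwistConfig(turns_end=20.0, seed=9)
        a, b = generate_twist_trace(cfg), generate_twist_trace(cfg)
        np.testing.assert_array_equal(a.torque, b.torque)
        np.testing.assert_array_equal(a.extension, b.extension)

    def test_different_seed_same_backbone(self):
        a = generate_twist_trace(TwistConfig(turns_end=20.0, seed=1))
        b = generate_twist_trace(TwistConfig(turns_end=20.0, seed=2))
        assert not np.array_equal(a.torque, b.torque)
        np.testing.assert_array_equal(a.turns, b.turns)

    def test_trace_length_matches_protocol(self):
        cfg = TwistConfig(turns_end=10.0)
        tr = generate_twist_trace(cfg)
        assert tr.t.size == int(10.0 / 2.0 * 400.0) + 1

    def test_invalid_regimes_rejected(self):
        with pytest.raises(ValueError):
            TwistConfig(buckling_plateau=-5.0)
        with pytest.raises(ValueError):
            TwistConfig(melting_turn=3.0)
        with pytest.raises(ValueError):
            TwistConfig(sampling_rate=4.0)

    @pytest.mark.parametrize("gamma,window", [(1.6, 0.5), (1.6, 1.0),
                                              (1.6, 2.0), (3.2, 0.5),
                                              (3.2, 1.0), (3.2, 2.0),
                                              (9.4, 0.5), (9.4, 1.0),
                                              (9.4, 2.0)])
    def test_window_averaged_noise_follows_ou_boxcar_law(self, gamma, window):
        """Empirical SD of window-averaged plateau torque matches the analytic
        OU + boxcar prediction (and hence the SNR formula's bandwidth scaling)
        across a (drag, window) grid."""
        cfg = TwistConfig(turns_end=140.0, gamma_theta=gamma,
                          extension_noise_nm=0.0, seed=int(10 * gamma + window))
        tr = generate_twist_trace(cfg)
        plat = tr.turns > cfg.buckling_turn + 2
        raw = tr.torque[plat] - cfg.buckling_plateau
        w = int(round(window * tr.samples_per_turn))
        means = raw[: raw.size // w * w].reshape(-1, w).mean(axis=1)
        tau_c = cfg.gamma_theta_per_rad / cfg.kappa_theta
        var = ou_boxcar_variance(KBT_ROOM_PNNM / cfg.kappa_theta, tau_c,
                                 window / cfg.twist_rate) * cfg.kappa_theta**2
        assert means.std(ddof=1) == pytest.approx(np.sqrt(var), rel=0.20)


class TestAnalysis:
    def test_noiseless_recovery_is_exact(self):
        cfg = TwistConfig(turns_end=30.0)
        ana = analyze_twist_trace(generate_twist_trace(cfg, noise=False))
        assert ana.buckling_turn_hat == pytest.approx(cfg.buckling_turn,
                                                      abs=1.0)
        assert ana.plateau_pos.mean == pytest.approx(cfg.buckling_plateau,
                                                     abs=1e-6)
        assert ana.pre_buckling_slope_hat == pytest.approx(0.85, abs=0.02)
        assert ana.extension_slope_hat == pytest.approx(-45.0, abs=0.5)

    def test_plateau_recovery_at_default_noise(self):
        """1-pN plateaus recovered within 0.5 pN·nm from long synthetic
        traces of both winding directions."""
        pos_cfg = TwistConfig(turns_end=260.0, seed=42)
        neg_cfg = TwistConfig(turns_end=-255.0, seed=43)
        ap = analyze_twist_trace(generate_twist_trace(pos_cfg))
        an = analyze_twist_trace(generate_twist_trace(neg_cfg))
        assert ap.plateau_pos.mean == pytest.approx(12.8, abs=0.5)
        assert an.plateau_neg.mean == pytest.approx(-10.5, abs=0.5)
        assert ap.plateau_pos.sd > 0 and an.plateau_neg.sd > 0

    def test_sd_ratio_tracks_drag_ratio(self):
        """Paired traces with gamma_theta 3.2 vs 9.4 (corner frequency held)
        show the ~1.7-fold torque-noise ratio."""
        sds = {}
        for g in (3.2, 9.4):
            cfg = TwistConfig(turns_end=260.0, gamma_theta=g,
                              kappa_theta=3000.0 * g / 3.2, seed=11)
            sds[g] = analyze_twist_trace(
                generate_twist_trace(cfg)).plateau_pos.sd
        assert sds[9.4] / sds[3.2] == pytest.approx(1.7, abs=0.2)

    def test_recovery_bias_small_across_seeds(self):
        """Across 50 seeds at default noise the buckling-turn bias stays
        below 0.2 turn and the plateau-mean bias below 0.1 pN·nm."""
        b_err, p_err = [], []
        for seed in range(50):
            cfg = TwistConfig(turns_end=40.0, seed=seed)
            ana = analyze_twist_trace(generate_twist_trace(cfg))
            b_err.append(ana.buckling_turn_hat - cfg.buckling_turn)
            p_err.append(ana.plateau_pos.mean - cfg.buckling_plateau)
        assert abs(np.mean(b_err)) < 0.2
        assert abs(np.mean(p_err)) < 0.1

    def test_invariance_to_time_offset_and_reversal(self):
        cfg = TwistConfig(turns_end=-40.0, seed=21)
        tr = generate_twist_trace(cfg)
        base = analyze_twist_trace(tr)
        shifted = TwistTrace(t=tr.t + 137.0, turns=tr.turns,
                             extension=tr.extension, torque=tr.torque)
        reversed_ = TwistTrace(t=tr.t, turns=tr.turns[::-1],
                               extension=tr.extension[::-1],
                               torque=tr.torque[::-1])
        for other in (analyze_twist_trace(shifted),
                      analyze_twist_trace(reversed_)):
            assert other.plateau_neg.mean == pytest.approx(
                base.plateau_neg.mean, abs=1e-9)
            assert other.melting_turn_hat == pytest.approx(
                base.melting_turn_hat, abs=1e-6)

    def test_compacted_tether_still_yields_plateau(self):
        """Very long winding drives the backbone extension to the floor; the
        breakpoint fit restricts itself to the usable region."""
        cfg = TwistConfig(turns_end=260.0, seed=4)
        ana = analyze_twist_trace(generate_twist_trace(cfg))
        assert ana.buckling_turn_hat == pytest.approx(cfg.buckling_turn,
                                                      abs=1.0)

    def test_short_positive_trace_flags_missing_plateau(self):
        cfg = TwistConfig(turns_end=18.0, seed=5)   # barely past buckling
        ana = analyze_twist_trace(generate_twist_trace(cfg))
        assert ana.plateau_pos is None
        assert any("plateau" in f for f in ana.flags)

    def test_summary_formats(self):
        ana = analyze_twist_trace(
            generate_twist_trace(TwistConfig(turns_end=40.0, seed=1)))
        s = ana.summary()
        assert "buckling turn" in s and "plateau" in s
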