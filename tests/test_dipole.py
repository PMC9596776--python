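"""Dipole model: regressor, least-squares fit, prediction, interface phase."""

import numpy as np
import pytest

from stimartifact import SimConfig, simulate_session, standard_grid
from stimartifact.core import (ArtifactAmplitudeMap, DipoleChannel,
                               ElectrodeSet, PipelineError)
from stimartifact.dipole import (dipole_regressor, electrode_area_cm2,
                                 fit_dipole, interface_phase_shift,
                                 predict_map)
from stimartifact.spatial import epoch_artifact_map
from stimartifact.timedomain import (detect_pulse_responses, exclude_saturated,
                                     segment_epochs)


def _maps_from_session(cfg, grid, use_filter=False):
    from stimartifact.timedomain import highpass
    rec, gt = simulate_session(cfg, grid)
    src = highpass(rec) if use_filter else rec
    maps = []
    for stim, _ in segment_epochs(src, gt.epochs):
        ann = stim.annotation
        excl = exclude_saturated(stim, ann.stim_pair)
        resp = detect_pulse_responses(stim, ann.pulse_freq, excluded=excl)
        maps.append(epoch_artifact_map(resp, ann))
    return maps, gt


class TestRegressor:
    CHAN = DipoleChannel([0.0, 0, 0], [30.0, 0, 0], ("a", "b"))

    def test_arithmetic(self):
        x = dipole_regressor([10.0, 0, 0], self.CHAN, current=5.0)
        assert x == pytest.approx(0.25)  # mA/mm
        assert 1000.0 * 3.3 * x == pytest.approx(825.0)  # uV with k=3.3

    def test_equidistant_is_zero(self):
        x = dipole_regressor([15.0, 40.0, 0], self.CHAN, current=5.0)
        assert x == pytest.approx(0.0)

    def test_pole_swap_antisymmetry(self):
        x1 = dipole_regressor([10.0, 0, 0], self.CHAN, 5.0)
        x2 = dipole_regressor([10.0, 0, 0], self.CHAN.swapped(), 5.0)
        assert x2 == pytest.approx(-x1)

    def test_electrode_at_pole_rejected(self):
        with pytest.raises(ValueError, match="pole"):
            dipole_regressor([0.0, 0, 0], self.CHAN, 5.0)


class TestFit:
    def test_noiseless_recovery_exact(self, grid):
        # n_true kept below half the weakest dipole amplitude so the signed
        # extremum always lands on the pulse sample
        cfg = SimConfig(seed=0, noise_sd=0.0, ratchet_step=0.0,
                        clip_limit=None, n_true=10.0)
        maps, gt = _maps_from_session(cfg, grid)
        chan = DipoleChannel.from_electrodes(grid, cfg.stim_pair)
        fit = fit_dipole(maps, chan, grid)
        assert fit.k_hat == pytest.approx(cfg.k_true, rel=1e-9)
        assert fit.n_hat == pytest.approx(cfg.n_true, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_three_collinear_points_perfect_fit(self):
        es = ElectrodeSet(["a", "b", "e1", "e2", "e3"],
                          [[0, 0, 0], [10, 0, 0],
                           [20, 0, 0], [30, 0, 0], [0, 20, 0]])
        chan = DipoleChannel.from_electrodes(es, ("a", "b"))
        values = {}
        for lab in ("e1", "e2", "e3"):
            x = dipole_regressor(es.position_of(lab), chan, 5.0)
            values[lab] = 1000.0 * 2.5 * x + 10.0
        amap = ArtifactAmplitudeMap(values=values, stim_pair=("a", "b"),
                                    amplitude=5.0)
        fit = fit_dipole([amap], chan, es)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.k_hat == pytest.approx(2.5)
        assert fit.n_hat == pytest.approx(10.0)

    def test_r_squared_matches_bruteforce(self, grid):
        cfg = SimConfig(seed=4, ratchet_step=0.0)
        maps, _ = _maps_from_session(cfg, grid)
        chan = DipoleChannel.from_electrodes(grid, cfg.stim_pair)
        fit = fit_dipole(maps, chan, grid)
        # independent recomputation from raw (x, V) pairs
        xs, vs = [], []
        for amap in maps:
            for lab, v in amap.values.items():
                if lab in cfg.stim_pair:
                    continue
                xs.append(1000.0 * dipole_regressor(
                    grid.position_of(lab), chan, amap.amplitude))
                vs.append(v)
        xs, vs = np.array(xs), np.array(vs)
        slope, intercept = np.polyfit(xs, vs, 1)
        pred = slope * xs + intercept
        r2 = 1.0 - np.sum((vs - pred) ** 2) / np.sum((vs - vs.mean()) ** 2)
        assert fit.r_squared == pytest.approx(r2, abs=1e-9)
        assert fit.k_hat == pytest.approx(abs(slope), rel=1e-9)

    def test_canonicalization_to_nonnegative_k(self, grid):
        cfg = SimConfig(seed=0, noise_sd=0.0, ratchet_step=0.0,
                        clip_limit=None)
        maps, _ = _maps_from_session(cfg, grid)
        # deliberately swap the pole assignment: slope comes out negative
        chan = DipoleChannel.from_electrodes(grid, ("G9", "G8"))
        fit = fit_dipole(maps, chan, grid)
        assert fit.k_hat == pytest.approx(cfg.k_true, rel=1e-9)
        assert fit.pole_swapped
        assert fit.channel.labels == ("G8", "G9")

    def test_current_scaling_leaves_k_unchanged(self):
        es = standard_grid()
        chan = DipoleChannel.from_electrodes(es, ("G8", "G9"))

        def build(scale):
            maps = []
            for current in (2.0, 4.0):
                values = {}
                for lab in es.labels:
                    if lab in ("G8", "G9"):
                        continue
                    x = dipole_regressor(es.position_of(lab), chan,
                                         scale * current)
                    values[lab] = 1000.0 * 3.3 * x
                maps.append(ArtifactAmplitudeMap(
                    values=values, stim_pair=("G8", "G9"),
                    amplitude=scale * current))
            return maps

        f1 = fit_dipole(build(1.0), chan, es)
        f3 = fit_dipole(build(3.0), chan, es)
        assert f3.k_hat == pytest.approx(f1.k_hat, rel=1e-9)

    def test_rigid_motion_invariance(self, grid):
        cfg = SimConfig(seed=1, ratchet_step=0.0)
        maps, _ = _maps_from_session(cfg, grid)
        chan = DipoleChannel.from_electrodes(grid, cfg.stim_pair)
        fit = fit_dipole(maps, chan, grid)
        rng = np.random.default_rng(9)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = np.array([-11.0, 23.0, 5.0])
        grid2 = grid.transformed(rotation=q, translation=t)
        chan2 = DipoleChannel.from_electrodes(grid2, cfg.stim_pair)
        fit2 = fit_dipole(maps, chan2, grid2)
        assert fit2.k_hat == pytest.approx(fit.k_hat, rel=1e-9)
        assert fit2.n_hat == pytest.approx(fit.n_hat, abs=1e-6)
        assert fit2.r_squared == pytest.approx(fit.r_squared, abs=1e-12)

    def test_noise_recovery_and_r2_trend(self, grid):
        # noise-only sessions: k-hat unbiased, R^2 falls as noise grows
        errs, r2s = [], []
        for noise in (5.0, 50.0, 200.0):
            rel = []
            r2 = []
            for seed in range(5):
                cfg = SimConfig(seed=seed, noise_sd=noise, ratchet_step=0.0)
                maps, _ = _maps_from_session(cfg, grid)
                chan = DipoleChannel.from_electrodes(grid, cfg.stim_pair)
                fit = fit_dipole(maps, chan, grid)
                rel.append(abs(fit.k_hat - cfg.k_true) / cfg.k_true)
                r2.append(fit.r_squared)
            errs.append(np.median(rel))
            r2s.append(np.median(r2))
        assert errs[0] < 0.05
        assert r2s[0] > r2s[1] > r2s[2]

    def test_insufficient_points_rejected(self):
        es = ElectrodeSet(["a", "b", "e"], [[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        chan = DipoleChannel.from_electrodes(es, ("a", "b"))
        amap = ArtifactAmplitudeMap(values={"e": 100.0},
                                    stim_pair=("a", "b"), amplitude=5.0)
        with pytest.raises(PipelineError, match=">= 3"):
            fit_dipole([amap], chan, es)

    def test_rank_deficient_rejected(self):
        es = ElectrodeSet(["a", "b", "e1", "e2", "e3"],
                          [[0, 0, 0], [10, 0, 0],
                           [5, 10, 0], [5, 20, 0], [5, 30, 0]])
        chan = DipoleChannel.from_electrodes(es, ("a", "b"))
        # all three electrodes sit on the zero-potential plane: x identical
        amap = ArtifactAmplitudeMap(
            values={"e1": 1.0, "e2": 2.0, "e3": 3.0},
            stim_pair=("a", "b"), amplitude=5.0)
        with pytest.raises(PipelineError, match="rank-deficient"):
            fit_dipole([amap], chan, es)


class TestPredictMap:
    def test_zero_slope_flat_at_intercept(self, grid):
        from stimartifact.core import DipoleFitResult
        chan = DipoleChannel.from_electrodes(grid, ("G8", "G9"))
        fit = DipoleFitResult(k_hat=0.0, n_hat=12.5, r_squared=1.0,
                              residuals=np.zeros(3), n_points=3, channel=chan)
        pred = predict_map(fit, grid, current=5.0)
        assert all(v == pytest.approx(12.5) for v in pred.values.values())
        assert set(pred.excluded) == {"G8", "G9"}

    def test_residual_consistency(self, grid):
        cfg = SimConfig(seed=2, ratchet_step=0.0)
        maps, _ = _maps_from_session(cfg, grid)
        chan = DipoleChannel.from_electrodes(grid, cfg.stim_pair)
        fit = fit_dipole(maps, chan, grid)
        resid = []
        for amap in maps:
            pred = predict_map(fit, grid, current=amap.amplitude)
            for lab, v in amap.values.items():
                if lab in chan.labels:
                    continue
                resid.append(v - pred.values[lab])
        assert np.allclose(sorted(resid), sorted(fit.residuals))

    def test_translation_invariance(self, grid):
        cfg = SimConfig(seed=3, ratchet_step=0.0)
        maps, _ = _maps_from_session(cfg, grid)
        chan = DipoleChannel.from_electrodes(grid, cfg.stim_pair)
        fit = fit_dipole(maps, chan, grid)
        pred1 = predict_map(fit, grid, current=6.0)
        grid2 = grid.transformed(translation=np.array([100.0, -50.0, 7.0]))
        chan2 = DipoleChannel.from_electrodes(grid2, cfg.stim_pair)
        fit2 = fit_dipole(maps, chan2, grid2)
        pred2 = predict_map(fit2, grid2, current=6.0)
        for lab in pred1.values:
            assert pred2.values[lab] == pytest.approx(pred1.values[lab],
                                                      abs=1e-6)


class TestInterfacePhase:
    FREQS = np.linspace(0.0, 200.0, 101)

    def test_resistive_limit_zero_delay(self):
        d = interface_phase_shift(self.FREQS, c_dl_uf_cm2=1e-12)
        assert np.all(np.abs(d) < 1e-9)

    def test_microsecond_range_at_defaults(self):
        d = interface_phase_shift(self.FREQS)
        mags = np.abs(d)
        assert mags.max() < 1e-4  # well under a tenth of a millisecond
        assert mags.max() > 1e-7  # but a measurable fraction of a us

    def test_continuous_and_bounded(self):
        d = interface_phase_shift(self.FREQS, c_dl_uf_cm2=20.0, r_s=200.0,
                                  r_dl=2e5, r_in=1e8)
        assert np.all(np.isfinite(d))
        # DC limit agrees with the small-omega evaluation
        d_eps = interface_phase_shift([1e-6], c_dl_uf_cm2=20.0, r_s=200.0,
                                      r_dl=2e5, r_in=1e8)
        assert d[0] == pytest.approx(d_eps[0], rel=1e-6)

    def test_area_helper(self):
        # 1.5 mm exposure diameter -> ~0.0177 cm^2
        assert electrode_area_cm2(1.5) == pytest.approx(0.01767, rel=1e-3)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            interface_phase_shift(self.FREQS, r_s=-1.0)
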