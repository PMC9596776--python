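"""Time-domain stage: filtering, epoching, exclusions, pulse extrema,
ratcheting drift and phase-locking."""

import numpy as np
import pytest

from stimartifact import (EpochAnnotation, Recording, SimConfig,
                          simulate_session)
from stimartifact.core import EpochData, PipelineError
from stimartifact.spatial import epoch_artifact_map
from stimartifact.timedomain import (detect_pulse_responses, exclude_saturated,
                                     highpass, phase_lock_stats, ratchet_drift,
                                     sampling_resolution_ms, segment_epochs,
                                     strongest_channels)

FS = 512.0


def _rec(x, labels=None):
    x = np.atleast_2d(x)
    return Recording(x, FS, labels or [f"C{i}" for i in range(len(x))])


class TestHighpass:
    def test_dc_rejection(self):
        rec = _rec(np.full(4096, 1000.0))
        out = highpass(rec).samples[0]
        interior = out[512:-512]
        assert np.abs(interior).max() < 1.0

    def test_50hz_passband_gain(self):
        t = np.arange(8192) / FS
        rec = _rec(np.sin(2 * np.pi * 50 * t))
        out = highpass(rec).samples[0][1024:-1024]
        # two-pass first-order gain at 50 Hz: 1/(1+(1.5/50)^2) ~ 0.9991
        assert out.max() >= 0.998

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 4096))
        y = rng.normal(size=(1, 4096))
        fx = highpass(_rec(x)).samples
        fy = highpass(_rec(y)).samples
        fxy = highpass(_rec(2.0 * x + 3.0 * y)).samples
        assert np.allclose(fxy, 2.0 * fx + 3.0 * fy, atol=1e-8)

    def test_removes_ratcheting_drift(self, grid):
        cfg = SimConfig(seed=0, noise_sd=0.0, amplitudes=(8.0,))
        rec, gt = simulate_session(cfg, grid)
        filt = highpass(rec)
        ep = gt.epochs[0]
        s0, s1 = int(ep.start * FS), int(ep.end * FS)
        k = int(0.2 * FS)

        def drift(x):
            return abs(x[s1 - k:s1].mean() - x[s0:s0 + k].mean())

        raw_d = drift(rec.channel("G7"))
        filt_d = drift(filt.channel("G7"))
        assert raw_d > 10 * filt_d

    def test_cutoff_validation(self):
        rec = _rec(np.zeros(1024))
        with pytest.raises(ValueError):
            highpass(rec, cutoff=FS / 2)

    def test_length_preserved(self):
        rec = _rec(np.random.default_rng(1).normal(size=3000))
        assert highpass(rec).n_samples == 3000


class TestSegmentEpochs:
    def test_window_arithmetic(self):
        rec = _rec(np.zeros(int(20 * FS)))
        ann = EpochAnnotation(10.0, 15.0, ("C0", "C0x"), 5.0)
        rec2 = Recording(np.zeros((2, int(20 * FS))), FS, ["C0", "C0x"])
        (stim, base), = segment_epochs(rec2, [ann])
        assert stim.n_samples == 2560
        assert stim.start_sample == 5120
        assert base.start_sample == 2560
        assert base.n_samples == 2560

    def test_baseline_out_of_range(self):
        rec = _rec(np.zeros(int(10 * FS)))
        ann = EpochAnnotation(1.0, 6.0, ("C0", "C0"), 5.0)
        with pytest.raises(PipelineError, match="bounds"):
            segment_epochs(_rec(np.zeros(int(10 * FS))), [ann])

    def test_adjacent_epochs_fill_gap_exactly(self):
        # two 2 s epochs separated by a 2 s gap: second baseline is the gap
        rec = _rec(np.zeros(int(12 * FS)))
        anns = [EpochAnnotation(2.0, 4.0, ("C0", "C0"), 5.0),
                EpochAnnotation(6.0, 8.0, ("C0", "C0"), 5.0)]
        pairs = segment_epochs(rec, anns)
        assert pairs[1][1].start_sample == int(4.0 * FS)

    def test_overlapping_baseline_rejected(self):
        rec = _rec(np.zeros(int(12 * FS)))
        anns = [EpochAnnotation(2.0, 4.0, ("C0", "C0"), 5.0),
                EpochAnnotation(5.0, 7.0, ("C0", "C0"), 5.0)]
        with pytest.raises(PipelineError, match="overlaps"):
            segment_epochs(rec, anns)


class TestExclusions:
    def _epoch(self, samples, labels):
        return EpochData(samples, FS, labels, start_sample=0)

    def test_only_stim_pair_when_clean(self):
        ep = self._epoch(np.zeros((4, 100)), ["A", "B", "C", "D"])
        excl = exclude_saturated(ep, ("A", "B"))
        assert excl == {"A": "stim_channel", "B": "stim_channel"}

    def test_saturated_neighbor(self, grid):
        # high ratcheting drives the nearest neighbour to the rails
        cfg = SimConfig(seed=0, ratchet_step=120.0, amplitudes=(10.0,))
        rec, gt = simulate_session(cfg, grid)
        (stim, _), = segment_epochs(rec, gt.epochs)
        excl = exclude_saturated(stim, ("G8", "G9"))
        assert excl.get("G7") == "saturated" or excl.get("G10") == "saturated"

    def test_all_excluded_gives_structured_error(self):
        samples = np.full((3, 100), 9000.0)
        ep = self._epoch(samples, ["A", "B", "C"])
        excl = exclude_saturated(ep, ("A", "B"))
        assert set(excl) == {"A", "B", "C"}
        resp = detect_pulse_responses(ep, 50.0, excluded=excl)
        ann = EpochAnnotation(0.0, 100 / FS, ("A", "B"), 5.0)
        with pytest.raises(PipelineError, match="no included channels"):
            epoch_artifact_map(resp, ann)

    def test_missing_stim_label(self):
        ep = self._epoch(np.zeros((2, 10)), ["A", "B"])
        with pytest.raises(KeyError):
            exclude_saturated(ep, ("A", "Z"))


class TestDetectPulseResponses:
    def test_response_count_5s_at_50hz(self):
        ep = EpochData(np.zeros((1, 2560)), FS, ["A"], 0)
        resp = detect_pulse_responses(ep, 50.0)
        assert len(resp.amplitudes["A"]) == 250

    @pytest.mark.parametrize("n_samples,expect",
                             [(2560, 250), (1024, 100), (1000, 97)])
    def test_count_is_floor_duration_times_rate(self, n_samples, expect):
        rng = np.random.default_rng(0)
        ep = EpochData(rng.normal(size=(1, n_samples)), FS, ["A"], 0)
        resp = detect_pulse_responses(ep, 50.0)
        assert len(resp.amplitudes["A"]) == expect

    def test_zero_channel_yields_zero_amplitudes(self):
        ep = EpochData(np.zeros((1, 2560)), FS, ["A"], 0)
        resp = detect_pulse_responses(ep, 50.0)
        assert np.all(resp.amplitudes["A"] == 0.0)

    def test_noiseless_times_and_amplitudes_exact(self, noiseless_session):
        cfg, rec, gt = noiseless_session
        pairs = segment_epochs(rec, gt.epochs)
        stim, _ = pairs[0]
        resp = detect_pulse_responses(
            stim, cfg.pulse_freq,
            excluded=exclude_saturated(stim, cfg.stim_pair))
        onsets = gt.pulse_onsets[0]
        amps = gt.pulse_amplitudes[0]
        for lab in ("G7", "G10", "G3"):
            assert np.all(np.abs(resp.times[lab] - onsets) <= 1.0 / FS)
            assert np.allclose(resp.amplitudes[lab], amps[lab])

    def test_median_interval_matches_pulse_period(self, noiseless_session):
        cfg, rec, gt = noiseless_session
        stim, _ = segment_epochs(rec, gt.epochs)[0]
        resp = detect_pulse_responses(
            stim, cfg.pulse_freq,
            excluded=exclude_saturated(stim, cfg.stim_pair))
        iri = np.median(np.diff(resp.times["G7"])) * 1000.0
        # 20 ms nominal; sample quantization at 512 Hz gives 10 samples
        assert abs(iri - 20.0) <= 0.5

    def test_amplitude_decreases_with_distance(self, noiseless_session, grid):
        cfg, rec, gt = noiseless_session
        stim, _ = segment_epochs(rec, gt.epochs)[-1]
        resp = detect_pulse_responses(
            stim, cfg.pulse_freq,
            excluded=exclude_saturated(stim, cfg.stim_pair))
        mid = 0.5 * (grid.position_of("G8") + grid.position_of("G9"))
        dist, mag = [], []
        for lab in resp.channels:
            dist.append(np.linalg.norm(grid.position_of(lab) - mid))
            mag.append(abs(np.median(resp.amplitudes[lab])))
        r = np.corrcoef(dist, mag)[0, 1]
        assert r < -0.5

    def test_window_too_short(self):
        ep = EpochData(np.zeros((1, 100)), FS, ["A"], 0)
        with pytest.raises(ValueError, match="2 samples"):
            detect_pulse_responses(ep, 300.0)


class TestRatchetDrift:
    def test_noise_only_drift_bounded(self):
        rng = np.random.default_rng(0)
        sd = 10.0
        n = 5000
        x = rng.normal(0, sd, n)
        drift, _ = ratchet_drift(x)
        # standard error of the difference of two 10% sample means
        bound = 2 * 3 * sd / np.sqrt(0.1 * n)
        assert abs(drift) < bound

    def test_polarity_follows_dipole_side(self, grid):
        cfg = SimConfig(seed=0, noise_sd=0.0, amplitudes=(8.0,))
        rec, gt = simulate_session(cfg, grid)
        stim, _ = segment_epochs(rec, gt.epochs)[0]
        # G7 on the source side, G10 on the sink side
        _, pol7 = ratchet_drift(stim.channel("G7"))
        _, pol10 = ratchet_drift(stim.channel("G10"))
        assert pol7 > 0 > pol10

    def test_infinite_tau_limit(self, grid):
        # with tau >> epoch, every pulse leaves its full step behind
        cfg = SimConfig(seed=0, noise_sd=0.0, amplitudes=(4.0,),
                        ratchet_step=5.0, ratchet_tau=1e6, clip_limit=None)
        rec, gt = simulate_session(cfg, grid)
        stim, _ = segment_epochs(rec, gt.epochs)[0]
        drift, _ = ratchet_drift(stim.channel("G7"))
        J = len(gt.pulse_onsets[0])
        expected = J * cfg.ratchet_step * 4.0
        # the 10%-mean estimator sees ~0.9 of the full staircase rise
        assert drift == pytest.approx(0.9 * expected, rel=0.05)


class TestPhaseLocking:
    def _resp(self, times):
        n = len(next(iter(times.values())))
        return __import__("stimartifact").PulseResponses(
            times={k: np.asarray(v, dtype=float) for k, v in times.items()},
            amplitudes={k: np.ones(n) for k in times},
            fs=FS, pulse_freq=50.0)

    def test_identical_channels_zero_offset(self):
        resp = self._resp({"A": [0.1], "B": [0.1]})
        offsets, max_s, max_samp = phase_lock_stats(resp)
        assert max_s == 0.0 and max_samp == 0.0

    def test_constructed_three_sample_shift(self):
        t = np.arange(10) * 0.02
        resp = self._resp({"A": t, "B": t + 3.0 / FS})
        _, max_s, max_samp = phase_lock_stats(resp)
        assert max_s == pytest.approx(3.0 / FS)
        assert max_samp == pytest.approx(3.0)

    def test_requires_two_channels(self):
        resp = self._resp({"A": [0.1]})
        with pytest.raises(ValueError, match="2 channels"):
            phase_lock_stats(resp)

    def test_simulated_session_within_2ms(self, noisy_session, grid):
        cfg, rec, gt = noisy_session
        filt = highpass(rec)
        stim, _ = segment_epochs(filt, gt.epochs)[-1]
        resp = detect_pulse_responses(
            stim, cfg.pulse_freq,
            excluded=exclude_saturated(stim, cfg.stim_pair))
        strongest = strongest_channels(resp, 4)
        _, max_s, _ = phase_lock_stats(resp, strongest)
        assert max_s <= 0.002


def test_sampling_resolution():
    assert sampling_resolution_ms(512.0) == pytest.approx(1.953125)
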