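"""Noise estimation, change-point step calling and binning."""

import numpy as np
import pytest

from bleachcount import (
    IntensityTrace,
    OligomerDistribution,
    SimulationConfig,
    StepCallParams,
    bin_steps,
    detect_steps,
    estimate_noise,
    inject_blink,
    simulate_traces,
)


def trace(y, **kw):
    return IntensityTrace(np.asarray(y, float), **kw)


class TestNoiseEstimate:
    def test_gaussian_noise_recovered(self, rng):
        y = rng.normal(0.0, 1.0, 10_000)
        assert estimate_noise(trace(y)) == pytest.approx(1.0, rel=0.05)

    def test_steps_do_not_inflate_the_estimate(self, rng, staircase):
        y = staircase + rng.normal(0, 2.0, staircase.size)
        assert estimate_noise(trace(y)) == pytest.approx(2.0, rel=0.2)

    def test_noiseless_staircase_is_essentially_zero(self, staircase):
        assert estimate_noise(trace(staircase)) < 1e-9 * 100  # step size 100

    def test_translation_invariance(self, rng):
        y = rng.normal(0.0, 1.5, 5000)
        assert estimate_noise(trace(y)) == pytest.approx(
            estimate_noise(trace(y + 1e4)), rel=1e-12
        )

    def test_constant_trace_gives_zero(self):
        assert estimate_noise(trace(np.full(50, 7.0))) == 0.0


class TestDetectSteps:
    def test_noiseless_staircase_exact(self, staircase):
        call = detect_steps(trace(staircase, trace_id="t"))
        assert call.status == "accepted"
        assert call.n_steps == 3
        assert call.changepoint_frames == (30, 60, 90)
        np.testing.assert_allclose(call.segment_levels, [300, 200, 100, 0], atol=1e-9)

    def test_constant_trace_rejected_zero_steps(self):
        call = detect_steps(trace(np.full(100, 50.0)))
        assert call.status == "rejected_zero_steps"
        call = detect_steps(trace(np.zeros(100)))
        assert call.status == "rejected_zero_steps"

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            trace(np.arange(10.0))

    def test_deterministic(self, rng, staircase):
        y = staircase + rng.normal(0, 10.0, staircase.size)
        a, b = detect_steps(trace(y)), detect_steps(trace(y))
        assert a == b

    def test_scale_equivariance(self, rng, staircase):
        y = staircase + 100 + rng.normal(0, 10.0, staircase.size)
        a = detect_steps(trace(y))
        b = detect_steps(trace(y * 37.5))
        assert (a.n_steps, a.status, a.changepoint_frames) == (
            b.n_steps, b.status, b.changepoint_frames,
        )

    def test_tiny_noise_changes_no_call(self, rng):
        """Noise 20x below the step size leaves a 100-trace panel unchanged."""
        cfg = SimulationConfig(
            q_true=OligomerDistribution(0.2, 0.3, 0.5), n_traces=100,
            noise_sigma=0.0, seed=5,
        )
        clean = simulate_traces(cfg).traces
        for t in clean:
            a = detect_steps(t)
            noisy = IntensityTrace(
                t.intensities + rng.normal(0, 5.0, t.n_frames),  # step 100, sigma 5
                frame_interval=t.frame_interval, trace_id=t.trace_id,
            )
            b = detect_steps(noisy)
            assert (a.status, a.n_steps) == (b.status, b.n_steps)

    def test_blink_rejected_upward(self, staircase):
        blinked = inject_blink(
            trace(staircase, trace_id="b"), start_frame=40, duration_frames=8, depth=150.0
        )
        assert detect_steps(blinked).status == "rejected_upward"

    def test_incomplete_bleach_rejected(self, staircase):
        """A dip below the final level means the trace did not end at baseline."""
        y = np.concatenate([staircase, np.full(30, 80.0)])  # ...0 then back up to 80
        assert detect_steps(trace(y)).status in ("rejected_upward", "rejected_no_bleach")

    def test_too_many_steps_rejected(self):
        y = np.concatenate([np.full(10, 100.0 * k) for k in range(12, -1, -1)])
        call = detect_steps(trace(y), StepCallParams(max_steps=10))
        assert call.status == "rejected_too_many"
        assert detect_steps(trace(y), StepCallParams(max_steps=12)).status == "accepted"

    def test_params_validation(self):
        with pytest.raises(ValueError, match="penalty"):
            StepCallParams(penalty=0)
        with pytest.raises(ValueError, match="max_steps"):
            StepCallParams(max_steps=2)


def test_benchmark_accuracy_on_simulated_traces():
    """step/noise = 5 with <= 3 true steps: at least 95% of accepted calls
    carry the true step count (spot-check at modest panel size)."""
    cfg = SimulationConfig(
        q_true=OligomerDistribution(0.2, 0.3, 0.5), r=0.7, n_traces=250,
        noise_sigma=20.0, seed=12,
    )
    res = simulate_traces(cfg)
    calls = [detect_steps(t) for t in res.traces]
    accepted = [(c.n_steps, gt) for c, gt in zip(calls, res.steps_in_window) if c.accepted]
    assert len(accepted) > 200
    agree = sum(n == gt for n, gt in accepted)
    assert agree / len(accepted) >= 0.95


class TestBinSteps:
    def test_binning_rule(self):
        calls = [
            detect_steps_stub(n, "accepted") for n in (1, 2, 3, 4, 5)
        ]
        counts, audit = bin_steps(calls)
        assert (counts.n1, counts.n2, counts.n3) == (1, 1, 3)
        assert audit == {"accepted": 5}

    def test_all_rejected_yields_empty_tally_with_audit(self):
        calls = [detect_steps_stub(0, "rejected_zero_steps") for _ in range(4)]
        counts, audit = bin_steps(calls)
        assert (counts.n1, counts.n2, counts.n3) == (0, 0, 0)
        assert audit == {"rejected_zero_steps": 4, "accepted": 0}

    def test_tallies_match_ground_truth_under_perfect_detection(self):
        cfg = SimulationConfig(
            q_true=OligomerDistribution(0.3, 0.3, 0.4), n_traces=150,
            noise_sigma=0.0, seed=3,
        )
        res = simulate_traces(cfg)
        calls = [detect_steps(t) for t in res.traces]
        counts, audit = bin_steps(calls)
        assert audit == {"accepted": 150}
        truth = np.minimum(res.steps_in_window, 3)
        assert (counts.n1, counts.n2, counts.n3) == tuple(
            int((truth == k).sum()) for k in (1, 2, 3)
        )


def test_higher_order_bin_monotone_in_max_steps():
    y = np.concatenate([np.full(10, 100.0 * k) for k in range(12, -1, -1)])
    tallies = []
    for max_steps in (3, 11, 12):
        call = detect_steps(trace(y), StepCallParams(max_steps=max_steps))
        tallies.append(bin_steps([call])[0].n3)
    assert tallies == sorted(tallies)


def detect_steps_stub(n_steps, status):
    from bleachcount import StepCall

    return StepCall(
        trace_id=f"s{n_steps}", n_steps=n_steps, status=status,
        changepoint_frames=(), segment_levels=(),
    )
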