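"""Synthetic step counts and photobleaching traces with known ground truth.

Two generative modes are first-class because the inference model and the
physical process differ subtly:

``model_faithful``
    Draws ``s ~ Categorical(q_true)`` and then ``w ~ Categorical(eta[s, .])``
    — exactly the likelihood the sampler inverts.  Use for calibration and
    recovery tests.

``physical``
    Draws ``s ~ Categorical(q_true)``, matures each subunit independently
    (``m ~ Binomial(s, r)``), discards complexes with no mature GFP (they are
    never detected), and reports ``w = min(m, 3)``.  Detection favors larger
    complexes (probability ``1 - (1-r)^s``), so the s-distribution among
    detected traces is tilted away from ``q_true``; this mode quantifies the
    resulting bias instead of hiding it.

``simulate_traces`` renders physical-mode complexes as intensity time series:
every mature GFP contributes ``unit_intensity`` until its own
``Exponential(bleach_rate)`` bleach time, on top of a constant background
with additive Gaussian camera noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np

from .inference import StepCountData
from .maturation import OligomerDistribution, eta_matrix
from .steps import IntensityTrace

__all__ = [
    "SimulationConfig",
    "CountsResult",
    "TracesResult",
    "simulate_counts",
    "simulate_traces",
    "inject_blink",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth conditions for the synthetic generator.

    Intensity defaults mimic a single-GFP TIRF experiment: 100 ms frames,
    one GFP worth of signal = 100 units over a background of 50, per-frame
    noise sigma = 12.5 (step-to-noise ratio 8), and a 0.1 /s bleach hazard
    (10 s mean bleach time, typical for GFP under continuous TIRF
    illumination) so that essentially every GFP bleaches inside the 60 s
    observation window while two bleach events rarely share a frame.
    """

    q_true: OligomerDistribution
    r: float = 0.7
    n_traces: int = 1000
    mode: str = "model_faithful"  # or "physical"
    unit_intensity: float = 100.0
    noise_sigma: float = 12.5
    bleach_rate: float = 0.1  # per second per mature GFP
    n_frames: int = 600
    frame_interval: float = 0.1
    background: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("model_faithful", "physical"):
            raise ValueError(f"mode must be 'model_faithful' or 'physical', got {self.mode!r}")
        if self.n_traces <= 0:
            raise ValueError("n_traces must be positive")
        if self.unit_intensity <= 0 or self.noise_sigma < 0 or self.bleach_rate <= 0:
            raise ValueError("unit_intensity > 0, noise_sigma >= 0, bleach_rate > 0 required")
        if self.n_frames < 20:
            raise ValueError("n_frames must be >= 20")
        # mean bleach time should fit comfortably inside the window
        if 1.0 / self.bleach_rate >= self.n_frames * self.frame_interval:
            warnings.warn(
                "expected bleach time exceeds the trace duration; "
                "many GFPs will survive the window and steps will be missed",
                stacklevel=2,
            )

    def rng(self) -> np.random.Generator:
        return np.random.Generator(np.random.Philox(np.uint64(self.seed)))


@dataclass(frozen=True)
class CountsResult:
    counts: StepCountData
    s_true: np.ndarray  # per delivered trace
    w_obs: np.ndarray
    n_discarded: int  # physical mode: attempted complexes with zero mature GFP


@dataclass(frozen=True)
class TracesResult:
    traces: list[IntensityTrace]
    s_true: np.ndarray
    m_true: np.ndarray  # mature GFP count per delivered trace
    steps_in_window: np.ndarray  # bleach events inside the observation window
    coincident: np.ndarray  # True where two bleach events share a frame
    n_discarded: int


def _draw_s(rng: np.random.Generator, q: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(3, size=n, p=q) + 1


def simulate_counts(config: SimulationConfig) -> CountsResult:
    """Generate a step-count tally with per-trace ground truth (s, w)."""
    q = config.q_true.as_array()
    rng = config.rng()
    eta = eta_matrix(config.r)

    if config.mode == "model_faithful":
        s = _draw_s(rng, q, config.n_traces)
        w = np.empty_like(s)
        for sv in (1, 2, 3):
            idx = s == sv
            if idx.any():
                w[idx] = rng.choice(3, size=int(idx.sum()), p=eta[sv, 1:]) + 1
        n_discarded = 0
    else:  # physical: resample until n_traces complexes are detected
        s_parts, w_parts = [], []
        delivered = 0
        n_discarded = 0
        while delivered < config.n_traces:
            batch = max(config.n_traces - delivered, 16)
            s_b = _draw_s(rng, q, batch)
            m_b = rng.binomial(s_b, config.r)
            detected = m_b > 0
            n_discarded += int((~detected).sum())
            s_parts.append(s_b[detected])
            w_parts.append(np.minimum(m_b[detected], 3))
            delivered += int(detected.sum())
        s = np.concatenate(s_parts)[: config.n_traces]
        w = np.concatenate(w_parts)[: config.n_traces]

    counts = StepCountData(int((w == 1).sum()), int((w == 2).sum()), int((w == 3).sum()))
    return CountsResult(counts=counts, s_true=s, w_obs=w, n_discarded=n_discarded)


def simulate_traces(config: SimulationConfig) -> TracesResult:
    """Render detected complexes as noisy stepwise-decreasing intensity traces.

    Each delivered trace carries ``m >= 1`` visible (mature) GFPs with
    independent exponential bleach times; the recorded ground truth is the
    number of bleach events that fall inside the observation window.  Two
    events landing in the same frame are forced onto distinct frames (the
    later one is nudged forward) and the trace is flagged ``coincident``.
    The mature count follows the configured mode:
    ``model_faithful`` draws it from the detection-conditioned eta row (the
    exact likelihood the sampler inverts), ``physical`` matures subunits by
    independent Bernoulli(r) trials and discards all-immature complexes.
    """
    q = config.q_true.as_array()
    rng = config.rng()
    eta = eta_matrix(config.r)

    s_list, m_list, nsteps, coinc = [], [], [], []
    traces: list[IntensityTrace] = []
    n_discarded = 0
    delivered = 0
    while delivered < config.n_traces:
        s = int(_draw_s(rng, q, 1)[0])
        if config.mode == "model_faithful":
            m = int(rng.choice(3, p=eta[s, 1:])) + 1
        else:
            m = int(rng.binomial(s, config.r))
            if m == 0:
                n_discarded += 1
                continue
        bleach_t = rng.exponential(1.0 / config.bleach_rate, size=m)
        # first dark frame per GFP; colliding events are nudged to the next
        # frame so every bleach is a distinct step, and flagged coincident
        frames = np.sort(np.floor(bleach_t / config.frame_interval).astype(int) + 1)
        was_coincident = len(frames) != len(np.unique(frames))
        for i in range(1, len(frames)):
            frames[i] = max(frames[i], frames[i - 1] + 1)
        in_window = frames <= config.n_frames - 1
        n_alive = m - (frames[:, None] <= np.arange(config.n_frames)[None, :]).sum(axis=0)
        signal = config.background + config.unit_intensity * n_alive
        if config.noise_sigma > 0:
            signal = signal + rng.normal(0.0, config.noise_sigma, size=config.n_frames)
        traces.append(
            IntensityTrace(signal, frame_interval=config.frame_interval, trace_id=f"trace{delivered:05d}")
        )
        s_list.append(s)
        m_list.append(m)
        nsteps.append(int(in_window.sum()))
        coinc.append(was_coincident)
        delivered += 1

    return TracesResult(
        traces=traces,
        s_true=np.array(s_list),
        m_true=np.array(m_list),
        steps_in_window=np.array(nsteps),
        coincident=np.array(coinc, dtype=bool),
        n_discarded=n_discarded,
    )


def inject_blink(
    trace: IntensityTrace,
    start_frame: int,
    duration_frames: int,
    depth: float,
) -> IntensityTrace:
    """Insert a transient dark interval (blink) into a trace.

    The intensity drops by ``depth`` for ``duration_frames`` frames and then
    recovers — an upward jump that a well-behaved bleaching trace never
    shows.  Used to exercise the step caller's ``rejected_upward`` rule.
    """
    y = trace.intensities.copy()
    stop = min(start_frame + duration_frames, y.size)
    if not (0 <= start_frame < stop):
        raise ValueError("blink interval falls outside the trace")
    y[start_frame:stop] -= depth
    return IntensityTrace(y, frame_interval=trace.frame_interval, trace_id=trace.trace_id)
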