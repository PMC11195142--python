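"""Photobleaching step calling on single-molecule intensity traces.

Each trace is fit with a piecewise-constant signal by penalized least-squares
change-point search (optimal partitioning with PELT-style pruning; the
penalty per change-point is ``penalty * sigma^2 * log(n)`` where ``sigma`` is
a robust noise scale from the median absolute first difference).  Fitted
jumps smaller than ``min_step_sigma * sigma`` are merged away; the remaining
downward jumps are the bleaching steps.

Traces are rejected rather than silently repaired when they violate the
single-fluorophore bleaching picture:

* an upward jump above threshold (blinking, aggregation) -> ``rejected_upward``
* final level not at the baseline level -> ``rejected_no_bleach``
* no detectable step -> ``rejected_zero_steps`` (zero-step complexes are
  structurally invisible, so such traces carry no usable information)
* more than ``max_steps`` jumps -> ``rejected_too_many``

Accepted calls are binned into the monomer / dimer / higher-order tally used
by inference: one step -> n1, two -> n2, three or more -> n3.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .inference import StepCountData

__all__ = [
    "IntensityTrace",
    "StepCallParams",
    "StepCall",
    "estimate_noise",
    "detect_steps",
    "bin_steps",
    "MIN_FRAMES",
]

MIN_FRAMES = 20

# Gaussian consistency constant: median(|N(0,1)|) = Phi^-1(0.75)
_MAD_NORM = 0.6744897501960817


@dataclass(frozen=True)
class IntensityTrace:
    """One molecule's fluorescence time series at a fixed frame interval."""

    intensities: np.ndarray
    frame_interval: float = 0.1  # seconds; 100 ms camera integration
    trace_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1 or arr.size < MIN_FRAMES:
            raise ValueError(
                f"trace {self.trace_id!r} needs >= {MIN_FRAMES} frames, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"trace {self.trace_id!r} contains missing/non-finite values")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        object.__setattr__(self, "intensities", arr)

    @property
    def n_frames(self) -> int:
        return self.intensities.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class StepCallParams:
    """Tunables of the step caller.

    penalty
        Dimensionless change-point penalty constant; the effective penalty is
        ``penalty * sigma^2 * log(n_frames)`` (BIC-like).
    min_step_sigma
        Minimum |jump| kept as a step, in multiples of the robust noise scale.
    max_steps
        Calls with more downward jumps are rejected.
    baseline_sigma
        The final segment must sit within this many noise scales of the
        lowest fitted level, so partially-bleached anomalies are rejected.
    """

    penalty: float = 3.0
    min_step_sigma: float = 3.0
    max_steps: int = 10
    baseline_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.penalty <= 0:
            raise ValueError("penalty must be positive")
        if self.min_step_sigma <= 0:
            raise ValueError("min_step_sigma must be positive")
        if self.max_steps < 3:
            raise ValueError("max_steps must be >= 3")


@dataclass(frozen=True)
class StepCall:
    trace_id: str
    n_steps: int
    status: str  # accepted | rejected_upward | rejected_no_bleach | rejected_zero_steps | rejected_too_many
    changepoint_frames: tuple[int, ...]
    segment_levels: tuple[float, ...]

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


def estimate_noise(trace: IntensityTrace) -> float:
    """Robust per-frame noise scale from the median absolute first difference.

    For i.i.d. Gaussian noise the first difference has scale sqrt(2)*sigma,
    so ``median|diff| / (sqrt(2) * 0.6745)`` is consistent for sigma while
    ignoring the few frames that straddle a bleaching step.  Returns 0 for a
    constant trace.
    """
    d = np.abs(np.diff(trace.intensities))
    return float(np.median(d) / (np.sqrt(2.0) * _MAD_NORM))


def _segment_changepoints(y: np.ndarray, penalty: float) -> list[int]:
    """Optimal partitioning of ``y`` into constant segments, PELT pruning.

    Minimizes sum of within-segment squared residuals + penalty per
    change-point.  Returns the sorted interior change-point indices
    (a change-point at ``t`` starts a new segment at frame ``t``).
    """
    n = y.size
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def seg_cost(a: np.ndarray, t: int) -> np.ndarray:
        # residual sum of squares of y[a:t] around its mean, vectorized in a
        length = t - a
        sy = s1[t] - s1[a]
        return (s2[t] - s2[a]) - sy * sy / length

    f = np.empty(n + 1)
    f[0] = -penalty
    prev = np.zeros(n + 1, dtype=np.int64)
    cands = np.array([0], dtype=np.int64)
    for t in range(1, n + 1):
        costs = f[cands] + seg_cost(cands, t) + penalty
        best = int(np.argmin(costs))
        f[t] = costs[best]
        prev[t] = cands[best]
        # prune candidates that can never be optimal again
        keep = f[cands] + seg_cost(cands, t) <= f[t]
        cands = np.append(cands[keep], t)

    cps: list[int] = []
    t = n
    while t > 0:
        a = int(prev[t])
        if a > 0:
            cps.append(a)
        t = a
    cps.reverse()
    return cps


def _merge_small_jumps(
    y: np.ndarray, cps: list[int], min_jump: float
) -> tuple[list[int], np.ndarray]:
    """Drop change-points whose level jump is below ``min_jump``.

    Iteratively removes the smallest sub-threshold jump and refits segment
    means, so two small artefactual jumps cannot shield each other.
    """
    bounds = [0, *cps, y.size]
    while True:
        means = np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
        if len(bounds) <= 2:
            return [], means
        jumps = np.abs(np.diff(means))
        worst = int(np.argmin(jumps))
        if jumps[worst] >= min_jump:
            return bounds[1:-1], means
        del bounds[worst + 1]


def detect_steps(trace: IntensityTrace, params: StepCallParams | None = None) -> StepCall:
    """Call photobleaching steps on one trace. Deterministic.

    See the module docstring for the fit, threshold and rejection rules.
    """
    if params is None:
        params = StepCallParams()
    y = trace.intensities
    sigma = estimate_noise(trace)
    # Penalty floor keeps the search well-posed on (near-)noiseless traces.
    scale_floor = 1e-9 * max(float(np.ptp(y)), 1.0)
    eff_sigma = max(sigma, scale_floor)
    penalty = params.penalty * eff_sigma**2 * np.log(y.size)

    cps = _segment_changepoints(y, penalty)
    cps, levels = _merge_small_jumps(y, cps, params.min_step_sigma * eff_sigma)
    jumps = np.diff(levels)

    def call(status: str, n_steps: int = 0) -> StepCall:
        return StepCall(
            trace_id=trace.trace_id,
            n_steps=n_steps,
            status=status,
            changepoint_frames=tuple(int(c) for c in cps),
            segment_levels=tuple(float(v) for v in levels),
        )

    if jumps.size and jumps.max() > 0:
        return call("rejected_upward")
    n_down = int(np.sum(jumps < 0))
    if n_down == 0:
        return call("rejected_zero_steps")
    if n_down > params.max_steps:
        return call("rejected_too_many", n_down)
    if levels[-1] > levels.min() + params.baseline_sigma * eff_sigma:
        return call("rejected_no_bleach", n_down)
    return call("accepted", n_down)


def bin_steps(calls: Iterable[StepCall]) -> tuple[StepCountData, dict[str, int]]:
    """Tally accepted calls into (n1, n2, n3+) and audit the rejections.

    Returns the tally and a dict of rejection counts by status (always
    including an ``accepted`` entry).
    """
    tally = [0, 0, 0]
    audit: Counter[str] = Counter()
    for c in calls:
        audit[c.status] += 1
        if c.accepted:
            tally[min(c.n_steps, 3) - 1] += 1
    audit.setdefault("accepted", 0)
    return StepCountData(*tally), dict(audit)
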