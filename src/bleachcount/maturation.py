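"""Probability model linking true subunit number to observed bleaching steps.

A complex carrying ``s`` GFP-tagged subunits shows only ``w`` photobleaching
steps, where ``w`` counts the *mature* (fluorescent) GFPs.  Each GFP matures
independently with probability ``r`` (~0.7 for GFP), so ``w | s`` is binomial.
Complexes in which every GFP failed to mature produce zero steps and are never
picked up during trace selection; conditioning on detection (``w >= 1``) gives
the eta matrix actually used in inference.

Two matrices are exposed:

* ``pi_matrix(r)``   — P(w mature | s total), the unconditional binomial rows.
* ``eta_matrix(r)``  — P(w | s, detected) = pi[s, w] / (1 - pi[s, 0]) for
  w >= 1, and eta[s, 0] = 0.

Subunit counts are modeled up to ``S_MAX = 3``; the ``s = 3`` class means
"trimer or larger", mirroring the experimental binning of three-or-more steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

__all__ = [
    "S_MAX",
    "DEFAULT_MATURATION",
    "OligomerDistribution",
    "MaturationModel",
    "pi_matrix",
    "eta_matrix",
    "observed_marginal",
]

S_MAX = 3
#: literature maturation efficiency of GFP used throughout
DEFAULT_MATURATION = 0.7

# Guard against 1 - pi[s, 0] underflowing to zero in eta normalisation.
_MIN_R_FOR_ETA = 1e-8


def _check_r(r: float, minimum: float = 0.0) -> float:
    r = float(r)
    if not np.isfinite(r) or r <= minimum or r > 1.0:
        raise ValueError(
            f"maturation efficiency r must satisfy {minimum} < r <= 1, got {r!r}"
        )
    return r


def pi_matrix(r: float) -> np.ndarray:
    """Binomial maturation matrix pi[s, w] = P(w mature | s total GFP).

    Parameters
    ----------
    r : float
        Per-GFP maturation probability, in (0, 1].

    Returns
    -------
    ndarray of shape (4, 4)
        Rows indexed by s = 0..3, columns by w = 0..3; row 0 is unused and
        kept only so that ``pi[s, w]`` reads naturally.  ``pi[s, w] = 0``
        whenever ``w > s``.
    """
    r = _check_r(r)
    pi = np.zeros((S_MAX + 1, S_MAX + 1))
    for s in range(1, S_MAX + 1):
        w = np.arange(s + 1)
        pi[s, : s + 1] = binom.pmf(w, s, r)
    return pi


def eta_matrix(r: float) -> np.ndarray:
    """Detection-conditioned step matrix eta[s, w] = P(w | s, w >= 1).

    Zero-step complexes are invisible to trace selection, so each binomial
    row is renormalised over w >= 1: ``eta[s, w] = pi[s, w] / (1 - pi[s, 0])``
    and ``eta[s, 0] = 0``.
    """
    r = _check_r(r, minimum=_MIN_R_FOR_ETA)
    pi = pi_matrix(r)
    eta = np.zeros_like(pi)
    for s in range(1, S_MAX + 1):
        # 1 - pi[s, 0] = 1 - (1-r)^s, computed cancellation-free
        detected = -np.expm1(s * np.log1p(-r)) if r < 1.0 else 1.0
        eta[s, 1:] = pi[s, 1:] / detected
    return eta


@dataclass(frozen=True)
class OligomerDistribution:
    """Fractions of complexes that are monomer, dimer, trimer-or-larger.

    A point on the 2-simplex: ``q1 + q2 + q3 = 1``.
    """

    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        q = self.as_array()
        if np.any(q < -1e-12) or np.any(q > 1 + 1e-12):
            raise ValueError(f"oligomer fractions must lie in [0, 1], got {tuple(q)}")
        if abs(q.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"oligomer fractions must sum to 1 (got sum {q.sum():.12g})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.q1, self.q2, self.q3], dtype=float)

    @classmethod
    def from_array(cls, q) -> "OligomerDistribution":
        q = np.asarray(q, dtype=float)
        if q.shape != (3,):
            raise ValueError(f"expected three fractions, got shape {q.shape}")
        return cls(*q)


@dataclass(frozen=True)
class MaturationModel:
    """Maturation efficiency ``r`` with its derived probability matrices.

    The matrices are recomputed from ``r`` on every access, so the object can
    never hold stale state.
    """

    r: float = DEFAULT_MATURATION
    s_max: int = field(default=S_MAX)

    def __post_init__(self) -> None:
        _check_r(self.r)
        if self.s_max != S_MAX:
            raise ValueError(f"only s_max = {S_MAX} is supported")

    @property
    def pi(self) -> np.ndarray:
        return pi_matrix(self.r)

    @property
    def eta(self) -> np.ndarray:
        return eta_matrix(self.r)


def observed_marginal(q: OligomerDistribution | np.ndarray, r: float) -> np.ndarray:
    """Marginal step distribution P(w) = sum_s q_s * eta[s, w] for w = 1..3.

    This is the distribution of observed step counts implied by an oligomer
    distribution ``q`` once immature GFPs and the loss of zero-step traces are
    accounted for; used for posterior-predictive checks.
    """
    if isinstance(q, OligomerDistribution):
        qv = q.as_array()
    else:
        qv = OligomerDistribution.from_array(q).as_array()
    eta = eta_matrix(r)
    # rows s=1..3, columns w=1..3
    return qv @ eta[1:, 1:]
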