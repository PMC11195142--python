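"""Posterior inference of the oligomer distribution from step-count tallies.

Model
-----
Each analyzed trace ``n`` carries a latent true subunit number
``s_n ~ Categorical(q1, q2, q3)`` and shows ``w_n ~ Categorical(eta[s_n, .])``
observed bleaching steps, where eta is the detection-conditioned maturation
matrix (see :mod:`bleachcount.maturation`).  The target ``q`` receives a flat
``Dirichlet(1, 1, 1)`` prior.  Because traces are exchangeable the data reduce
to the tally ``(n1, n2, n3)`` of traces with 1, 2, 3 steps; zero-step traces
are structurally unobservable and have no category.

Sampling
--------
``gibbs_sample`` alternates two exact conditional draws:

1. latent tallies: for each observed ``w``, assign the ``n_w`` traces to
   ``s in {w..3}`` with probability proportional to ``q_s * eta[s, w]``
   (a multinomial draw per step category);
2. ``q ~ Dirichlet(alpha + latent tallies)`` — conjugate update.

No tuning parameters are needed.  ``exact_posterior_grid`` integrates the same
posterior over a barycentric lattice on the simplex and serves as an
independent brute-force check of the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .maturation import OligomerDistribution, eta_matrix, observed_marginal

__all__ = [
    "StepCountData",
    "InferenceConfig",
    "PosteriorResult",
    "gibbs_sample",
    "exact_posterior_grid",
    "posterior_predictive_check",
]


@dataclass(frozen=True)
class StepCountData:
    """Per-condition tally of accepted traces by observed step count.

    ``n1``/``n2`` count one- and two-step traces; ``n3`` counts traces with
    three **or more** steps (binned as higher-order oligomers).  There is no
    zero-step category: such traces are never observed.
    """

    n1: int
    n2: int
    n3: int

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3

    def as_array(self) -> np.ndarray:
        return np.array([self.n1, self.n2, self.n3], dtype=np.int64)

    def fractions(self) -> np.ndarray:
        """Empirical step fractions; uniform for an empty tally."""
        if self.total == 0:
            return np.full(3, 1.0 / 3.0)
        return self.as_array() / self.total


@dataclass(frozen=True)
class InferenceConfig:
    r: float = 0.7
    prior_alpha: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_iterations: int = 20_000
    n_burn_in: int = 5_000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.prior_alpha) != 3 or any(a <= 0 for a in self.prior_alpha):
            raise ValueError(f"prior_alpha must be three positive values, got {self.prior_alpha}")
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")
        if not (0 <= self.n_burn_in < self.n_iterations):
            raise ValueError("n_burn_in must satisfy 0 <= n_burn_in < n_iterations")
        if self.thin <= 0:
            raise ValueError("thin must be positive")
        object.__setattr__(self, "prior_alpha", tuple(float(a) for a in self.prior_alpha))


@dataclass
class PosteriorResult:
    """Retained posterior draws of q with summary statistics."""

    samples: np.ndarray  # (n_retained, 3)
    mean_q: np.ndarray
    sd_q: np.ndarray
    ess: np.ndarray
    config: InferenceConfig
    data: StepCountData

    def to_dict(self) -> dict:
        """JSON-serializable report (samples excluded; write those as TSV)."""
        return {
            "counts": {"n1": self.data.n1, "n2": self.data.n2, "n3": self.data.n3},
            "config": asdict(self.config),
            "mean_q": [float(x) for x in self.mean_q],
            "sd_q": [float(x) for x in self.sd_q],
            "ess": [float(x) for x in self.ess],
            "n_samples": int(self.samples.shape[0]),
        }

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """Central credible interval per component, shape (3, 2)."""
        lo = (1.0 - level) / 2.0
        return np.quantile(self.samples, [lo, 1.0 - lo], axis=0).T


def _effective_sample_size(samples: np.ndarray) -> np.ndarray:
    """Per-component ESS via arviz (bulk ESS)."""
    import arviz as az

    ess = np.empty(samples.shape[1])
    for j in range(samples.shape[1]):
        ess[j] = float(az.ess(np.asarray(samples[:, j])[None, :]))
    return ess


def gibbs_sample(data: StepCountData, config: InferenceConfig) -> PosteriorResult:
    """Draw from the posterior p(q | step counts) by two-block Gibbs sampling.

    Deterministic given ``config.seed`` (a counter-based Philox generator).
    With an empty tally the chain samples the prior.
    """
    eta = eta_matrix(config.r)
    alpha = np.asarray(config.prior_alpha, dtype=float)
    counts = data.as_array()
    rng = np.random.Generator(np.random.Philox(np.uint64(config.seed)))

    # For a trace with w steps, the latent s ranges over s >= w only
    # (eta[s, w] = 0 for s < w); precompute the eta column per category.
    eta_cols = [eta[1:, w] for w in (1, 2, 3)]  # each length-3 over s=1..3

    q = rng.dirichlet(alpha)
    n_retained = (config.n_iterations - config.n_burn_in) // config.thin
    samples = np.empty((n_retained, 3))
    k = 0
    for it in range(config.n_iterations):
        tally = np.zeros(3)
        for w_idx in range(3):
            n_w = counts[w_idx]
            if n_w == 0:
                continue
            p = q * eta_cols[w_idx]
            p /= p.sum()
            tally += rng.multinomial(n_w, p)
        q = rng.dirichlet(alpha + tally)
        if it >= config.n_burn_in and (it - config.n_burn_in) % config.thin == 0:
            samples[k] = q
            k += 1
    samples = samples[:k]

    return PosteriorResult(
        samples=samples,
        mean_q=samples.mean(axis=0),
        sd_q=samples.std(axis=0, ddof=1),
        ess=_effective_sample_size(samples),
        config=config,
        data=data,
    )


def exact_posterior_grid(
    data: StepCountData,
    r: float,
    prior_alpha: tuple[float, float, float] = (1.0, 1.0, 1.0),
    resolution: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and SD of q by quadrature on a simplex lattice.

    Evaluates the unnormalized log posterior
    ``sum_w n_w log(sum_s q_s eta[s, w]) + sum_s (alpha_s - 1) log q_s``
    with an equal-weight midpoint rule: the simplex is triangulated into
    ``resolution^2`` congruent cells and the density is evaluated at each
    cell centroid (no boundary points, O(1/resolution^2) error).
    Independent of the Gibbs code path.
    """
    if resolution < 100:
        raise ValueError(f"resolution must be >= 100, got {resolution}")
    alpha = np.asarray(prior_alpha, dtype=float)
    eta = eta_matrix(r)
    counts = data.as_array()

    def _centroids(total: int, offset: float) -> np.ndarray:
        i, j = np.meshgrid(np.arange(total + 1), np.arange(total + 1), indexing="ij")
        mask = i + j <= total
        i, j = i[mask], j[mask]
        k = total - i - j
        return (np.stack([i, j, k], axis=1) + offset) / resolution

    # upward cells have barycentric centroids (i+1/3)/R, downward (i+2/3)/R
    q = np.concatenate(
        [_centroids(resolution - 1, 1.0 / 3.0), _centroids(resolution - 2, 2.0 / 3.0)]
    )

    logpost = np.where(
        (q > 0) | (alpha == 1.0), (alpha - 1.0) * np.log(np.where(q > 0, q, 1.0)), -np.inf
    ).sum(axis=1)
    pw = q @ eta[1:, 1:]  # (M, 3) marginal step probabilities
    for w_idx in range(3):  # only observed categories constrain the posterior
        if counts[w_idx] > 0:
            col = pw[:, w_idx]
            logpost = logpost + np.where(
                col > 0, counts[w_idx] * np.log(np.where(col > 0, col, 1.0)), -np.inf
            )

    logpost -= logpost.max()
    wgt = np.exp(logpost)
    wgt /= wgt.sum()
    mean = wgt @ q
    var = wgt @ (q - mean) ** 2
    return mean, np.sqrt(var)


def posterior_predictive_check(result: PosteriorResult, data: StepCountData) -> dict:
    """Compare posterior-predicted step fractions with the empirical ones.

    Averages the observed-step marginal P(w | q, r) over the retained
    posterior draws; the maximum absolute difference from the empirical
    fractions is a crude goodness-of-fit summary.
    """
    r = result.config.r
    eta = eta_matrix(r)
    predicted = (result.samples @ eta[1:, 1:]).mean(axis=0)
    empirical = data.fractions()
    return {
        "predicted_fractions": predicted,
        "empirical_fractions": empirical,
        "max_abs_discrepancy": float(np.max(np.abs(predicted - empirical))),
    }
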