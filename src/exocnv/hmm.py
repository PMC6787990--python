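"""Three-state copy-number HMM over per-sample z-scored read depths.

States are DEL (deletion), DIP (diploid), DUP (duplication).  Emissions
are unit-variance normals on the z-score scale with means ``-M``, ``0``,
``+M``.  Transitions attenuate with the genomic distance ``d`` between
consecutive targets::

    T(d) = f * T0 + (1 - f) * Pi,     f = exp(-d / D)

where ``T0`` is the zero-distance transition matrix built from the CNV
start probability ``p`` and exit probability ``q = 1 / mean length``, and
``Pi`` has every row equal to the stationary-prior row ``(p, 1-2p, p)``.
A chromosome change uses ``f = 0`` so state carries no information across
it.

Decoding uses the Viterbi algorithm in natural-log space; likelihoods and
posteriors use the scaled forward/backward recursions (per-step
renormalization) so that chains hundreds of targets long never underflow
in double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import TargetInterval, inter_target_distances

__all__ = [
    "DEL",
    "DIP",
    "DUP",
    "HMMParameters",
    "StatePath",
    "transition_matrix",
    "emission_logdensity",
    "viterbi",
    "forward_backward_scaled",
    "constrained_loglikelihood",
    "phred",
]

DEL, DIP, DUP = 0, 1, 2
STATE_NAMES = ("DEL", "DIP", "DUP")
_LOG_2PI = math.log(2.0 * math.pi)


class HMMError(ValueError):
    pass


@dataclass(frozen=True)
class HMMParameters:
    """XHMM-protocol HMM constants.

    Attributes
    ----------
    cnv_start_probability : float
        Per-target probability ``p`` of entering DEL (or DUP) from DIP;
        default 1e-8.
    mean_targets_per_cnv : float
        Expected CNV length in targets; the exit probability is
        ``q = 1 / mean_targets_per_cnv`` (default 6 targets).
    distance_scale_bp : float
        Attenuation scale ``D`` in bp for the distance-dependent
        transition mixture (default 70 kb).
    emission_shift : float
        Emission mean offset ``M`` in z-units for DEL/DUP (default 3).
    min_some_quality : int
        Phred Q_SOME threshold for reporting a call (default 30).
    distance_mode : str
        ``'midpoint'`` (default) or ``'gap'`` inter-target distance.
    """

    cnv_start_probability: float = 1e-8
    mean_targets_per_cnv: float = 6.0
    distance_scale_bp: float = 70_000.0
    emission_shift: float = 3.0
    min_some_quality: int = 30
    distance_mode: str = "midpoint"

    def __post_init__(self) -> None:
        if not 0.0 < self.cnv_start_probability < 0.5:
            raise HMMError("cnv_start_probability must be in (0, 0.5)")
        if self.mean_targets_per_cnv < 1.0:
            raise HMMError("mean_targets_per_cnv must be >= 1")
        if self.distance_scale_bp <= 0:
            raise HMMError("distance_scale_bp must be positive")
        if self.emission_shift <= 0:
            raise HMMError("emission_shift must be positive")
        if not 0 <= self.min_some_quality <= 99:
            raise HMMError("min_some_quality must be in [0, 99]")
        if self.distance_mode not in ("midpoint", "gap"):
            raise HMMError(f"unknown distance_mode {self.distance_mode!r}")

    @property
    def exit_probability(self) -> float:
        return 1.0 / self.mean_targets_per_cnv

    @property
    def initial_distribution(self) -> np.ndarray:
        p = self.cnv_start_probability
        return np.array([p, 1.0 - 2.0 * p, p])

    @property
    def emission_means(self) -> np.ndarray:
        return np.array([-self.emission_shift, 0.0, self.emission_shift])


@dataclass
class StatePath:
    """A Viterbi decoding: one state per target plus the joint log score."""

    states: np.ndarray  # int array over {DEL, DIP, DUP}
    log_probability: float

    def __len__(self) -> int:
        return len(self.states)


def transition_matrix(d: float, params: HMMParameters) -> np.ndarray:
    """Distance-``d`` transition matrix (rows/cols ordered DEL, DIP, DUP)."""
    if d < 0:
        raise HMMError(f"negative inter-target distance {d}")
    p = params.cnv_start_probability
    q = params.exit_probability
    f = 0.0 if math.isinf(d) else math.exp(-d / params.distance_scale_bp)
    T0 = np.array(
        [
            [1.0 - q, q, 0.0],
            [p, 1.0 - 2.0 * p, p],
            [0.0, q, 1.0 - q],
        ]
    )
    Pi = np.tile(params.initial_distribution, (3, 1))
    return f * T0 + (1.0 - f) * Pi


def emission_logdensity(
    z: float | np.ndarray, state: int, params: HMMParameters
) -> float | np.ndarray:
    """Log density of z under the state's unit-variance normal emission."""
    mu = params.emission_means[state]
    return -0.5 * (np.asarray(z, dtype=np.float64) - mu) ** 2 - 0.5 * _LOG_2PI


def _emission_logmatrix(z_row: np.ndarray, params: HMMParameters) -> np.ndarray:
    """T x 3 log emission densities."""
    z = np.asarray(z_row, dtype=np.float64)[:, None]
    mu = params.emission_means[None, :]
    return -0.5 * (z - mu) ** 2 - 0.5 * _LOG_2PI


def _transition_logmatrices(
    targets: Sequence[TargetInterval], params: HMMParameters
) -> np.ndarray:
    """(T-1) x 3 x 3 log transition matrices for consecutive target pairs."""
    ds = inter_target_distances(targets, mode=params.distance_mode)
    out = np.empty((len(ds), 3, 3))
    for i, d in enumerate(ds):
        out[i] = np.log(transition_matrix(d, params))
    return out


def _check_chain(z_row: np.ndarray, targets: Sequence[TargetInterval]) -> np.ndarray:
    z = np.asarray(z_row, dtype=np.float64)
    if z.ndim != 1 or len(z) != len(targets):
        raise HMMError(
            f"z-score row of length {z.size} does not match {len(targets)} targets"
        )
    if len(targets) == 0:
        raise HMMError("empty target list")
    if not np.all(np.isfinite(z)):
        raise HMMError("non-finite z-score in chain")
    return z


def viterbi(
    z_row: np.ndarray, targets: Sequence[TargetInterval], params: HMMParameters
) -> StatePath:
    """Most probable state path, computed entirely in log space."""
    z = _check_chain(z_row, targets)
    T = len(z)
    log_emit = _emission_logmatrix(z, params)
    log_trans = _transition_logmatrices(targets, params)
    log_pi = np.log(params.initial_distribution)

    delta = log_pi + log_emit[0]
    back = np.zeros((T, 3), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, None] + log_trans[t - 1]  # prev x cur
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(3)] + log_emit[t]
    states = np.empty(T, dtype=np.intp)
    states[-1] = int(np.argmax(delta))
    log_prob = float(delta[states[-1]])
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return StatePath(states=states, log_probability=log_prob)


@dataclass
class ForwardBackwardResult:
    """Scaled forward/backward variables for one sample's chain.

    ``alpha_hat[t]`` sums to 1; ``scales[t]`` is the per-step
    normalization constant, so ``log_likelihood = sum(log(scales))``.
    ``gamma[t]`` are per-target state posteriors (each row sums to 1).
    """

    alpha_hat: np.ndarray  # T x 3
    beta_hat: np.ndarray  # T x 3
    scales: np.ndarray  # T
    log_likelihood: float
    gamma: np.ndarray  # T x 3


def forward_backward_scaled(
    z_row: np.ndarray, targets: Sequence[TargetInterval], params: HMMParameters
) -> ForwardBackwardResult:
    """Scaled forward/backward recursions (per-step renormalization)."""
    z = _check_chain(z_row, targets)
    T = len(z)
    emit = np.exp(_emission_logmatrix(z, params))
    trans = np.exp(_transition_logmatrices(targets, params))
    pi = params.initial_distribution

    alpha_hat = np.empty((T, 3))
    scales = np.empty(T)
    a = pi * emit[0]
    scales[0] = a.sum()
    if scales[0] == 0.0:
        raise HMMError("forward scaling factor underflowed to zero at target 0")
    alpha_hat[0] = a / scales[0]
    for t in range(1, T):
        a = (alpha_hat[t - 1] @ trans[t - 1]) * emit[t]
        scales[t] = a.sum()
        if scales[t] == 0.0:
            raise HMMError(f"forward scaling factor underflowed at target {t}")
        alpha_hat[t] = a / scales[t]

    beta_hat = np.empty((T, 3))
    beta_hat[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta_hat[t] = (trans[t] * emit[t + 1][None, :]) @ beta_hat[t + 1]
        beta_hat[t] /= scales[t + 1]

    gamma = alpha_hat * beta_hat
    gamma /= gamma.sum(axis=1, keepdims=True)
    return ForwardBackwardResult(
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        scales=scales,
        log_likelihood=float(np.log(scales).sum()),
        gamma=gamma,
    )


def constrained_loglikelihood(
    z_row: np.ndarray,
    targets: Sequence[TargetInterval],
    params: HMMParameters,
    allowed: np.ndarray,
) -> float:
    """Log joint probability of the data restricted to allowed states.

    ``allowed`` is a T x 3 boolean mask; disallowed states contribute zero
    probability at that target.  Computed with the same scaled forward
    recursion as the unconstrained likelihood, so the ratio
    ``exp(constrained - unconstrained)`` is a well-conditioned posterior
    probability of the path event.  Returns ``-inf`` when no path is
    allowed.
    """
    z = _check_chain(z_row, targets)
    allowed = np.asarray(allowed, dtype=bool)
    if allowed.shape != (len(z), 3):
        raise HMMError("allowed-state mask must be T x 3")
    emit = np.exp(_emission_logmatrix(z, params))
    trans = np.exp(_transition_logmatrices(targets, params))
    a = params.initial_distribution * emit[0] * allowed[0]
    log_lik = 0.0
    scale = a.sum()
    if scale == 0.0:
        return float("-inf")
    a /= scale
    log_lik += math.log(scale)
    for t in range(1, len(z)):
        a = (a @ trans[t - 1]) * emit[t] * allowed[t]
        scale = a.sum()
        if scale == 0.0:
            return float("-inf")
        a /= scale
        log_lik += math.log(scale)
    return log_lik


def phred(probability: float) -> int:
    """Phred-scale an event probability: ``round(-10*log10(1 - P))``.

    Rounds half up and clamps to [0, 99] (XHMM-style integer qualities).
    """
    if probability >= 1.0:
        return 99
    if probability <= 0.0:
        return 0
    score = -10.0 * math.log10(1.0 - probability)
    return int(min(99, max(0, math.floor(score + 0.5))))
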