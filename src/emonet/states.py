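"""Probable emotional states: the stationary distribution of intensity.

Intensity is the fraction of active components, so with ``n`` components it
takes the ``n + 1`` values ``k/n``.  Under Glauber dynamics at constant
external field the component states are distributed according to the
Boltzmann distribution

    P(s) ∝ exp(beta * (Σ_{i<j} w_ij s_i s_j + Σ_i (tau_i + field) s_i)),

so the distribution of intensity can be computed exactly by enumerating all
``2^n`` states (small n) or estimated by long Monte-Carlo sampling.  Both
routes are provided and must agree; the sampled route exists for networks
too large to enumerate and as a cross-check of the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .network import ComponentNetwork, InvalidParameterError, convert_coding

__all__ = [
    "IntensityDistribution",
    "ShapeStatistics",
    "CapacityError",
    "enumerate_spin_states",
    "state_log_weights",
    "exact_distribution",
    "exact_state_distribution",
    "sampled_distribution",
    "shape_statistics",
    "total_variation",
]

#: hard cap on exact enumeration (2^20 ≈ 1e6 states); emotion networks are ~10 nodes
ENUMERATION_LIMIT = 20


class CapacityError(ValueError):
    """Exact enumeration requested for a network too large to enumerate."""


@dataclass(frozen=True)
class IntensityDistribution:
    """Distribution of emotion intensity over its ``n + 1`` levels ``k/n``."""

    n: int
    probs: np.ndarray  # probs[k] = P(intensity = k/n)
    method: str  # "exact" | "sampled"
    beta: float
    field: float = 0.0

    def __post_init__(self) -> None:
        p = np.array(self.probs, dtype=float)
        if p.shape != (self.n + 1,):
            raise InvalidParameterError("probs must have length n + 1")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-10:
            raise InvalidParameterError("probs must be a probability vector")
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    @property
    def levels(self) -> np.ndarray:
        """Intensity values ``k/n`` for ``k = 0..n``."""
        return np.arange(self.n + 1) / self.n

    def expected_intensity(self) -> float:
        return float(self.levels @ self.probs)


@dataclass(frozen=True)
class ShapeStatistics:
    """Shape summary of an intensity distribution.

    ``low_mass``/``high_mass``/``mid_mass`` are the probabilities of
    intensity ≤ 0.2, ≥ 0.8 and within [0.4, 0.6].  The bimodality flag marks
    the connectivity signature (mass piled at both extremes); negative
    skewness with dominant high mass marks the high-threshold signature
    (many high-intensity states with a skewed tail of low ones).
    """

    bimodality_flag: bool
    skewness: float
    low_mass: float
    high_mass: float
    mid_mass: float
    degenerate: bool = False


def enumerate_spin_states(n: int) -> np.ndarray:
    """All ``2^n`` spin configurations as a ``(2^n, n)`` −1/+1 int8 array."""
    if n > ENUMERATION_LIMIT:
        raise CapacityError(
            f"n = {n} exceeds the enumeration limit of {ENUMERATION_LIMIT}; "
            "use sampled_distribution instead"
        )
    codes = np.arange(2 ** n, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(n)) & 1
    return (2 * bits - 1).astype(np.int8)


def state_log_weights(
    net: ComponentNetwork, beta: float = 1.0, field: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized log-Boltzmann weight and active count for every state.

    Returns ``(log_w, k)`` over all ``2^n`` spin states; normalization is
    left to the caller (log-sum-exp) so high beta or strong fields cannot
    overflow.
    """
    net = convert_coding(net, "spin")
    n = net.n
    s = enumerate_spin_states(n).astype(float)
    w, tau = net.weights, net.thresholds
    # chunk the pairwise term to keep memory flat for n near the limit
    log_w = np.empty(s.shape[0])
    chunk = 1 << 15
    for start in range(0, s.shape[0], chunk):
        sc = s[start : start + chunk]
        pair = 0.5 * np.einsum("si,si->s", sc @ w, sc)
        log_w[start : start + chunk] = beta * (pair + sc @ (tau + field))
    k = ((s > 0).sum(axis=1)).astype(np.int64)
    return log_w, k


def exact_state_distribution(
    net: ComponentNetwork, beta: float = 1.0, field: float = 0.0
) -> np.ndarray:
    """Exact probability of each of the ``2^n`` spin states."""
    log_w, _ = state_log_weights(net, beta, field)
    return np.exp(log_w - logsumexp(log_w))


def exact_distribution(
    net: ComponentNetwork, beta: float = 1.0, field: float = 0.0
) -> IntensityDistribution:
    """Exact stationary distribution of intensity by full enumeration."""
    if beta <= 0 or not np.isfinite(beta):
        raise InvalidParameterError("beta must be positive and finite")
    log_w, k = state_log_weights(net, beta, field)
    p = np.exp(log_w - logsumexp(log_w))
    probs = np.bincount(k, weights=p, minlength=net.n + 1)
    probs = probs / probs.sum()  # remove residual rounding
    return IntensityDistribution(net.n, probs, method="exact", beta=beta, field=field)


def sampled_distribution(
    net: ComponentNetwork,
    config=None,
    field: float = 0.0,
    sweeps: int = 50_000,
    thin: int = 10,
    burn_in: int = 1_000,
) -> IntensityDistribution:
    """Monte-Carlo estimate of the intensity distribution via Glauber sampling.

    Runs a single long chain at constant ``field``, discards ``burn_in``
    sweeps, and tabulates intensity every ``thin``-th sweep.  Agrees with
    :func:`exact_distribution` up to sampling error.
    """
    from .dynamics import SimulationConfig, run_constant_field_chain

    if config is None:
        config = SimulationConfig()
    if thin < 1 or sweeps < thin:
        raise InvalidParameterError("need sweeps >= thin >= 1")
    states = run_constant_field_chain(
        net, sweeps=sweeps, field=field, config=config, burn_in=burn_in
    )
    k = (states[::thin] > 0).sum(axis=1)
    counts = np.bincount(k, minlength=net.n + 1).astype(float)
    return IntensityDistribution(
        net.n, counts / counts.sum(), method="sampled", beta=config.beta, field=field
    )


def shape_statistics(dist: IntensityDistribution) -> ShapeStatistics:
    """Low/mid/high mass, bimodality flag and skewness of an intensity distribution."""
    x = dist.levels
    p = dist.probs
    eps = 1e-12
    low = float(p[x <= 0.2 + eps].sum())
    high = float(p[x >= 0.8 - eps].sum())
    mid = float(p[(x >= 0.4 - eps) & (x <= 0.6 + eps)].sum())
    mu = float(x @ p)
    var = float(((x - mu) ** 2) @ p)
    degenerate = var < 1e-12
    skew = 0.0 if degenerate else float((((x - mu) ** 3) @ p) / var ** 1.5)
    return ShapeStatistics(
        bimodality_flag=bool(low > mid and high > mid),
        skewness=skew,
        low_mass=low,
        high_mass=high,
        mid_mass=mid,
        degenerate=degenerate,
    )


def total_variation(p: IntensityDistribution, q: IntensityDistribution) -> float:
    """Total-variation distance between two intensity distributions."""
    if p.n != q.n:
        raise InvalidParameterError("distributions have different n")
    return 0.5 * float(np.abs(p.probs - q.probs).sum())
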