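"""Stochastic network dynamics under a fading external event.

The simulation follows single-component (asynchronous) Glauber dynamics:
one time unit — a *sweep* — consists of ``n`` single-component updates, each
resampling one component from its conditional activation probability

    P(s_i = +1 | rest) = 1 / (1 + exp(−2 β (Σ_j w_ij s_j + τ_i + e(t)))),

where ``e(t)`` is a uniform external field representing the emotion-eliciting
event: zero at baseline, raised to ``amplitude`` while the event holds, then
fading back to zero.  At constant field the chain satisfies detailed balance
with respect to the Boltzmann distribution of the network, which is what
makes exact enumeration (``states`` module) a usable oracle for the sampler.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so ensembles are bit-reproducible
and replicate runs are statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import ComponentNetwork, CommonCauseModel, InvalidParameterError, \
    convert_coding, star_network

__all__ = [
    "EventSchedule",
    "SimulationConfig",
    "TrajectoryEnsemble",
    "InvalidScheduleError",
    "conditional_activation_probability",
    "sweep",
    "simulate",
    "simulate_common_cause",
    "run_constant_field_chain",
]

UPDATE_ORDERS = ("random_sequential", "fixed_cycle")
FADE_SHAPES = ("linear", "exponential")


class InvalidScheduleError(ValueError):
    """An event schedule with no recordable sweeps or inconsistent counts."""


def intensity_of(state: np.ndarray) -> float:
    """Emotion intensity of one spin state: the fraction of active components.

    With ten components of which seven are active the intensity is exactly
    0.7.
    """
    state = np.asarray(state)
    return float((state > 0).mean())


@dataclass(frozen=True)
class EventSchedule:
    """Time course of the external event field, in sweeps.

    The field is 0 for ``baseline_sweeps``, jumps to ``amplitude`` for
    ``hold_sweeps``, decays to 0 over ``fade_sweeps`` (linearly by default,
    exponentially with time constant ``fade_sweeps / 5`` otherwise), and
    stays 0 for ``post_sweeps``.
    """

    baseline_sweeps: int = 100
    amplitude: float = 2.0
    hold_sweeps: int = 20
    fade_sweeps: int = 50
    fade_shape: str = "linear"
    post_sweeps: int = 800

    def __post_init__(self) -> None:
        for name in ("baseline_sweeps", "hold_sweeps", "fade_sweeps", "post_sweeps"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InvalidScheduleError(f"{name} must be a non-negative integer, got {v!r}")
        if not np.isfinite(self.amplitude):
            raise InvalidScheduleError("amplitude must be finite")
        if self.fade_shape not in FADE_SHAPES:
            raise InvalidScheduleError(
                f"unknown fade_shape {self.fade_shape!r}; expected one of {FADE_SHAPES}"
            )
        if self.total_sweeps == 0:
            raise InvalidScheduleError("schedule has zero total sweeps")

    @property
    def total_sweeps(self) -> int:
        return (self.baseline_sweeps + self.hold_sweeps
                + self.fade_sweeps + self.post_sweeps)

    @property
    def onset(self) -> int:
        """First sweep of the event (start of the hold phase)."""
        return self.baseline_sweeps

    @property
    def fade_end(self) -> int:
        """First sweep at which the field has returned to zero."""
        return self.baseline_sweeps + self.hold_sweeps + self.fade_sweeps

    def field_profile(self) -> np.ndarray:
        """The field value ``e(t)`` for every recorded sweep."""
        e = np.zeros(self.total_sweeps)
        a, b = self.baseline_sweeps, self.baseline_sweeps + self.hold_sweeps
        e[a:b] = self.amplitude
        f = self.fade_sweeps
        if f > 0:
            i = np.arange(f)
            if self.fade_shape == "linear":
                e[b : b + f] = self.amplitude * (1.0 - (i + 1) / f)
            else:
                e[b : b + f] = self.amplitude * np.exp(-(i + 1) / (f / 5.0))
        return e


@dataclass(frozen=True)
class SimulationConfig:
    """Sampler settings: inverse temperature, replicate count, seed, update order."""

    beta: float = 1.0
    runs: int = 100
    seed: int = 0
    update_order: str = "random_sequential"
    burn_in: int = 100  # equilibration sweeps at zero field, not recorded

    def __post_init__(self) -> None:
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise InvalidParameterError("beta must be positive and finite")
        if self.runs < 1:
            raise InvalidParameterError("runs must be >= 1")
        if self.burn_in < 0:
            raise InvalidParameterError("burn_in must be >= 0")
        if self.update_order not in UPDATE_ORDERS:
            raise InvalidParameterError(
                f"unknown update_order {self.update_order!r}; expected one of {UPDATE_ORDERS}"
            )


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Replicate trajectories of component states and emotion intensity.

    ``states`` is ``runs x sweeps x n_nodes`` of ±1 spins (may be ``None``
    when an ensemble is reconstructed from an intensity-only CSV);
    ``intensity[r, t]`` is the fraction of active *components* at sweep
    ``t`` of run ``r`` (for a star-embedded common-cause model the latent
    cause node is excluded).
    """

    intensity: np.ndarray
    field: np.ndarray
    schedule: EventSchedule
    config: SimulationConfig
    states: np.ndarray | None = None
    intensity_labels: tuple[str, ...] | None = None

    @property
    def runs(self) -> int:
        return self.intensity.shape[0]

    @property
    def sweeps(self) -> int:
        return self.intensity.shape[1]


@njit(cache=True)
def _glauber_chain(w, tau, beta, field, s0, order, unif):  # pragma: no cover - jit
    T, n = order.shape
    out = np.empty((T, n), np.int8)
    s = s0.copy()
    for t in range(T):
        f = field[t]
        for k in range(n):
            i = order[t, k]
            h = tau[i] + f
            for j in range(n):
                h += w[i, j] * s[j]
            p = 1.0 / (1.0 + np.exp(-2.0 * beta * h))
            s[i] = 1.0 if unif[t, k] < p else -1.0
        for j in range(n):
            out[t, j] = 1 if s[j] > 0.0 else -1
    return out


def conditional_activation_probability(
    net: ComponentNetwork,
    state: np.ndarray,
    i: int,
    field: float = 0.0,
    beta: float = 1.0,
) -> float:
    """P(component ``i`` active | all other components), the Glauber rule."""
    net = convert_coding(net, "spin")
    state = np.asarray(state, dtype=float)
    if state.shape != (net.n,) or not np.all(np.abs(state) == 1.0):
        raise InvalidParameterError("state must be a length-n vector of -1/+1")
    if not 0 <= i < net.n:
        raise InvalidParameterError(f"component index {i} out of range")
    h = float(net.weights[i] @ state) + float(net.thresholds[i]) + float(field)
    return float(1.0 / (1.0 + np.exp(-2.0 * beta * h)))


def sweep(
    net: ComponentNetwork,
    state: np.ndarray,
    field: float,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One time unit: ``n`` single-component Glauber updates; returns a new state."""
    net = convert_coding(net, "spin")
    n = net.n
    s = np.asarray(state, dtype=float).copy()
    if config.update_order == "random_sequential":
        order = rng.permutation(n)
    else:
        order = np.arange(n)
    u = rng.random(n)
    for k in range(n):
        i = int(order[k])
        h = float(net.weights[i] @ s) + float(net.thresholds[i]) + float(field)
        p = 1.0 / (1.0 + np.exp(-2.0 * config.beta * h))
        s[i] = 1.0 if u[k] < p else -1.0
    return s


def _run_one(w, tau, beta, field_full, update_order, rng):
    T, n = field_full.shape[0], w.shape[0]
    if update_order == "random_sequential":
        # sequential scan in a fresh random order each sweep: every component
        # is updated exactly once per time unit
        order = rng.permuted(
            np.broadcast_to(np.arange(n, dtype=np.int64), (T, n)), axis=1
        )
    else:
        order = np.broadcast_to(np.arange(n, dtype=np.int64), (T, n)).copy()
    unif = rng.random((T, n))
    # start at rest (all components inactive) and equilibrate at zero field:
    # the pre-event state of an emotion network is the resting basin, not a
    # random draw that could seed the high-intensity basin of a bistable net
    s0 = np.full(n, -1.0)
    return _glauber_chain(w, tau, beta, field_full, s0, order, unif)


def simulate(
    net: ComponentNetwork,
    schedule: EventSchedule,
    config: SimulationConfig,
    intensity_nodes: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Simulate replicate runs of the network through an event schedule.

    Each run starts from a random state, equilibrates for ``config.burn_in``
    sweeps at zero field (not recorded), then experiences the event field.
    Per-run seeds are spawned from ``config.seed`` so results are
    bit-reproducible and runs are independent.

    ``intensity_nodes`` restricts the intensity computation to a subset of
    nodes (used by the common-cause comparator to exclude the latent cause).
    """
    net = convert_coding(net, "spin")
    field_rec = schedule.field_profile()
    T_rec = field_rec.shape[0]
    field_full = np.concatenate([np.zeros(config.burn_in), field_rec])
    w = np.ascontiguousarray(net.weights)
    tau = np.ascontiguousarray(net.thresholds)
    n = net.n
    states = np.empty((config.runs, T_rec, n), np.int8)
    children = np.random.SeedSequence(config.seed).spawn(config.runs)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        traj = _run_one(w, tau, config.beta, field_full, config.update_order, rng)
        states[r] = traj[config.burn_in :]
    if intensity_nodes is None:
        nodes = np.arange(n)
    else:
        nodes = np.asarray(intensity_nodes, dtype=int)
    intensity = (states[:, :, nodes] > 0).mean(axis=2)
    labels = tuple(net.labels[i] for i in nodes)
    return TrajectoryEnsemble(
        intensity=intensity,
        field=field_rec,
        schedule=schedule,
        config=config,
        states=states,
        intensity_labels=labels,
    )


def simulate_common_cause(
    model: CommonCauseModel,
    schedule: EventSchedule,
    config: SimulationConfig,
) -> TrajectoryEnsemble:
    """Simulate the common-cause comparator via its star-network embedding.

    The event field drives every node, including the latent cause; reported
    intensity is the mean activity of the ``n`` components only.
    """
    net = star_network(model)
    return simulate(net, schedule, config, intensity_nodes=np.arange(model.n))


def run_constant_field_chain(
    net: ComponentNetwork,
    sweeps: int,
    field: float,
    config: SimulationConfig,
    burn_in: int | None = None,
) -> np.ndarray:
    """One long chain at constant field; returns ``sweeps x n`` spin states.

    Used for stationary sampling (probable states, cross-sectional draws for
    large n); ``burn_in`` defaults to ``config.burn_in``.
    """
    net = convert_coding(net, "spin")
    if burn_in is None:
        burn_in = config.burn_in
    T = burn_in + sweeps
    field_full = np.full(T, float(field))
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    traj = _run_one(
        np.ascontiguousarray(net.weights),
        np.ascontiguousarray(net.thresholds),
        config.beta,
        field_full,
        config.update_order,
        rng,
    )
    return traj[burn_in:]
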