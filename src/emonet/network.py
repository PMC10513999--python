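"""Emotion-component networks: data model, manipulations, and parametrizations.

An emotion episode is modelled as a set of binary components (appraisals,
feelings, motivations, physiological changes, expressions) that exert direct
pairwise causal effects on each other.  The model is a pairwise Markov random
field (an Ising model): a symmetric weight matrix holds the coupling
strengths ("connectivity") and a per-component threshold holds the state each
component tends to be in absent input.

Two parametrizations of the same family are supported:

* ``spin`` — component states are −1 (inactive) / +1 (active).  This is the
  canonical internal coding: with positive couplings, inactive neighbours
  actively suppress activation, which is what lets a densely connected
  network hold its components "in check" at rest.
* ``binary`` — states are 0/1.  Nodewise logistic-regression estimates live
  naturally in this coding.

:func:`convert_coding` maps exactly between the two, preserving the full
state distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ComponentNetwork",
    "CommonCauseModel",
    "NetworkValidationError",
    "InvalidParameterError",
    "scale_connectivity",
    "shift_thresholds",
    "convert_coding",
    "build_common_cause",
    "star_network",
]

#: tolerance for the symmetry invariant of the weight matrix
SYMMETRY_ATOL = 1e-12

CODINGS = ("spin", "binary")


class NetworkValidationError(ValueError):
    """A network or model violates a structural invariant."""


class InvalidParameterError(ValueError):
    """An operation was called with an out-of-range parameter."""


def _readonly(a: np.ndarray) -> np.ndarray:
    a = np.array(a, dtype=float)
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class ComponentNetwork:
    """A symmetric pairwise network over binary emotion components.

    Parameters
    ----------
    labels
        Component names, unique, length ``n``.
    weights
        ``n x n`` symmetric coupling matrix with zero diagonal.  Entry
        ``w[i, j]`` is the strength of the causal relationship between
        components ``i`` and ``j`` (negative values allowed).
    thresholds
        Length-``n`` vector; ``thresholds[i]`` is the external field on
        component ``i`` — the disposition of the component to be active.
    coding
        ``"spin"`` if the parameters are expressed for −1/+1 states,
        ``"binary"`` for 0/1 states.
    """

    labels: tuple[str, ...]
    weights: np.ndarray
    thresholds: np.ndarray
    coding: str = "spin"

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        w = np.array(self.weights, dtype=float)
        tau = np.array(self.thresholds, dtype=float)
        n = len(labels)
        if n < 1:
            raise NetworkValidationError("network must have at least one component")
        if len(set(labels)) != n:
            raise NetworkValidationError("labels are not unique")
        if w.shape != (n, n):
            raise NetworkValidationError(
                f"weights must be {n}x{n}, got shape {w.shape}"
            )
        if tau.shape != (n,):
            raise NetworkValidationError(
                f"thresholds must have length {n}, got shape {tau.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise NetworkValidationError("weights contain non-finite entries")
        if not np.all(np.isfinite(tau)):
            raise NetworkValidationError("thresholds contain non-finite entries")
        asym = np.abs(w - w.T).max() if n > 1 else 0.0
        if asym > SYMMETRY_ATOL:
            i, j = np.unravel_index(np.abs(w - w.T).argmax(), w.shape)
            raise NetworkValidationError(
                f"weights not symmetric: |w[{i}][{j}] - w[{j}][{i}]| = {asym:g}"
            )
        if np.abs(np.diag(w)).max() > 0:
            raise NetworkValidationError("weight matrix diagonal must be zero")
        if self.coding not in CODINGS:
            raise NetworkValidationError(
                f"unknown coding {self.coding!r}; expected one of {CODINGS}"
            )
        object.__setattr__(self, "weights", _readonly(w))
        object.__setattr__(self, "thresholds", _readonly(tau))

    @property
    def n(self) -> int:
        """Number of components."""
        return len(self.labels)

    def mean_abs_weight(self) -> float:
        """Mean absolute off-diagonal weight (a simple connectivity index)."""
        n = self.n
        if n < 2:
            return 0.0
        iu = np.triu_indices(n, k=1)
        return float(np.abs(self.weights[iu]).mean())


@dataclass(frozen=True)
class CommonCauseModel:
    """Comparator architecture: one latent cause drives every component.

    The components share no direct connections; each is tied only to the
    common cause with strength ``loadings[i]``.  This is the affect-program
    alternative to the component network: once external activation vanishes,
    components cannot reactivate each other, so the episode cannot outlive
    the event by much.
    """

    labels: tuple[str, ...]
    loadings: np.ndarray
    thresholds: np.ndarray
    cause_threshold: float
    cause_label: str = "cause"

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        lo = np.array(self.loadings, dtype=float)
        tau = np.array(self.thresholds, dtype=float)
        n = len(labels)
        if lo.shape != (n,) or tau.shape != (n,):
            raise InvalidParameterError(
                "loadings and thresholds must match the number of labels"
            )
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(tau))
                and np.isfinite(self.cause_threshold)):
            raise NetworkValidationError("common-cause model has non-finite entries")
        if self.cause_label in labels:
            raise NetworkValidationError("cause_label collides with a component label")
        object.__setattr__(self, "loadings", _readonly(lo))
        object.__setattr__(self, "thresholds", _readonly(tau))

    @property
    def n(self) -> int:
        """Number of components (excluding the cause node)."""
        return len(self.labels)


def scale_connectivity(net: ComponentNetwork, factor: float) -> ComponentNetwork:
    """Multiply every pairwise weight by ``factor``; thresholds unchanged.

    This is the connectivity manipulation: ``factor > 1`` strengthens all
    causal relationships proportionally, ``factor = 0`` disconnects the
    network entirely.
    """
    factor = float(factor)
    if not np.isfinite(factor) or factor < 0:
        raise InvalidParameterError(f"connectivity factor must be finite and >= 0, got {factor}")
    return replace(net, weights=net.weights * factor)


def shift_thresholds(net: ComponentNetwork, constant: float) -> ComponentNetwork:
    """Add ``constant`` to every component threshold; weights unchanged.

    This is the threshold manipulation: a positive constant makes every
    component more disposed to be active.
    """
    constant = float(constant)
    if not np.isfinite(constant):
        raise InvalidParameterError(f"threshold shift must be finite, got {constant}")
    return replace(net, thresholds=net.thresholds + constant)


def convert_coding(net: ComponentNetwork, target: str) -> ComponentNetwork:
    """Re-express the network in the ``target`` parametrization.

    The binary (0/1) and spin (−1/+1) codings describe the same family of
    distributions; substituting ``x = (s + 1)/2`` in the binary energy gives

    ``w_spin = w_bin / 4``,
    ``tau_spin_i = tau_bin_i / 2 + (sum_j w_bin_ij) / 4``,

    up to a state-independent constant that cancels in normalization.  The
    map is an exact involution and leaves the full ``2^n`` state distribution
    (after relabelling states) unchanged.
    """
    if target not in CODINGS:
        raise InvalidParameterError(f"unknown coding {target!r}; expected one of {CODINGS}")
    if net.coding == target:
        return net
    w, tau = net.weights, net.thresholds
    if net.coding == "binary":  # binary -> spin
        w_new = w / 4.0
        tau_new = tau / 2.0 + w.sum(axis=1) / 4.0
    else:  # spin -> binary
        w_new = 4.0 * w
        tau_new = 2.0 * tau - 2.0 * w.sum(axis=1)
    return ComponentNetwork(net.labels, w_new, tau_new, coding=target)


def build_common_cause(
    labels: Sequence[str],
    loadings: Sequence[float],
    thresholds: Sequence[float],
    cause_threshold: float,
) -> CommonCauseModel:
    """Construct a common-cause model (no component–component couplings)."""
    return CommonCauseModel(
        labels=tuple(labels),
        loadings=np.asarray(loadings, dtype=float),
        thresholds=np.asarray(thresholds, dtype=float),
        cause_threshold=float(cause_threshold),
    )


def star_network(model: CommonCauseModel) -> ComponentNetwork:
    """Embed a common-cause model as an (n+1)-node star :class:`ComponentNetwork`.

    Components occupy indices ``0..n-1``; the cause node is appended last.
    The only nonzero weights connect the cause to each component, so every
    component–component coupling is exactly zero by construction.
    """
    n = model.n
    w = np.zeros((n + 1, n + 1))
    w[:n, n] = model.loadings
    w[n, :n] = model.loadings
    tau = np.concatenate([model.thresholds, [model.cause_threshold]])
    labels = model.labels + (model.cause_label,)
    return ComponentNetwork(labels, w, tau, coding="spin")
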