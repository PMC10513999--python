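"""Network estimation from cross-sectional binary data.

Implements the standard nodewise regularized approach for binary
psychological networks (eLasso): each component is regressed on all others
with ℓ1-penalized logistic regression over a penalty grid, the penalty is
selected per node by the extended Bayesian information criterion (EBIC), and
an undirected edge is kept under the AND rule — both directed coefficients
must survive — with the edge weight set to their mean.  Intercepts become
the node thresholds.  Because logistic coefficients of 0/1 predictors are
the Ising parameters of the 0/1 parametrization, results are reported in
binary coding; :func:`emonet.network.convert_coding` maps them to spin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.exceptions import ConvergenceWarning
import warnings

from .network import ComponentNetwork, InvalidParameterError
from .synthesis import BinaryDataMatrix

__all__ = [
    "EstimationResult",
    "DegenerateColumnError",
    "binarize",
    "estimate_network",
]

#: coefficient magnitude beyond which a nodewise fit is flagged as (near-)separable
_SEPARABILITY_COEF = 15.0


class DegenerateColumnError(ValueError):
    """A rating column is constant and cannot be dichotomized or regressed."""


@dataclass(frozen=True)
class EstimationResult:
    """Nodewise estimation output.

    ``network`` is in binary (0/1) coding.  ``penalties`` holds the
    EBIC-selected ℓ1 penalty per node, ``ebic`` the corresponding criterion
    value, ``sparsity`` the fraction of absent edges, and
    ``separability_flags`` marks nodes whose fit hit the penalty floor or
    produced runaway coefficients (perfectly predictable columns).
    """

    network: ComponentNetwork
    penalties: np.ndarray
    ebic: np.ndarray
    sparsity: float
    separability_flags: np.ndarray
    gamma: float
    rule: str = "and"


def binarize(
    ratings,
    rule: str = "median_split",
    cut: float | None = None,
    labels=None,
) -> BinaryDataMatrix:
    """Dichotomize an ordinal rating matrix column by column.

    ``median_split`` activates entries strictly above the column median
    (ties at the median go to 0); ``fixed_cut`` activates entries strictly
    above ``cut``.  Columns that come out constant are rejected by name —
    a component that never (or always) switches carries no information for
    nodewise regression.
    """
    try:
        cols = list(ratings.columns)
        values = ratings.to_numpy(dtype=float)
    except AttributeError:
        values = np.asarray(ratings, dtype=float)
        cols = None
    if labels is None:
        labels = cols if cols is not None else [f"c{i}" for i in range(values.shape[1])]
    if values.ndim != 2:
        raise InvalidParameterError("ratings must be a 2-D matrix")
    if not np.all(np.isfinite(values)):
        raise InvalidParameterError("ratings contain non-finite entries")
    if rule == "median_split":
        cuts = np.median(values, axis=0)
    elif rule == "fixed_cut":
        if cut is None or not np.isfinite(cut):
            raise InvalidParameterError("fixed_cut requires a finite cut value")
        cuts = np.full(values.shape[1], float(cut))
    else:
        raise InvalidParameterError(f"unknown binarization rule {rule!r}")
    binary = (values > cuts).astype(np.int8)
    for j in range(binary.shape[1]):
        if binary[:, j].min() == binary[:, j].max():
            raise DegenerateColumnError(
                f"column {labels[j]!r} is constant after dichotomization"
            )
    return BinaryDataMatrix(binary, labels)


def _lambda_grid(x_others: np.ndarray, y: np.ndarray, n_lambdas: int,
                 min_ratio: float) -> np.ndarray:
    n_obs = y.shape[0]
    lam_max = np.abs(x_others.T @ (y - y.mean())).max() / n_obs
    lam_max = max(lam_max, 1e-4)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def _fit_node(
    x_others: np.ndarray,
    y: np.ndarray,
    gamma: float,
    n_lambdas: int,
    min_ratio: float,
) -> tuple[np.ndarray, float, float, float, bool]:
    """EBIC-selected ℓ1 logistic fit of one node on the others.

    Returns (coefficients, intercept, selected penalty, selected EBIC,
    separability flag).
    """
    n_obs, n_pred = x_others.shape
    if y.min() == y.max():
        # constant node: no regression possible; empty neighbourhood
        p = y.mean()
        intercept = 30.0 if p > 0.5 else -30.0
        return np.zeros(n_pred), intercept, np.nan, np.nan, True
    lambdas = _lambda_grid(x_others, y, n_lambdas, min_ratio)
    best = None
    flagged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for lam in lambdas:
            clf = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / (n_obs * lam),
                solver="liblinear",
                intercept_scaling=100.0,
                tol=1e-7,
                max_iter=2000,
            )
            clf.fit(x_others, y)
            coef = clf.coef_.ravel()
            intercept = float(clf.intercept_[0])
            eta = x_others @ coef + intercept
            # numerically safe Bernoulli log-likelihood
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            df = int(np.count_nonzero(coef))
            ebic = -2.0 * ll + df * np.log(n_obs) + 2.0 * gamma * df * np.log(max(n_pred, 1))
            if np.max(np.abs(coef), initial=0.0) > _SEPARABILITY_COEF:
                flagged = True
            if best is None or ebic < best[0]:
                best = (ebic, lam, coef, intercept)
    ebic, lam, coef, intercept = best
    if lam == lambdas[-1]:
        flagged = True  # ran into the penalty floor
    return coef, intercept, float(lam), float(ebic), flagged


def estimate_network(
    data: BinaryDataMatrix,
    gamma: float = 0.25,
    rule: str = "and",
    n_lambdas: int = 50,
    lambda_min_ratio: float = 1e-3,
) -> EstimationResult:
    """Estimate a component network from cross-sectional 0/1 data (eLasso).

    Per node: ℓ1-penalized logistic regression on all other columns over a
    ``n_lambdas``-point geometric penalty grid from the node's maximal
    penalty down by ``lambda_min_ratio``, selected by EBIC with parameter
    ``gamma`` (0.25 by default; larger values are more conservative).
    Edges are symmetrized by the AND rule (``rule="or"`` keeps an edge when
    either coefficient is nonzero); weights are coefficient means, node
    thresholds are the selected intercepts.  The returned network is in
    binary coding.
    """
    if rule not in ("and", "or"):
        raise InvalidParameterError(f"unknown symmetrization rule {rule!r}")
    if not (0 <= gamma):
        raise InvalidParameterError("gamma must be >= 0")
    x = data.values.astype(float)
    n_obs, n = x.shape
    if n < 2:
        raise InvalidParameterError("estimation needs at least two components")
    if n_obs <= n:
        warnings.warn(
            f"only {n_obs} observations for {n} components; estimates will be unstable",
            stacklevel=2,
        )
    beta_dir = np.zeros((n, n))  # beta_dir[i, j]: coefficient of j in node i's fit
    intercepts = np.zeros(n)
    penalties = np.full(n, np.nan)
    ebics = np.full(n, np.nan)
    flags = np.zeros(n, dtype=bool)
    others_idx = [np.delete(np.arange(n), i) for i in range(n)]
    for i in range(n):
        coef, b0, lam, ebic, flagged = _fit_node(
            x[:, others_idx[i]], x[:, i], gamma, n_lambdas, lambda_min_ratio
        )
        beta_dir[i, others_idx[i]] = coef
        intercepts[i] = b0
        penalties[i] = lam
        ebics[i] = ebic
        flags[i] = flagged
    if rule == "and":
        keep = (beta_dir != 0) & (beta_dir.T != 0)
    else:
        keep = (beta_dir != 0) | (beta_dir.T != 0)
    weights = np.where(keep, 0.5 * (beta_dir + beta_dir.T), 0.0)
    weights = 0.5 * (weights + weights.T)  # exact symmetry
    np.fill_diagonal(weights, 0.0)
    iu = np.triu_indices(n, k=1)
    sparsity = float(np.mean(weights[iu] == 0.0)) if n > 1 else 1.0
    net = ComponentNetwork(data.labels, weights, intercepts, coding="binary")
    return EstimationResult(
        network=net,
        penalties=penalties,
        ebic=ebics,
        sparsity=sparsity,
        separability_flags=flags,
        gamma=gamma,
        rule=rule,
    )
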