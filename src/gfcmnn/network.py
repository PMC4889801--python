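"""General fuzzy cerebellar-model neural network (GFCMNN).

The network is a CMAC-style associative memory whose association space is
organized as ``n_j`` layers of ``n_k`` blocks per input dimension.  Each
(layer, block) pair carries one Gaussian receptive-field membership function
per input variable; the product of the per-input memberships forms the
activation ``r_jk`` of one fuzzy rule (hypercube), and the ``o``-th category
output is the weighted sum

    O_o = sum_j sum_k w_jko * r_jk.

Training is online gradient descent on the squared-error cost
``E = 1/2 sum_o (d_o - O_o)^2`` with separate learning rates for weights,
means, and variances.  A Lyapunov argument bounds the admissible rate for
each parameter family by ``2 / ||P||^2``, where ``P`` is the gradient factor
``dO_o/dz``; the variance-normalized optimal rate ``1 / ||P||^2`` gives the
fastest single-step error contraction.  Both fixed-rate and adaptive
(optimal-rate) modes are provided.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateGradientError,
    DimensionError,
    DivergenceError,
    InvalidParamsError,
)

__all__ = [
    "NetworkShape",
    "NetworkParams",
    "TrainConfig",
    "TrainTrace",
    "init_params",
    "membership",
    "receptive_field",
    "forward",
    "cost",
    "gradient_factors",
    "update_step",
    "rate_bound",
    "optimal_rate",
    "delta_lyapunov",
    "train",
    "one_hot_targets",
    "save_model",
    "load_model",
]

#: Epoch-total cost above which training is aborted as divergent.
DIVERGENCE_GUARD = 1e6

#: Variances are clamped below at this fraction of the input range width
#: after every update, so the Gaussian widths cannot collapse to zero.
VARIANCE_FLOOR_FRAC = 1e-3


@dataclass(frozen=True)
class NetworkShape:
    """Dimensions of the network.

    ``n_i`` inputs, ``n_j`` layers per input, ``n_k`` blocks per layer,
    ``n_o`` output categories.  ``n_e`` is the nominal quantization
    resolution of each input variable; with randomly placed receptive
    fields it only sets bookkeeping defaults (range-widening epsilon).
    """

    n_i: int
    n_j: int
    n_k: int
    n_o: int
    n_e: int = 5

    def __post_init__(self):
        for name in ("n_i", "n_j", "n_k", "n_o", "n_e"):
            if getattr(self, name) < 1:
                raise InvalidParamsError(f"{name} must be >= 1")

    @property
    def n_rules(self) -> int:
        """Number of fuzzy rules / hypercubes, n_j * n_k."""
        return self.n_j * self.n_k


@dataclass
class NetworkParams:
    """Trainable parameters: Gaussian means/variances and output weights.

    ``means`` and ``variances`` are indexed (input i, layer j, block k);
    ``weights`` is indexed (layer j, block k, output o).  ``variances`` holds
    the width parameter v of exp(-(I - m)^2 / v^2) and must stay positive.
    """

    shape: NetworkShape
    means: np.ndarray  # (n_i, n_j, n_k)
    variances: np.ndarray  # (n_i, n_j, n_k)
    weights: np.ndarray  # (n_j, n_k, n_o)
    input_low: np.ndarray = None  # (n_i,), receptive-field placement range
    input_high: np.ndarray = None

    def __post_init__(self):
        s = self.shape
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.means.shape != (s.n_i, s.n_j, s.n_k):
            raise DimensionError(
                f"means shape {self.means.shape} != {(s.n_i, s.n_j, s.n_k)}"
            )
        if self.variances.shape != self.means.shape:
            raise DimensionError("variances shape differs from means shape")
        if self.weights.shape != (s.n_j, s.n_k, s.n_o):
            raise DimensionError(
                f"weights shape {self.weights.shape} != {(s.n_j, s.n_k, s.n_o)}"
            )
        if not np.all(self.variances > 0):
            raise InvalidParamsError("all variances must be strictly positive")

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            shape=self.shape,
            means=self.means.copy(),
            variances=self.variances.copy(),
            weights=self.weights.copy(),
            input_low=None if self.input_low is None else self.input_low.copy(),
            input_high=None if self.input_high is None else self.input_high.copy(),
        )


@dataclass
class TrainConfig:
    """Learning-rate, initialization, and stopping configuration.

    With ``adaptive`` off, the fixed rates ``eta_w``, ``eta_m``, ``eta_v``
    are used (default 0.1 each).  With ``adaptive`` on, each parameter
    family instead uses the optimal rate 1/||P||^2 recomputed per sample.
    """

    eta_w: float = 0.1
    eta_m: float = 0.1
    eta_v: float = 0.1
    adaptive: bool = False
    max_epochs: int = 2000
    cost_tol: float = 1e-3
    seed: int = 0
    init_weight_scale: float = 0.5
    variance_range: tuple[float, float] = (0.3, 0.7)

    def __post_init__(self):
        if not self.adaptive:
            if min(self.eta_w, self.eta_m, self.eta_v) < 0:
                raise InvalidParamsError("learning rates must be nonnegative")
        if self.max_epochs < 1:
            raise InvalidParamsError("max_epochs must be >= 1")
        lo, hi = self.variance_range
        if not (0 < lo <= hi):
            raise InvalidParamsError("variance_range must satisfy 0 < low <= high")
        if self.init_weight_scale <= 0:
            raise InvalidParamsError("init_weight_scale must be positive")
        if self.cost_tol < 0:
            raise InvalidParamsError("cost_tol must be nonnegative")


@dataclass
class TrainTrace:
    """Per-epoch summed cost history and the stopping outcome."""

    costs: list[float] = field(default_factory=list)
    epochs_run: int = 0
    converged: bool = False


def init_params(
    shape: NetworkShape,
    input_low,
    input_high,
    cfg: TrainConfig,
) -> NetworkParams:
    """Randomly initialize means, variances, and weights.

    Means are uniform over each input's observed range; variances uniform in
    ``cfg.variance_range`` scaled by the range width; weights uniform in
    ``[-init_weight_scale, +init_weight_scale]``.  A degenerate (zero-width)
    range is widened by ``1 / n_e`` on each side.  Fully determined by
    ``cfg.seed``.
    """
    low = np.broadcast_to(np.asarray(input_low, dtype=float), (shape.n_i,)).copy()
    high = np.broadcast_to(np.asarray(input_high, dtype=float), (shape.n_i,)).copy()
    if np.any(high < low):
        raise InvalidParamsError("input_high must be >= input_low elementwise")
    eps = 1.0 / shape.n_e
    degenerate = (high - low) <= 0
    low[degenerate] -= eps
    high[degenerate] += eps

    rng = np.random.default_rng(cfg.seed)
    width = (high - low)[:, None, None]  # (n_i, 1, 1)
    means = low[:, None, None] + width * rng.random(
        (shape.n_i, shape.n_j, shape.n_k)
    )
    v_lo, v_hi = cfg.variance_range
    variances = width * (
        v_lo + (v_hi - v_lo) * rng.random((shape.n_i, shape.n_j, shape.n_k))
    )
    s = cfg.init_weight_scale
    weights = rng.uniform(-s, s, size=(shape.n_j, shape.n_k, shape.n_o))
    return NetworkParams(
        shape=shape,
        means=means,
        variances=variances,
        weights=weights,
        input_low=low,
        input_high=high,
    )


def membership(I_i: float, m: float, v: float) -> float:
    """Gaussian receptive-field membership exp(-(I - m)^2 / v^2), in (0, 1]."""
    if v <= 0:
        raise InvalidParamsError(f"variance must be positive, got {v}")
    return math.exp(-((I_i - m) ** 2) / v**2)


def _check_input(I, params: NetworkParams) -> np.ndarray:
    I = np.asarray(I, dtype=float)
    if I.shape != (params.shape.n_i,):
        raise DimensionError(
            f"input length {I.shape} != ({params.shape.n_i},)"
        )
    return I


def receptive_field(I, params: NetworkParams) -> np.ndarray:
    """Rule activations r_jk = prod_i exp(-(I_i - m_ijk)^2 / v_ijk^2).

    Returned as an (n_j, n_k) array; flatten in C order for the layer-major
    rule vector (r_11 .. r_1nk, r_21 .. ).
    """
    I = _check_input(I, params)
    diff = I[:, None, None] - params.means
    return np.exp(-np.sum(diff**2 / params.variances**2, axis=0))


def forward(I, params: NetworkParams) -> np.ndarray:
    """Category outputs O_o = sum_jk w_jko r_jk, as an (n_o,) vector."""
    r = receptive_field(I, params)
    return np.einsum("jk,jko->o", r, params.weights)


def cost(d, O) -> float:
    """Squared-error cost 1/2 sum_o (d_o - O_o)^2."""
    d = np.asarray(d, dtype=float)
    O = np.asarray(O, dtype=float)
    if d.shape != O.shape:
        raise DimensionError(f"target shape {d.shape} != output shape {O.shape}")
    return 0.5 * float(np.sum((d - O) ** 2))


def gradient_factors(
    I, params: NetworkParams, o: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradient factors P_z = dO_o/dz for the o-th output (o is 1-based).

    Returns ``(P_w, P_m, P_v)``: P_w is (n_j, n_k) and equals the rule
    activations; P_m and P_v are (n_i, n_j, n_k) with

        dO_o/dm_ijk = w_jko * r_jk * 2 (I_i - m_ijk) / v_ijk^2
        dO_o/dv_ijk = w_jko * r_jk * 2 (I_i - m_ijk)^2 / v_ijk^3
    """
    I = _check_input(I, params)
    s = params.shape
    if not (1 <= o <= s.n_o):
        raise DimensionError(f"output index {o} outside 1..{s.n_o}")
    r = receptive_field(I, params)
    w_o = params.weights[:, :, o - 1]  # (n_j, n_k)
    diff = I[:, None, None] - params.means
    wr = (w_o * r)[None, :, :]
    P_m = wr * 2.0 * diff / params.variances**2
    P_v = wr * 2.0 * diff**2 / params.variances**3
    return r, P_m, P_v


def rate_bound(P) -> float:
    """Stability bound 2 / ||P||^2 on the learning rate for factor P."""
    sq = float(np.sum(np.asarray(P, dtype=float) ** 2))
    if sq == 0.0:
        raise DegenerateGradientError("zero-norm gradient factor")
    return 2.0 / sq

def optimal_rate(P) -> float:
    """Fastest-convergence rate 1 / ||P||^2 (half the stability bound)."""
    return rate_bound(P) / 2.0


def delta_lyapunov(e: float, eta: float, P) -> float:
    """Single-step change of the Lyapunov function V = e^2 / 2.

    Equals ``1/2 * eta * e^2 * ||P||^2 * (eta ||P||^2 - 2)``: negative for
    every rate inside the open stability interval (0, 2/||P||^2), zero at
    its endpoints, and minimized at the optimal rate where it equals
    ``-e^2/2`` (the error is annihilated in one step).
    """
    sq = float(np.sum(np.asarray(P, dtype=float) ** 2))
    return 0.5 * eta * e**2 * sq * (eta * sq - 2.0)


def update_step(I, d, params: NetworkParams, cfg: TrainConfig) -> NetworkParams:
    """One online gradient step on sample (I, d); returns new parameters.

    Update laws (all deltas from the pre-update parameters, applied
    simultaneously)::

        dw_jko = eta_w * e_o * r_jk
        dm_ijk = 2 eta_m * sum_o e_o w_jko r_jk (I_i - m_ijk) / v_ijk^2
        dv_ijk = 2 eta_v * sum_o e_o w_jko r_jk (I_i - m_ijk)^2 / v_ijk^3

    In adaptive mode each family's rate is the optimal rate 1/||P||^2 of its
    stacked gradient factor (a zero-norm factor skips that family's update).
    Updated variances are clamped below at a floor proportional to the input
    range width so the Gaussians cannot degenerate.
    """
    I = _check_input(I, params)
    d = np.asarray(d, dtype=float)
    s = params.shape
    if d.shape != (s.n_o,):
        raise DimensionError(f"target length {d.shape} != ({s.n_o},)")

    r = receptive_field(I, params)  # (n_j, n_k)
    O = np.einsum("jk,jko->o", r, params.weights)
    e = d - O  # (n_o,)

    diff = I[:, None, None] - params.means  # (n_i, n_j, n_k)
    v = params.variances
    # Output-summed error-weighted rule responsibilities.
    ew = np.einsum("jko,o->jk", params.weights, e)  # sum_o e_o w_jko
    grad_m = 2.0 * (ew * r)[None, :, :] * diff / v**2
    grad_v = 2.0 * (ew * r)[None, :, :] * diff**2 / v**3

    if cfg.adaptive:
        # P_w = r for every output; P_m / P_v stacked over outputs.
        sq_w = float(np.sum(r**2))
        eta_w = 1.0 / sq_w if sq_w > 0 else 0.0
        wr = (params.weights * r[:, :, None])  # (n_j, n_k, n_o)
        base_m = 2.0 * diff[:, :, :, None] / v[:, :, :, None] ** 2
        base_v = 2.0 * diff[:, :, :, None] ** 2 / v[:, :, :, None] ** 3
        sq_m = float(np.sum((wr[None] * base_m) ** 2))
        sq_v = float(np.sum((wr[None] * base_v) ** 2))
        eta_m = 1.0 / sq_m if sq_m > 0 else 0.0
        eta_v = 1.0 / sq_v if sq_v > 0 else 0.0
    else:
        eta_w, eta_m, eta_v = cfg.eta_w, cfg.eta_m, cfg.eta_v

    new_w = params.weights + eta_w * r[:, :, None] * e[None, None, :]
    new_m = params.means + eta_m * grad_m
    new_v = v + eta_v * grad_v

    if params.input_low is not None and params.input_high is not None:
        width = (params.input_high - params.input_low)[:, None, None]
        floor = VARIANCE_FLOOR_FRAC * np.maximum(width, 1e-12)
    else:
        floor = VARIANCE_FLOOR_FRAC
    new_v = np.maximum(new_v, floor)

    out = params.copy()
    out.weights = new_w
    out.means = new_m
    out.variances = new_v
    return out


def one_hot_targets(labels, n_o: int) -> np.ndarray:
    """One-hot target matrix: row s has 1 at column label_s - 1."""
    labels = np.asarray(labels, dtype=int)
    if np.any(labels < 1) or np.any(labels > n_o):
        raise DimensionError(f"labels must lie in 1..{n_o}")
    D = np.zeros((labels.size, n_o))
    D[np.arange(labels.size), labels - 1] = 1.0
    return D


def train(
    X,
    labels,
    shape: NetworkShape,
    cfg: TrainConfig,
    params: NetworkParams | None = None,
) -> tuple[NetworkParams, TrainTrace]:
    """Train the network online on a sample matrix with 1-based labels.

    Samples are presented in dataset order each epoch with one
    :func:`update_step` per sample.  The per-epoch cost is the sum of the
    pre-update sample costs; training stops when it falls below
    ``cfg.cost_tol`` or after ``cfg.max_epochs`` epochs.  If ``params`` is
    omitted they are initialized from the observed per-feature input range.
    Reproducible from ``cfg.seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 1:
        raise DimensionError("need at least one training sample")
    if X.shape[1] != shape.n_i:
        raise DimensionError(
            f"X has {X.shape[1]} features, network expects {shape.n_i}"
        )
    D = one_hot_targets(labels, shape.n_o)
    if D.shape[0] != X.shape[0]:
        raise DimensionError("labels length differs from number of samples")

    if params is None:
        params = init_params(shape, X.min(axis=0), X.max(axis=0), cfg)

    trace = TrainTrace()
    for epoch in range(1, cfg.max_epochs + 1):
        epoch_cost = 0.0
        for s_idx in range(X.shape[0]):
            I = X[s_idx]
            d = D[s_idx]
            O = forward(I, params)
            epoch_cost += cost(d, O)
            params = update_step(I, d, params, cfg)
        trace.costs.append(epoch_cost)
        trace.epochs_run = epoch
        if not math.isfinite(epoch_cost) or epoch_cost > DIVERGENCE_GUARD:
            raise DivergenceError(epoch, epoch_cost)
        if epoch_cost < cfg.cost_tol:
            trace.converged = True
            break
    return params, trace


# ---------------------------------------------------------------------------
# Serialization

def save_model(params: NetworkParams, path, extra: dict | None = None) -> None:
    """Write a model to JSON; arrays are stored in layer-major order."""
    s = params.shape
    doc = {
        "shape": {"n_i": s.n_i, "n_j": s.n_j, "n_k": s.n_k, "n_o": s.n_o,
                  "n_e": s.n_e},
        "means": params.means.tolist(),
        "variances": params.variances.tolist(),
        "weights": params.weights.tolist(),
        "input_low": None if params.input_low is None else params.input_low.tolist(),
        "input_high": None if params.input_high is None else params.input_high.tolist(),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc) + "\n", encoding="utf-8")


def load_model(path) -> tuple[NetworkParams, dict]:
    """Read a model written by :func:`save_model`; returns (params, extras)."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    shape = NetworkShape(**doc["shape"])
    params = NetworkParams(
        shape=shape,
        means=np.array(doc["means"]),
        variances=np.array(doc["variances"]),
        weights=np.array(doc["weights"]),
        input_low=None if doc.get("input_low") is None else np.array(doc["input_low"]),
        input_high=None if doc.get("input_high") is None else np.array(doc["input_high"]),
    )
    known = {"shape", "means", "variances", "weights", "input_low", "input_high"}
    extras = {k: v for k, v in doc.items() if k not in known}
    return params, extras
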