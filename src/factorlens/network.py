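"""Equation-learner network: linear stages interleaved with operator units.

Each layer computes ``g = W x + b`` and then applies its operator units:
unary units consume one linear output, binary units two consecutive outputs.
A final linear read-out maps the last layer's unit outputs to the prediction.
Training minimizes the squared residual plus a smoothed-L1/2 sparsity penalty
(``l12_star_penalty``) on every weight and bias, so that after pruning at a
coefficient threshold the surviving structure can be read off as a closed-form
formula.

Backpropagation and the Adam optimizer are implemented directly on numpy
arrays; the network is small (tens of units), so the matrix work per epoch is
a handful of dense products.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .operators import BINARY, UNARY, OperatorSet, arity
from .triplets import TripletDataset


GRAD_CLIP = 10.0


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


# ---------------------------------------------------------------------------
# penalty

def l12_star_penalty(w, a: float):
    """Smoothed L1/2 regularizer.

    Equals ``|w|**0.5`` for ``|w| >= a`` and the smooth quartic surrogate
    ``|-(w^4)/(8 a^3) + 3 w^2 / (4 a) + 3 a / 8|**0.5`` below, which removes
    the singular gradient at zero while agreeing with the square-root norm at
    the boundary ``|w| = a``.
    """
    if a <= 0:
        raise ValueError("smoothing constant a must be positive")
    w = np.asarray(w, dtype=float)
    absw = np.abs(w)
    inner = np.abs(-(w ** 4) / (8 * a ** 3) + 3 * w ** 2 / (4 * a) + 3 * a / 8)
    return np.where(absw >= a, np.sqrt(absw), np.sqrt(inner))


def l12_star_grad(w, a: float):
    """Derivative of :func:`l12_star_penalty` with respect to w."""
    if a <= 0:
        raise ValueError("smoothing constant a must be positive")
    w = np.asarray(w, dtype=float)
    absw = np.abs(w)
    outer_grad = np.sign(w) * 0.5 / np.sqrt(np.maximum(absw, a))
    inner = -(w ** 4) / (8 * a ** 3) + 3 * w ** 2 / (4 * a) + 3 * a / 8
    inner_grad = (-(w ** 3) / (2 * a ** 3) + 3 * w / (2 * a)) / (2 * np.sqrt(np.abs(inner)))
    return np.where(absw >= a, outer_grad, inner_grad)


# ---------------------------------------------------------------------------
# layers and network

@dataclass
class EqlLayer:
    """One linear stage plus its fixed unit-to-operator assignment."""

    W: np.ndarray                 # (n_g, n_in)
    b: np.ndarray                 # (n_g,)
    units: Tuple[str, ...]        # operator name per unit, fixed at construction

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.units = tuple(self.units)
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[0],):
            raise ValueError("inconsistent layer weight/bias shapes")
        if self.n_g != self.W.shape[0]:
            raise ValueError(
                f"sum of operator arities ({self.n_g}) must equal the number "
                f"of linear outputs ({self.W.shape[0]})")
        # runs of identical operators, applied slice-wise for speed
        segments = []
        hs = gs = 0
        for name in self.units:
            if segments and segments[-1][0] == name:
                segments[-1][2] += 1
            else:
                segments.append([name, hs, 0, gs])
            hs += 1
            gs += arity(name)
            segments[-1][2] = hs - segments[-1][1]
        self._segments = [(name, h0, h0 + k, g0, g0 + k * arity(name))
                          for name, h0, k, g0 in segments]

    @property
    def n_h(self) -> int:
        return len(self.units)

    @property
    def n_g(self) -> int:
        return sum(arity(u) for u in self.units)

    @property
    def n_in(self) -> int:
        return self.W.shape[1]

    def forward(self, x: np.ndarray):
        """Return (h, cache) where h is (N, n_h)."""
        g = x @ self.W.T + self.b
        h = np.empty((g.shape[0], self.n_h))
        for name, h0, h1, g0, g1 in self._segments:
            if name in UNARY:
                h[:, h0:h1] = UNARY[name][0](g[:, g0:g1])
            else:
                h[:, h0:h1] = BINARY[name][0](g[:, g0:g1:2], g[:, g0 + 1:g1:2])
        return h, (x, g)

    def backward(self, dh: np.ndarray, cache):
        """Given dL/dh, return (dL/dx, dL/dW, dL/db)."""
        x, g = cache
        dg = np.empty_like(g)
        for name, h0, h1, g0, g1 in self._segments:
            if name in UNARY:
                dg[:, g0:g1] = dh[:, h0:h1] * UNARY[name][1](g[:, g0:g1])
            else:
                da_fn, db_fn = BINARY[name][1]
                a_cols, b_cols = g[:, g0:g1:2], g[:, g0 + 1:g1:2]
                dg[:, g0:g1:2] = dh[:, h0:h1] * da_fn(a_cols, b_cols)
                dg[:, g0 + 1:g1:2] = dh[:, h0:h1] * db_fn(a_cols, b_cols)
        dW = dg.T @ x
        db = dg.sum(axis=0)
        dx = dg @ self.W
        return dx, dW, db


@dataclass
class EqlNetwork:
    """Stack of :class:`EqlLayer` plus a linear read-out.

    Hyperparameters carried by the network: the coefficient threshold
    ``theta`` used for pruning/extraction and the penalty smoothing constant
    ``a``.
    """

    layers: List[EqlLayer]
    w_out: np.ndarray             # (n_h_last,)
    b_out: np.ndarray             # shape (1,)
    operator_set: OperatorSet
    theta: float = 0.01
    a: float = 0.01
    # affine output map applied after the read-out; training sets it to the
    # target standardization so pruning thresholds act on the trained scale
    y_mean: float = 0.0
    y_scale: float = 1.0

    def __post_init__(self):
        self.w_out = np.asarray(self.w_out, dtype=float).reshape(-1)
        self.b_out = np.asarray(self.b_out, dtype=float).reshape(1)
        if self.theta < 0:
            raise ValueError("coefficient threshold theta must be >= 0")
        if self.a <= 0:
            raise ValueError("smoothing constant a must be > 0")
        n_in = self.operator_set.n_inputs
        for li, layer in enumerate(self.layers):
            if layer.n_in != n_in:
                raise ValueError(f"layer {li} expects {layer.n_in} inputs, got {n_in}")
            n_in = layer.n_h
        if self.w_out.shape[0] != n_in:
            raise ValueError("read-out width does not match last layer")

    @property
    def n_inputs(self) -> int:
        return self.operator_set.n_inputs

    def parameters(self) -> List[np.ndarray]:
        params = []
        for layer in self.layers:
            params.extend([layer.W, layer.b])
        params.extend([self.w_out, self.b_out])
        return params

    def copy(self) -> "EqlNetwork":
        return EqlNetwork(
            layers=[EqlLayer(l.W.copy(), l.b.copy(), l.units) for l in self.layers],
            w_out=self.w_out.copy(), b_out=self.b_out.copy(),
            operator_set=self.operator_set, theta=self.theta, a=self.a,
            y_mean=self.y_mean, y_scale=self.y_scale)

    # -- forward / backward -------------------------------------------------

    def _coerce_features(self, data) -> np.ndarray:
        if isinstance(data, TripletDataset):
            x = data.features(self.operator_set.with_derivative)
        else:
            x = np.asarray(data, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected feature array with {self.n_inputs} columns, "
                f"got shape {x.shape}")
        return x

    def forward(self, data) -> np.ndarray:
        """Predictions for a TripletDataset or an (N, n_inputs) array."""
        x = self._coerce_features(data)
        for layer in self.layers:
            x, _ = layer.forward(x)
        return (x @ self.w_out + self.b_out[0]) * self.y_scale + self.y_mean

    predict = forward

    def _forward_cached(self, x: np.ndarray):
        caches = []
        for layer in self.layers:
            x, cache = layer.forward(x)
            caches.append((x, cache))
        yhat = x @ self.w_out + self.b_out[0]
        return yhat, caches

    def _backward(self, dyhat: np.ndarray, caches):
        """Gradients in the order of :meth:`parameters`."""
        h_last = caches[-1][0]
        dw_out = h_last.T @ dyhat
        db_out = np.array([dyhat.sum()])
        dh = np.outer(dyhat, self.w_out)
        grads = [None] * (2 * len(self.layers)) + [dw_out, db_out]
        for li in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[li]
            dh, dW, db = layer.backward(dh, caches[li][1])
            grads[2 * li] = dW
            grads[2 * li + 1] = db
        return grads

    def penalty(self) -> float:
        """Sum of the smoothed-L1/2 penalty over every weight and bias."""
        return float(sum(l12_star_penalty(p, self.a).sum() for p in self.parameters()))

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "operator_set": {
                "unary": list(self.operator_set.unary),
                "binary": list(self.operator_set.binary),
                "with_derivative": self.operator_set.with_derivative,
            },
            "theta": self.theta,
            "a": self.a,
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "layers": [
                {"W": l.W.tolist(), "b": l.b.tolist(), "units": list(l.units)}
                for l in self.layers
            ],
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EqlNetwork":
        ops = OperatorSet(tuple(d["operator_set"]["unary"]),
                          tuple(d["operator_set"]["binary"]),
                          d["operator_set"]["with_derivative"])
        layers = [EqlLayer(np.array(l["W"]), np.array(l["b"]), tuple(l["units"]))
                  for l in d["layers"]]
        return cls(layers=layers, w_out=np.array(d["w_out"]),
                   b_out=np.array(d["b_out"]), operator_set=ops,
                   theta=d["theta"], a=d["a"],
                   y_mean=d.get("y_mean", 0.0), y_scale=d.get("y_scale", 1.0))


# ---------------------------------------------------------------------------
# construction

DEFAULT_UNITS_PER_OP = {
    "identity": 2, "square": 2, "exp": 1, "sin": 3, "cos": 3, "relu": 1,
    "logabs": 1, "sum": 0, "difference": 0, "product": 2, "quotient": 1,
}


def build_network(operator_set: OperatorSet = OperatorSet(),
                  depth: int = 2,
                  units_per_op: Union[int, dict, None] = None,
                  theta: float = 0.01,
                  a: float = 0.01,
                  seed: int = 0,
                  init_scale: float = 0.4) -> EqlNetwork:
    """Build a reproducibly initialized equation-learner network.

    ``units_per_op`` is either a single count applied to every enabled
    operator or a mapping from operator name to count (defaults give a
    moderately over-complete layer).  Layer widths satisfy the arity-sum
    invariant: the linear stage of each layer has one output per unary unit
    and two per binary unit.  Weights are drawn N(0, init_scale^2/n_in) from
    ``seed``; trig units get a wider fan of initial frequencies so that
    oscillatory structure at several scales is reachable by gradient descent.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if units_per_op is None:
        counts = dict(DEFAULT_UNITS_PER_OP)
    elif isinstance(units_per_op, int):
        counts = {name: units_per_op for name in operator_set.names}
    else:
        counts = {name: 0 for name in operator_set.names}
        counts.update(units_per_op)
    units = []
    for name in operator_set.unary + operator_set.binary:
        units.extend([name] * counts.get(name, 0))
    if not units:
        raise ValueError("network has zero units; enable at least one operator")
    units = tuple(units)

    rng = np.random.default_rng(seed)
    layers = []
    n_in = operator_set.n_inputs
    for _ in range(depth):
        n_g = sum(arity(u) for u in units)
        W = rng.normal(0.0, init_scale / np.sqrt(n_in), size=(n_g, n_in))
        # spread initial frequencies of trig units across scales
        k = 0
        for name in units:
            ar = arity(name)
            if name in ("sin", "cos"):
                W[k:k + ar] *= rng.uniform(0.5, 4.0)
            k += ar
        b = rng.normal(0.0, 0.1, size=n_g)
        layers.append(EqlLayer(W, b, units))
        n_in = len(units)
    w_out = rng.normal(0.0, init_scale / np.sqrt(n_in), size=n_in)
    b_out = np.zeros(1)
    return EqlNetwork(layers=layers, w_out=w_out, b_out=b_out,
                      operator_set=operator_set, theta=theta, a=a)


# ---------------------------------------------------------------------------
# loss and training

def loss(y, yhat, network: Optional[EqlNetwork] = None, lam: float = 0.0) -> float:
    """Squared residual norm plus ``lam`` times the network penalty.

    With ``lam = 0`` (or no network) this is the plain squared Euclidean
    residual.
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    yhat = np.asarray(yhat, dtype=float).reshape(-1)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same length")
    fit = float(np.sum((y - yhat) ** 2))
    if lam and network is not None:
        fit += lam * network.penalty()
    return fit


@dataclass
class TrainConfig:
    """Training hyperparameters.

    The penalty weight follows a phased schedule: zero during the first
    ``warmup_frac`` of epochs (so structure can form before sparsification),
    the constant ``lam`` in the middle phase, and zero again during the final
    ``polish_frac`` of epochs, in which coefficients below the network's
    pruning threshold are frozen at zero and the survivors are fine-tuned.
    """

    epochs: int = 4000
    lr: float = 0.02
    lam: float = 1e-3
    warmup_frac: float = 0.25
    polish_frac: float = 0.1
    seed: int = 0
    train_frac: float = 0.8
    batch_size: Optional[int] = None
    standardize_y: bool = True
    dtype: str = "float32"   # optimization precision; parameters are
                             # returned in float64 either way

    def __post_init__(self):
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie strictly between 0 and 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _cast_network(network: EqlNetwork, dtype) -> None:
    for layer in network.layers:
        layer.W = layer.W.astype(dtype)
        layer.b = layer.b.astype(dtype)
    network.w_out = network.w_out.astype(dtype)
    network.b_out = network.b_out.astype(dtype)


def train(network: EqlNetwork, dataset, config: TrainConfig = TrainConfig()):
    """Gradient-based minimization of the penalized squared error.

    ``dataset`` is a TripletDataset (already restricted to the training split;
    splitting is the caller's responsibility) or a ``(X, y)`` pair.  The fit
    term is normalized by the number of samples during optimization so that
    the default penalty weight is dataset-size independent.  Returns
    ``(network, history)`` with one recorded loss per epoch; the network is
    modified in place.  Raises :class:`TrainingDivergence` on non-finite loss.
    """
    if isinstance(dataset, TripletDataset):
        X = network._coerce_features(dataset)
        y = dataset.y
    else:
        X, y = dataset
        X = network._coerce_features(X)
        y = np.asarray(y, dtype=float).reshape(-1)
    if len(y) != X.shape[0]:
        raise ValueError("feature/target length mismatch")

    network.y_mean, network.y_scale = 0.0, 1.0
    mu, sd = 0.0, 1.0
    if config.standardize_y:
        mu = float(np.mean(y))
        sd = float(np.std(y))
        if sd == 0.0:
            sd = 1.0
    z = (y - mu) / sd

    dtype = np.dtype(config.dtype)
    X = X.astype(dtype)
    z = z.astype(dtype)
    _cast_network(network, dtype)
    rng = np.random.default_rng(config.seed)
    params = network.parameters()
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n = len(z)

    warmup_end = int(config.warmup_frac * config.epochs)
    polish_start = int((1.0 - config.polish_frac) * config.epochs)
    freeze_masks = None
    history = []
    step = 0
    for epoch in range(config.epochs):
        lam_t = 0.0 if (epoch < warmup_end or epoch >= polish_start) else config.lam
        if epoch == polish_start and config.polish_frac > 0:
            freeze_masks = [np.abs(p) < network.theta for p in params]
            for p, mask in zip(params, freeze_masks):
                p[mask] = 0.0

        if config.batch_size is None or config.batch_size >= n:
            batches = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            batches = np.array_split(perm, int(np.ceil(n / config.batch_size)))

        epoch_loss = 0.0
        for idx in batches:
            xb, zb = X[idx], z[idx]
            yhat, caches = network._forward_cached(xb)
            resid = yhat - zb
            batch_fit = float(np.mean(resid ** 2))
            dyhat = 2.0 * resid / len(zb)
            grads = network._backward(dyhat, caches)
            # global-norm gradient clipping stabilizes the early transient of
            # exp/square compositions
            gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if gnorm > GRAD_CLIP:
                scale = GRAD_CLIP / gnorm
                grads = [g * scale for g in grads]
            if lam_t:
                for p, g in zip(params, grads):
                    g += lam_t * l12_star_grad(p, network.a)
            step += 1
            # cosine decay of the learning rate over the run
            lr_t = config.lr * (0.05 + 0.95 * 0.5 *
                                (1 + np.cos(np.pi * epoch / max(config.epochs - 1, 1))))
            for pi, (p, g) in enumerate(zip(params, grads)):
                m_state[pi] = beta1 * m_state[pi] + (1 - beta1) * g
                v_state[pi] = beta2 * v_state[pi] + (1 - beta2) * g * g
                mhat = m_state[pi] / (1 - beta1 ** step)
                vhat = v_state[pi] / (1 - beta2 ** step)
                p -= lr_t * mhat / (np.sqrt(vhat) + eps)
                if freeze_masks is not None:
                    p[freeze_masks[pi]] = 0.0
            epoch_loss += batch_fit * len(zb)
        epoch_loss /= n
        if lam_t:
            epoch_loss += lam_t * network.penalty()
        if not np.isfinite(epoch_loss):
            raise TrainingDivergence(epoch)
        history.append(epoch_loss)

    _cast_network(network, np.float64)
    # record the target standardization as the network's affine output map so
    # predictions are on the raw scale while the pruning threshold keeps
    # acting on the weights at their trained (standardized) scale
    network.y_mean, network.y_scale = mu, sd
    return network, history


def fit_with_restarts(train_set: TripletDataset,
                      operator_set: OperatorSet = OperatorSet(),
                      depth: int = 2,
                      units_per_op: Union[int, dict, None] = None,
                      config: TrainConfig = TrainConfig(),
                      restarts: int = 3):
    """Train from several seeded initializations; keep the best final loss.

    Restart seeds are derived deterministically from ``config.seed``.
    Returns ``(network, history)`` of the winning restart.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    best = None
    for child in ss.spawn(restarts):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        net = build_network(operator_set, depth=depth, units_per_op=units_per_op,
                            seed=seed)
        cfg = replace(config, seed=seed)
        try:
            net, history = train(net, train_set, cfg)
        except TrainingDivergence:
            continue
        if best is None or history[-1] < best[1][-1]:
            best = (net, history)
    if best is None:
        raise TrainingDivergence(-1)
    return best
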