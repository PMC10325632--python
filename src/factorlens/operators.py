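"""Safeguarded elementary operators for the equation-learner network.

Each hidden unit of the network applies one of these operators to the output of
a linear stage.  Unary operators consume one linear output; binary operators
consume two consecutive linear outputs.  Every operator is total on the reals
after safeguarding: the quotient floors the magnitude of its denominator at
``EPS`` (keeping the sign), log-abs floors the magnitude of its argument at
``EPS``, and exp clips its argument at ``EXP_CLIP`` so activations stay finite
through arbitrarily deep compositions.

The same primitives are used by three independent code paths that must agree
numerically: the network forward pass, the extracted-formula evaluator, and the
synthetic surface generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EPS = 1e-3
EXP_CLIP = 6.0


def safe_denominator(d):
    """Sign-preserving magnitude floor used by the quotient operator."""
    d = np.asarray(d, dtype=float)
    sign = np.where(d >= 0, 1.0, -1.0)
    return sign * np.maximum(np.abs(d), EPS)


def safe_log_abs(x):
    """log(max(|x|, EPS)); total on the reals, natural log."""
    return np.log(np.maximum(np.abs(np.asarray(x, dtype=float)), EPS))


def safe_exp(x):
    return np.exp(np.minimum(np.asarray(x, dtype=float), EXP_CLIP))


# ---------------------------------------------------------------------------
# unary operators: name -> (f, df/dx)

def _d_logabs(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    mask = np.abs(x) > EPS
    np.divide(1.0, x, out=out, where=mask)
    return out


UNARY = {
    "identity": (lambda x: np.asarray(x, dtype=float), lambda x: np.ones_like(np.asarray(x, dtype=float))),
    "square": (lambda x: x * x, lambda x: 2.0 * x),
    # beyond the clip the true derivative is 0; keeping exp(EXP_CLIP) there
    # avoids dead saturated units and pressures their inputs back into range
    "exp": (safe_exp, safe_exp),
    "sin": (np.sin, np.cos),
    "cos": (np.cos, lambda x: -np.sin(x)),
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
    "logabs": (safe_log_abs, _d_logabs),
}


# ---------------------------------------------------------------------------
# binary operators: name -> (f, (df/da, df/db))

def _quotient(a, b):
    return a / safe_denominator(b)


def _d_quotient_a(a, b):
    return 1.0 / safe_denominator(b)


def _d_quotient_b(a, b):
    b = np.asarray(b, dtype=float)
    out = np.zeros_like(np.broadcast_arrays(np.asarray(a, dtype=float), b)[0])
    mask = np.abs(b) > EPS
    np.divide(-a, b * b, out=out, where=mask)
    return out


BINARY = {
    "sum": (lambda a, b: a + b,
            (lambda a, b: np.ones_like(a), lambda a, b: np.ones_like(b))),
    "difference": (lambda a, b: a - b,
                   (lambda a, b: np.ones_like(a), lambda a, b: -np.ones_like(b))),
    "product": (lambda a, b: a * b,
                (lambda a, b: np.asarray(b, dtype=float), lambda a, b: np.asarray(a, dtype=float))),
    "quotient": (_quotient, (_d_quotient_a, _d_quotient_b)),
}

DEFAULT_UNARY = ("identity", "square", "exp", "sin", "cos", "relu", "logabs")
DEFAULT_BINARY = ("sum", "difference", "product", "quotient")


def arity(name: str) -> int:
    if name in UNARY:
        return 1
    if name in BINARY:
        return 2
    raise KeyError(f"unknown operator {name!r}")


def apply_unary(name, x):
    return UNARY[name][0](x)


def apply_binary(name, a, b):
    return BINARY[name][0](a, b)


@dataclass(frozen=True)
class OperatorSet:
    """Inventory of operators available to a network.

    The set is extensible: any subset of the registered unary/binary operators
    may be enabled.  ``with_derivative`` exposes the precomputed first
    difference of the target along the row index as an extra input feature
    (it is not an in-network operator).
    """

    unary: tuple = DEFAULT_UNARY
    binary: tuple = DEFAULT_BINARY
    with_derivative: bool = False

    def __post_init__(self):
        object.__setattr__(self, "unary", tuple(self.unary))
        object.__setattr__(self, "binary", tuple(self.binary))
        for name in self.unary:
            if name not in UNARY:
                raise ValueError(f"unknown unary operator {name!r}; known: {sorted(UNARY)}")
        for name in self.binary:
            if name not in BINARY:
                raise ValueError(f"unknown binary operator {name!r}; known: {sorted(BINARY)}")
        if not self.unary and not self.binary:
            raise ValueError("operator set must enable at least one operator")

    @property
    def n_inputs(self) -> int:
        return 3 if self.with_derivative else 2

    @property
    def names(self) -> tuple:
        return self.unary + self.binary
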