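"""Closed-form formula extraction from a pruned equation-learner network.

Weights with magnitude strictly below the coefficient threshold are treated
as exactly zero; the surviving structure is composed layer by layer into an
expression tree with constant folding (no aggressive algebraic rewriting).
The tree evaluates with the same safeguarded primitives as the network, so a
pruned network's forward pass and the extracted formula agree to floating
tolerance by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import sympy

from .operators import BINARY, UNARY, apply_binary, apply_unary
from .triplets import TripletDataset

_RENDER = {
    "square": lambda s: f"({s})^2",
    "logabs": lambda s: f"log|{s}|",
    "exp": lambda s: f"exp({s})",
    "sin": lambda s: f"sin({s})",
    "cos": lambda s: f"cos({s})",
    "relu": lambda s: f"relu({s})",
    "identity": lambda s: s,
}


def _fmt(v: float) -> str:
    return f"{v:.6g}"


# ---------------------------------------------------------------------------
# expression nodes

class Expr:
    """Base expression node over X1, X2, dy and constants."""

    def evaluate(self, env: dict) -> np.ndarray:
        raise NotImplementedError

    def variables(self) -> set:
        raise NotImplementedError

    def constants(self) -> list:
        raise NotImplementedError

    def to_sympy(self):
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    def __str__(self) -> str:
        return self._render(0)

    def _render(self, parent_prec: int) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class Const(Expr):
    value: float

    def evaluate(self, env):
        return np.full_like(next(iter(env.values())), self.value, dtype=float)

    def variables(self):
        return set()

    def constants(self):
        return [self.value]

    def to_sympy(self):
        return sympy.Float(self.value)

    def to_dict(self):
        return {"type": "const", "value": self.value}

    def _render(self, parent_prec):
        s = _fmt(self.value)
        return f"({s})" if self.value < 0 and parent_prec >= 2 else s


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def evaluate(self, env):
        return np.asarray(env[self.name], dtype=float)

    def variables(self):
        return {self.name}

    def constants(self):
        return []

    def to_sympy(self):
        return sympy.Symbol(self.name)

    def to_dict(self):
        return {"type": "var", "name": self.name}

    def _render(self, parent_prec):
        return self.name


@dataclass(frozen=True)
class Add(Expr):
    terms: tuple

    def evaluate(self, env):
        out = self.terms[0].evaluate(env)
        for t in self.terms[1:]:
            out = out + t.evaluate(env)
        return out

    def variables(self):
        return set().union(*(t.variables() for t in self.terms))

    def constants(self):
        return [c for t in self.terms for c in t.constants()]

    def to_sympy(self):
        return sympy.Add(*(t.to_sympy() for t in self.terms))

    def to_dict(self):
        return {"type": "add", "terms": [t.to_dict() for t in self.terms]}

    def _render(self, parent_prec):
        parts = [self.terms[0]._render(1)]
        for t in self.terms[1:]:
            s = t._render(1)
            parts.append(f" - {s[1:]}" if s.startswith("-") else f" + {s}")
        s = "".join(parts)
        return f"({s})" if parent_prec >= 2 else s


@dataclass(frozen=True)
class Mul(Expr):
    factors: tuple

    def evaluate(self, env):
        out = self.factors[0].evaluate(env)
        for f in self.factors[1:]:
            out = out * f.evaluate(env)
        return out

    def variables(self):
        return set().union(*(f.variables() for f in self.factors))

    def constants(self):
        return [c for f in self.factors for c in f.constants()]

    def to_sympy(self):
        return sympy.Mul(*(f.to_sympy() for f in self.factors))

    def to_dict(self):
        return {"type": "mul", "factors": [f.to_dict() for f in self.factors]}

    def _render(self, parent_prec):
        s = "*".join(f._render(2) for f in self.factors)
        return f"({s})" if parent_prec >= 3 else s


@dataclass(frozen=True)
class Unary(Expr):
    op: str
    child: Expr

    def evaluate(self, env):
        return apply_unary(self.op, self.child.evaluate(env))

    def variables(self):
        return self.child.variables()

    def constants(self):
        return self.child.constants()

    def to_sympy(self):
        c = self.child.to_sympy()
        table = {
            "identity": lambda x: x,
            "square": lambda x: x ** 2,
            "exp": sympy.exp,
            "sin": sympy.sin,
            "cos": sympy.cos,
            "relu": lambda x: sympy.Max(x, 0),
            "logabs": lambda x: sympy.log(sympy.Abs(x)),
        }
        return table[self.op](c)

    def to_dict(self):
        return {"type": "unary", "op": self.op, "child": self.child.to_dict()}

    def _render(self, parent_prec):
        inner = self.child._render(0)
        return _RENDER[self.op](inner)


@dataclass(frozen=True)
class Binary(Expr):
    op: str
    left: Expr
    right: Expr

    def evaluate(self, env):
        return apply_binary(self.op, self.left.evaluate(env), self.right.evaluate(env))

    def variables(self):
        return self.left.variables() | self.right.variables()

    def constants(self):
        return self.left.constants() + self.right.constants()

    def to_sympy(self):
        a, b = self.left.to_sympy(), self.right.to_sympy()
        if self.op == "quotient":
            return a / b
        raise ValueError(self.op)

    def to_dict(self):
        return {"type": "binary", "op": self.op,
                "left": self.left.to_dict(), "right": self.right.to_dict()}

    def _render(self, parent_prec):
        a = self.left._render(2)
        b = self.right._render(3)
        s = f"{a}/{b}"
        return f"({s})" if parent_prec >= 3 else s


# -- smart constructors with constant folding -------------------------------

def _is_const(e: Expr, v: Optional[float] = None) -> bool:
    return isinstance(e, Const) and (v is None or e.value == v)


def add(terms: Sequence[Expr]) -> Expr:
    flat: List[Expr] = []
    const_sum = 0.0
    for t in terms:
        if isinstance(t, Add):
            sub = list(t.terms)
        else:
            sub = [t]
        for s in sub:
            if _is_const(s):
                const_sum += s.value
            else:
                flat.append(s)
    if const_sum != 0.0 or not flat:
        flat.append(Const(const_sum))
    if len(flat) == 1:
        return flat[0]
    return Add(tuple(flat))


def mul(factors: Sequence[Expr]) -> Expr:
    flat: List[Expr] = []
    coeff = 1.0
    for f in factors:
        if isinstance(f, Mul):
            sub = list(f.factors)
        else:
            sub = [f]
        for s in sub:
            if _is_const(s):
                coeff *= s.value
            else:
                flat.append(s)
    if coeff == 0.0:
        return Const(0.0)
    if not flat:
        return Const(coeff)
    if coeff != 1.0:
        flat.insert(0, Const(coeff))
    if len(flat) == 1:
        return flat[0]
    return Mul(tuple(flat))


def unary(op: str, child: Expr) -> Expr:
    if op == "identity":
        return child
    if _is_const(child):
        return Const(float(apply_unary(op, np.float64(child.value))))
    return Unary(op, child)


def binary(op: str, left: Expr, right: Expr) -> Expr:
    if op == "sum":
        return add([left, right])
    if op == "difference":
        return add([left, mul([Const(-1.0), right])])
    if op == "product":
        return mul([left, right])
    if _is_const(left) and _is_const(right):
        return Const(float(apply_binary(op, np.float64(left.value),
                                        np.float64(right.value))))
    return Binary(op, left, right)


_NODE_TYPES = {"const": Const, "var": Var}


def expr_from_dict(d: dict) -> Expr:
    t = d["type"]
    if t == "const":
        return Const(d["value"])
    if t == "var":
        return Var(d["name"])
    if t == "add":
        return Add(tuple(expr_from_dict(x) for x in d["terms"]))
    if t == "mul":
        return Mul(tuple(expr_from_dict(x) for x in d["factors"]))
    if t == "unary":
        return Unary(d["op"], expr_from_dict(d["child"]))
    if t == "binary":
        return Binary(d["op"], expr_from_dict(d["left"]), expr_from_dict(d["right"]))
    raise ValueError(f"unknown expression node type {t!r}")


# ---------------------------------------------------------------------------
# formula object

@dataclass
class SymbolicFormula:
    """Expression tree read off a pruned network.

    ``is_constant`` flags the degenerate case in which pruning removed every
    path from the inputs, leaving only the bias-driven constant.
    """

    expr: Expr
    theta: float
    is_constant: bool = False
    pruned_network: object = field(default=None, repr=False, compare=False)

    def evaluate(self, data, X2=None, dy=None) -> np.ndarray:
        """Evaluate on a TripletDataset or on coordinate arrays (X1, X2[, dy])."""
        if isinstance(data, TripletDataset):
            env = {"X1": data.x1, "X2": data.x2}
            if data.dy is not None:
                env["dy"] = data.dy
        else:
            X1 = np.asarray(data, dtype=float)
            env = {"X1": X1, "X2": np.asarray(X2, dtype=float)}
            if dy is not None:
                env["dy"] = np.asarray(dy, dtype=float)
        shape = np.broadcast_shapes(*(v.shape for v in env.values()))
        env = {k: np.broadcast_to(v, shape).astype(float) for k, v in env.items()}
        return np.asarray(self.expr.evaluate(env), dtype=float)

    __call__ = evaluate

    def __str__(self) -> str:
        return str(self.expr)

    @property
    def expression(self) -> str:
        return str(self.expr)

    @property
    def operators_used(self) -> list:
        ops = set()

        def walk(e):
            if isinstance(e, Unary):
                ops.add(e.op)
            elif isinstance(e, Binary):
                ops.add(e.op)
            elif isinstance(e, Add):
                ops.add("sum")
            elif isinstance(e, Mul):
                ops.add("product")
            for c in getattr(e, "terms", ()) or ():
                walk(c)
            for c in getattr(e, "factors", ()) or ():
                walk(c)
            if isinstance(e, Unary):
                walk(e.child)
            if isinstance(e, Binary):
                walk(e.left), walk(e.right)
        walk(self.expr)
        return sorted(ops)

    @property
    def coefficients(self) -> list:
        return self.expr.constants()

    def to_sympy(self):
        """Canonical sympy form (unsafeguarded log|.| and /)."""
        return self.expr.to_sympy()

    def to_json(self, path=None, accuracy: Optional[dict] = None):
        record = {
            "expression": self.expression,
            "operators_used": self.operators_used,
            "coefficients": self.coefficients,
            "theta": self.theta,
            "is_constant": self.is_constant,
            "tree": self.expr.to_dict(),
        }
        if accuracy is not None:
            record["accuracy"] = accuracy
        if path is None:
            return json.dumps(record, indent=2)
        with open(path, "w") as fh:
            json.dump(record, fh, indent=2)
        return None

    @classmethod
    def from_json(cls, source) -> "SymbolicFormula":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            record = json.loads(source)
        else:
            with open(source) as fh:
                record = json.load(fh)
        expr = expr_from_dict(record["tree"])
        return cls(expr=expr, theta=record["theta"],
                   is_constant=record["is_constant"])


def extract_formula(network, theta: Optional[float] = None) -> SymbolicFormula:
    """Prune a trained network at the coefficient threshold and read it off.

    Magnitudes strictly below ``theta`` are zeroed (a coefficient exactly at
    the threshold is retained); the surviving structure is composed layer by
    layer into an expression tree with constant folding.  A fully pruned
    network yields the constant bias-only formula, flagged ``is_constant``.
    """
    if theta is None:
        theta = network.theta
    pruned = network.copy()
    for p in pruned.parameters():
        p[np.abs(p) < theta] = 0.0

    names = ["X1", "X2"] + (["dy"] if network.operator_set.with_derivative else [])
    exprs: List[Expr] = [Var(n) for n in names]
    for layer in pruned.layers:
        lin = []
        for k in range(layer.n_g):
            terms = [mul([Const(w), e]) for w, e in zip(layer.W[k], exprs) if w != 0.0]
            if layer.b[k] != 0.0:
                terms.append(Const(float(layer.b[k])))
            lin.append(add(terms) if terms else Const(0.0))
        out = []
        k = 0
        for name in layer.units:
            from .operators import arity
            if arity(name) == 1:
                out.append(unary(name, lin[k]))
                k += 1
            else:
                out.append(binary(name, lin[k], lin[k + 1]))
                k += 2
        exprs = out
    terms = [mul([Const(float(w)), e]) for w, e in zip(pruned.w_out, exprs) if w != 0.0]
    if pruned.b_out[0] != 0.0:
        terms.append(Const(float(pruned.b_out[0])))
    expr = add(terms) if terms else Const(0.0)
    # affine output map recorded by training (target standardization)
    if network.y_scale != 1.0 or network.y_mean != 0.0:
        expr = add([mul([Const(float(network.y_scale)), expr]),
                    Const(float(network.y_mean))])
    return SymbolicFormula(expr=expr, theta=theta,
                           is_constant=not expr.variables(),
                           pruned_network=pruned)


# ---------------------------------------------------------------------------
# verification accuracy

@dataclass
class AccuracyReport:
    """Tolerance-band accuracy of a predictor on held-out triplets.

    ``accuracy`` is the percentage of test records whose prediction falls
    within ``tau`` times the observed target range of the true value
    (boundary inclusive).
    """

    accuracy: float
    tau: float
    n_test: int
    mae: float
    nrmse: float

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "tau": self.tau, "n_test": self.n_test,
                "mae": self.mae, "nrmse": self.nrmse}


def verification_accuracy(predictor, testset: TripletDataset,
                          tau: float = 0.05) -> AccuracyReport:
    """Fraction (in percent) of test points predicted within the tolerance band.

    The band is ``tau * (max(y) - min(y))`` over the test targets; a constant
    target range leaves the tolerance undefined and is an error.  The
    predictor may be a SymbolicFormula, an EqlNetwork, or any callable on a
    TripletDataset.
    """
    if len(testset) == 0:
        raise ValueError("test set is empty")
    y = testset.y
    spread = float(y.max() - y.min())
    if spread == 0.0:
        raise ValueError("constant target range: tolerance band undefined")
    if hasattr(predictor, "predict"):
        yhat = predictor.predict(testset)
    elif isinstance(predictor, SymbolicFormula):
        yhat = predictor.evaluate(testset)
    else:
        yhat = predictor(testset)
    yhat = np.asarray(yhat, dtype=float).reshape(-1)
    resid = np.abs(yhat - y)
    within = resid <= tau * spread
    return AccuracyReport(
        accuracy=100.0 * float(np.mean(within)),
        tau=tau,
        n_test=len(y),
        mae=float(np.mean(resid)),
        nrmse=float(np.sqrt(np.mean(resid ** 2)) / spread),
    )
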