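"""Mode-product tensor algebra for frame reconstruction.

A 3D volume frame is reconstructed from three mode factor matrices and a
small fixed core (kernel) tensor, X = G x1 A x2 S x3 C, in the Tucker sense;
frames are merged along a trailing axis into a 4D reference tensor.  A
simplified seeded gradient-descent fitter recovers factor matrices from a
frame with the core held constant — a desk-scale factor learner whose only
contract is reconstruction error, not factor identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

_NONLINEARITIES = {
    "identity": (lambda x: x, lambda x: np.ones_like(x)),
    "relu": (lambda x: np.maximum(x, 0.0), lambda x: (x > 0).astype(float)),
    "sigmoid": (lambda x: 1.0 / (1.0 + np.exp(-x)),
                lambda x: (s := 1.0 / (1.0 + np.exp(-x))) * (1 - s)),
}


def mode_product(tensor: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n product: contract the tensor's ``mode`` axis with the matrix columns.

    The output extent along ``mode`` equals the matrix row count; all other
    extents are unchanged.
    """
    tensor = np.asarray(tensor, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("mode_product expects a 2D matrix")
    if not 0 <= mode < tensor.ndim:
        raise ValueError(f"mode {mode} out of range for a {tensor.ndim}-way tensor")
    if matrix.shape[1] != tensor.shape[mode]:
        raise ValueError(
            f"mode-{mode} extent mismatch: matrix has {matrix.shape[1]} columns, "
            f"tensor extent is {tensor.shape[mode]}")
    moved = np.moveaxis(tensor, mode, 0)
    out = np.tensordot(matrix, moved, axes=(1, 0))
    return np.moveaxis(out, 0, mode)


@dataclass
class CoreTensor:
    """Fixed 3-way kernel G coupling the factor matrices."""

    G: np.ndarray
    tag: str = "user"

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 3:
            raise ValueError("core tensor must be 3-way")
        if min(self.G.shape) < 1:
            raise ValueError("core ranks must be >= 1")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("core tensor entries must be finite")

    @property
    def ranks(self) -> Tuple[int, int, int]:
        return self.G.shape

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# shape=" + ",".join(map(str, self.G.shape)) + "\n")
            fh.write(f"# tag={self.tag}\n")
            np.savetxt(fh, self.G.reshape(-1, 1))

    @classmethod
    def load(cls, path) -> "CoreTensor":
        meta = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    meta[key.strip()] = value.strip()
                elif line.strip():
                    rows.append(float(line))
        if "shape" not in meta:
            raise ValueError(f"{path}: missing shape header")
        shape = tuple(int(s) for s in meta["shape"].split(","))
        return cls(G=np.array(rows).reshape(shape), tag=meta.get("tag", "user"))


def superdiagonal_core(ranks: Tuple[int, int, int],
                       seed: Optional[int] = None) -> CoreTensor:
    """Identity-like core: ones (or seeded positive values) on the superdiagonal."""
    G = np.zeros(tuple(int(r) for r in ranks))
    r = min(ranks)
    values = np.ones(r) if seed is None else np.random.default_rng(seed).uniform(0.5, 1.5, r)
    for k in range(r):
        G[k, k, k] = values[k]
    return CoreTensor(G=G, tag="superdiagonal")


def random_core(ranks: Tuple[int, int, int], seed: int = 0) -> CoreTensor:
    G = np.random.default_rng(seed).normal(size=tuple(int(r) for r in ranks))
    return CoreTensor(G=G, tag="random")


@dataclass
class FactorSet:
    """Three mode factor matrices (modes 1..3; e.g. coronal/sagittal/axial)."""

    A: np.ndarray
    S: np.ndarray
    C: np.ndarray
    labels: Tuple[str, str, str] = ("mode-1", "mode-2", "mode-3")

    def __post_init__(self):
        for name in "ASC":
            m = np.asarray(getattr(self, name), dtype=float)
            if m.ndim != 2:
                raise ValueError(f"factor {name} must be a matrix")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"factor {name} has non-finite entries")
            setattr(self, name, m)

    @property
    def matrices(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.A, self.S, self.C)

    @property
    def dims(self) -> Tuple[int, int, int]:
        return (self.A.shape[0], self.S.shape[0], self.C.shape[0])

    @property
    def ranks(self) -> Tuple[int, int, int]:
        return (self.A.shape[1], self.S.shape[1], self.C.shape[1])


def reconstruct_frame(core: CoreTensor, factors: FactorSet,
                      nonlinearity: str = "identity") -> np.ndarray:
    """X = G x1 f(A) x2 f(S) x3 f(C); deterministic.

    ``nonlinearity`` applies an elementwise map to each raw factor matrix
    before the mode products (identity, relu, or sigmoid).
    """
    f = _NONLINEARITIES[nonlinearity][0]
    if factors.ranks != core.ranks:
        raise ValueError(
            f"factor column counts {factors.ranks} do not match core ranks {core.ranks}")
    out = core.G
    for mode, m in enumerate(factors.matrices):
        out = mode_product(out, f(m), mode)
    return out


def split_frames(tensor4d: np.ndarray) -> List[np.ndarray]:
    """Unstack a 4-way array into its T temporal frames (in order)."""
    tensor4d = np.asarray(tensor4d, dtype=float)
    if tensor4d.ndim != 4:
        raise ValueError(f"expected a 4-way tensor, got {tensor4d.ndim}-way")
    return [tensor4d[..., t].copy() for t in range(tensor4d.shape[3])]


def merge_frames(frames: Sequence[np.ndarray]) -> np.ndarray:
    """Stack 3D frames into a 4D reference tensor; inverse of split_frames."""
    frames = [np.asarray(f, dtype=float) for f in frames]
    if not frames:
        raise ValueError("no frames to merge")
    for f in frames:
        if f.ndim != 3 or f.shape != frames[0].shape:
            raise ValueError("frames must all be 3-way with equal shapes")
    return np.stack(frames, axis=-1)


@dataclass
class FitConfig:
    """Options for the gradient-descent factor fitter."""

    max_iter: int = 6000
    tol: float = 1e-12
    seed: int = 0
    nonlinearity: str = "identity"
    init_scale: float = 0.1
    lr: float = 0.05

    def __post_init__(self):
        if self.nonlinearity not in _NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")


class FitDivergence(RuntimeError):
    def __init__(self, history):
        super().__init__("factor fitting diverged")
        self.history = history


def fit_factors(frame: np.ndarray, core: CoreTensor,
                config: FitConfig = FitConfig()):
    """Fit factor matrices to a frame by seeded gradient descent.

    The core is fixed; factors (optionally passed through an elementwise
    non-linearity) minimize the mean squared reconstruction error.  Plain
    gradient descent with backtracking step halving on loss increase keeps
    the recorded loss history non-increasing.  Returns (FactorSet, history);
    the returned matrices are the post-nonlinearity factors, i.e. the frame is
    reproduced by ``reconstruct_frame(core, factors)`` with the identity map.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3:
        raise ValueError("frame must be 3-way")
    ranks = core.ranks
    for mode, (d, r) in enumerate(zip(frame.shape, ranks), start=1):
        if r > d:
            raise ValueError(f"core rank {r} exceeds frame extent {d} in mode {mode}")
    f, df = _NONLINEARITIES[config.nonlinearity]
    rng = np.random.default_rng(config.seed)
    raw = [rng.normal(0.0, config.init_scale, size=(d, r))
           for d, r in zip(frame.shape, ranks)]
    n = frame.size

    def recon(mats):
        out = core.G
        for mode, m in enumerate(mats):
            out = mode_product(out, f(m), mode)
        return out

    def unfold(t, mode):
        return np.moveaxis(t, mode, 0).reshape(t.shape[mode], -1)

    def grads(mats, err):
        fm = [f(m) for m in mats]
        out = []
        for mode in range(3):
            partial = core.G
            for other in range(3):
                if other != mode:
                    partial = mode_product(partial, fm[other], other)
            g = (2.0 / n) * unfold(err, mode) @ unfold(partial, mode).T
            out.append(g * df(mats[mode]))
        return out

    err = recon(raw) - frame
    current = float(np.mean(err ** 2))
    history = [current]
    lr = config.lr
    for _ in range(config.max_iter):
        g = grads(raw, err)
        accepted = False
        for _ in range(30):
            trial = [m - lr * gm for m, gm in zip(raw, g)]
            trial_err = recon(trial) - frame
            trial_loss = float(np.mean(trial_err ** 2))
            if not np.isfinite(trial_loss):
                raise FitDivergence(history)
            if trial_loss <= current:
                accepted = True
                break
            lr *= 0.5
        if not accepted:
            break
        raw, err = trial, trial_err
        improvement = current - trial_loss
        current = trial_loss
        history.append(current)
        lr *= 1.05
        if improvement < config.tol * max(current, 1e-30):
            break
    factors = FactorSet(A=f(raw[0]), S=f(raw[1]), C=f(raw[2]))
    return factors, history
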