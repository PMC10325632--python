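"""Synthetic data generators.

Everything the analysis modules consume can be regenerated here with no
external download: factor surfaces from the six built-in closed-form
equations (one per anatomical plane and group), random factorized tensors for
round-trip tests, phantom label volumes standing in for an anatomical
parcellation, and two-group ROI time series with planted connectivity
differences.  All generators are pure functions of their spec (seed
included).

The six built-in surfaces are evaluated with the same safeguarded primitives
as the equation-learner network (quotient and log-abs floor their arguments
at 1e-3), so a network equipped with those operators can in principle
represent each surface exactly.  The axial-autism surface is defined
implicitly through the first difference of the value along the row index; it
is generated by a forward recursion (see :func:`_axial_autism_surface`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import sympy

from .connectome import Parcellation, RoiTimeSeriesSet, SUBNETWORKS
from .operators import EPS, safe_denominator, safe_exp, safe_log_abs
from .tensorops import CoreTensor, FactorSet, reconstruct_frame, superdiagonal_core
from .triplets import TripletDataset, matrix_to_triplets

# ---------------------------------------------------------------------------
# built-in factor surfaces


def _relu(x):
    return np.maximum(x, 0.0)


def _coronal_autism(X1, X2):
    return 0.14 * np.cos(np.sin(safe_log_abs(-0.165 * np.cos(0.05 * X1))) - 0.11 * X2)


def _coronal_normal(X1, X2):
    den = _relu(np.sin(0.624 - 1.0 * X2)) * 0.568 + X1 - 5.29
    return 1.0 / np.abs(safe_denominator(den))


def _sagittal_autism(X1, X2):
    return np.cos(np.abs(27.709 + _relu(np.sin(X1 + 1.0 * np.cos(np.abs(4.71 * X2))))))


def _sagittal_normal(X1, X2):
    return np.cos(safe_exp(0.017 * safe_log_abs(X1 * X2 - 4.2 * X2)))


def _axial_autism_c(X1, X2):
    return np.cos(1.0 * X1 * safe_exp(np.cos(1.0 * X1) + X2))


def _axial_normal(X1, X2):
    return np.sin(np.cos((1.0 / 7.65) * np.abs(safe_log_abs(X1))) * np.sin(X2))


def _axial_autism_surface(X1, X2):
    """Row-recursive surface: y = 0.431 y' - 0.055 cos(X1 exp(cos X1 + X2)).

    The equation is implicit in y through the first difference
    y'_i = y_i - y_{i-1} (index-unit spacing, matching the triplet derivative
    convention).  Rearranging gives the stable forward recursion
    ``y_i = -(0.431 y_{i-1} + 0.055 c_i) / 0.569`` with the first row set to
    the non-derivative part ``-0.055 c_0``.
    """
    c = _axial_autism_c(X1, X2)
    y = np.empty_like(c)
    y[0] = -0.055 * c[0]
    for i in range(1, c.shape[0]):
        y[i] = -(0.431 * y[i - 1] + 0.055 * c[i]) / 0.569
    return y


BUILTIN_SURFACES = {
    "coronal-autism": _coronal_autism,
    "coronal-normal": _coronal_normal,
    "sagittal-autism": _sagittal_autism,
    "sagittal-normal": _sagittal_normal,
    "axial-autism": _axial_autism_surface,
    "axial-normal": _axial_normal,
}


@dataclass(frozen=True)
class FormulaSpec:
    """Recipe for a factor surface.

    ``name`` is one of the built-ins or a user expression over X1 and X2
    (sympy syntax).  Noise is additive Gaussian: ``noise_sd`` is absolute;
    ``noise_frac`` is relative to the clean surface's value range and takes
    precedence when set.
    """

    name: str
    shape: Tuple[int, int] = (100, 100)
    noise_sd: float = 0.0
    noise_frac: Optional[float] = None
    seed: int = 0
    with_derivative: bool = False


def _grid(shape):
    n_rows, n_cols = shape
    x1 = np.linspace(-1.0, 1.0, n_rows) if n_rows > 1 else np.zeros(1)
    x2 = np.linspace(-1.0, 1.0, n_cols) if n_cols > 1 else np.zeros(1)
    return np.meshgrid(x1, x2, indexing="ij")


def _user_surface(expression: str, X1, X2):
    sX1, sX2 = sympy.symbols("X1 X2")
    expr = sympy.sympify(expression, locals={"X1": sX1, "X2": sX2})
    extra = expr.free_symbols - {sX1, sX2}
    if extra:
        raise ValueError(f"user expression may only use X1 and X2; found {extra}")
    fn = sympy.lambdify((sX1, sX2), expr, modules="numpy")
    return np.broadcast_to(np.asarray(fn(X1, X2), dtype=float), X1.shape).copy()


def formula_surface(spec: FormulaSpec):
    """Evaluate a formula on the normalized grid; returns (matrix, triplets)."""
    X1, X2 = _grid(spec.shape)
    if spec.name in BUILTIN_SURFACES:
        clean = BUILTIN_SURFACES[spec.name](X1, X2)
    else:
        try:
            clean = _user_surface(spec.name, X1, X2)
        except (sympy.SympifyError, SyntaxError, TypeError) as err:
            raise ValueError(
                f"unknown surface {spec.name!r} and not a valid expression; "
                f"built-ins: {sorted(BUILTIN_SURFACES)}") from err
    sd = spec.noise_sd
    if spec.noise_frac is not None:
        sd = spec.noise_frac * float(clean.max() - clean.min())
    matrix = clean
    if sd > 0:
        rng = np.random.default_rng(spec.seed)
        matrix = clean + rng.normal(0.0, sd, size=clean.shape)
    return matrix, matrix_to_triplets(matrix, with_derivative=spec.with_derivative)


# ---------------------------------------------------------------------------
# factorized tensors


def random_factor_tensor(dims: Tuple[int, int, int],
                         ranks: Tuple[int, int, int],
                         seed: int = 0):
    """Seeded (core, factors, volume) with volume == exact reconstruction."""
    dims = tuple(int(d) for d in dims)
    ranks = tuple(int(r) for r in ranks)
    for mode, (d, r) in enumerate(zip(dims, ranks), start=1):
        if r > d:
            raise ValueError(f"rank {r} exceeds extent {d} in mode {mode}")
        if r < 1:
            raise ValueError("ranks must be >= 1")
    rng = np.random.default_rng(seed)
    core = superdiagonal_core(ranks)
    factors = FactorSet(
        A=rng.normal(0.0, 1.0, size=(dims[0], ranks[0])),
        S=rng.normal(0.0, 1.0, size=(dims[1], ranks[1])),
        C=rng.normal(0.0, 1.0, size=(dims[2], ranks[2])),
    )
    volume = reconstruct_frame(core, factors)
    return core, factors, volume


# ---------------------------------------------------------------------------
# phantom parcellation


def phantom_parcellation(dims: Tuple[int, int, int],
                         n_rois: int = 116,
                         seed: int = 0) -> Parcellation:
    """Voronoi-style label volume with every label 1..n_rois occupied.

    Seeded ROI centers are drawn without replacement from the voxel grid and
    every voxel is assigned to the nearest center (ties to the lowest label).
    ROI ids are partitioned into eight contiguous, near-equal blocks mapped to
    the canonical subnetwork names.
    """
    dims = tuple(int(d) for d in dims)
    n_vox = int(np.prod(dims))
    if n_vox < n_rois:
        raise ValueError(f"{n_vox} voxels cannot host {n_rois} ROIs")
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    rng = np.random.default_rng(seed)
    centers_flat = rng.choice(n_vox, size=n_rois, replace=False)
    centers = np.column_stack(np.unravel_index(centers_flat, dims)).astype(float)
    coords = np.column_stack([g.ravel() for g in
                              np.meshgrid(*(np.arange(d) for d in dims),
                                          indexing="ij")]).astype(float)
    from scipy.spatial import cKDTree
    _, nearest = cKDTree(centers).query(coords)
    labels = (nearest + 1).reshape(dims).astype(np.int32)

    blocks = np.array_split(np.arange(1, n_rois + 1), min(len(SUBNETWORKS), n_rois))
    subnet_map = {}
    for name, block in zip(SUBNETWORKS, blocks):
        for roi in block:
            subnet_map[int(roi)] = name
    return Parcellation(labels=labels, subnet_map=subnet_map)


# ---------------------------------------------------------------------------
# two-group time series with planted connectivity differences


@dataclass(frozen=True)
class PlantedDifferenceSpec:
    """Simulation recipe for a two-group connectivity comparison.

    Both groups share a weak common background (pairwise correlation
    ``base_corr`` between all ROIs).  In group B each planted edge's pair of
    ROIs additionally mixes a shared latent source whose weight is calibrated
    (by a seeded internal pilot under the default histogram-MI estimator) so
    that the expected MI difference equals ``effect_size`` pooled standard
    deviations of the null edge-MI distribution.  ROI indices in ``edges``
    are 0-based rows of the time-series matrix.
    """

    n_rois: int = 12
    n_frames: int = 150
    n_per_group: int = 20
    edges: Tuple[Tuple[int, int], ...] = ()
    effect_size: float = 0.0
    base_corr: float = 0.1
    seed: int = 0
    bins: int = 16

    def __post_init__(self):
        object.__setattr__(self, "edges",
                           tuple((int(p), int(q)) for p, q in self.edges))
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if not 0.0 <= self.base_corr < 1.0:
            raise ValueError("base_corr must lie in [0, 1)")
        seen = set()
        for p, q in self.edges:
            if p == q or not (0 <= p < self.n_rois and 0 <= q < self.n_rois):
                raise ValueError(f"invalid planted edge ({p}, {q})")
            key = (min(p, q), max(p, q))
            if key in seen:
                raise ValueError(f"duplicate planted edge ({p}, {q})")
            seen.add(key)


def _correlated_pair(rng, n, rho):
    z = rng.normal(size=n)
    e1 = rng.normal(size=n)
    e2 = rng.normal(size=n)
    s = np.sqrt(rho)
    c = np.sqrt(1.0 - rho)
    return s * z + c * e1, s * z + c * e2


def _pilot_mixing_weight(spec: PlantedDifferenceSpec, rng) -> float:
    """Map the pooled-SD effect size to a latent mixing weight.

    Short Monte-Carlo pilot: estimate the null edge-MI mean/SD at the base
    correlation, then the mean MI at a grid of added shared-latent weights,
    and invert the (monotone) weight -> MI-difference curve at
    ``effect_size * SD``.
    """
    from .connectome import mutual_information
    reps = 24
    null_mi = np.array([
        mutual_information(*_correlated_pair(rng, spec.n_frames, spec.base_corr),
                           bins=spec.bins)
        for _ in range(reps)
    ])
    sd = float(null_mi.std(ddof=1))
    target = spec.effect_size * sd
    w_grid = np.array([0.0, 0.3, 0.45, 0.6, 0.7, 0.8, 0.9, 0.97])
    max_w = np.sqrt(0.99 - spec.base_corr)
    w_grid = np.clip(w_grid, 0.0, max_w)
    deltas = []
    for w in w_grid:
        rho = spec.base_corr + w * w
        mi = np.mean([
            mutual_information(*_correlated_pair(rng, spec.n_frames, rho),
                               bins=spec.bins)
            for _ in range(reps)
        ])
        deltas.append(mi - null_mi.mean())
    deltas = np.maximum.accumulate(np.asarray(deltas))  # enforce monotone curve
    if target >= deltas[-1]:
        return float(w_grid[-1])
    return float(np.interp(target, deltas, w_grid))


def group_timeseries(spec: PlantedDifferenceSpec):
    """Simulate the two groups; returns (group_a, group_b) lists of ROI series."""
    ss = np.random.SeedSequence(spec.seed)
    pilot_ss, *subject_ss = ss.spawn(1 + 2 * spec.n_per_group)
    weight = 0.0
    if spec.effect_size > 0 and spec.edges:
        weight = _pilot_mixing_weight(spec, np.random.default_rng(pilot_ss))

    v = spec.base_corr
    groups = ([], [])
    for g, label in enumerate("AB"):
        for s in range(spec.n_per_group):
            rng = np.random.default_rng(subject_ss[g * spec.n_per_group + s])
            background = rng.normal(size=spec.n_frames)
            noise = rng.normal(size=(spec.n_rois, spec.n_frames))
            w_roi = np.zeros(spec.n_rois)
            latent_of_roi = {}
            if label == "B" and weight > 0:
                for ei, (p, q) in enumerate(spec.edges):
                    latent = rng.normal(size=spec.n_frames)
                    latent_of_roi[p] = latent
                    latent_of_roi[q] = latent
                    w_roi[p] = weight
                    w_roi[q] = weight
            data = np.empty((spec.n_rois, spec.n_frames))
            for r in range(spec.n_rois):
                w = w_roi[r]
                resid = np.sqrt(max(1.0 - v - w * w, 0.0))
                data[r] = resid * noise[r] + np.sqrt(v) * background
                if w > 0:
                    data[r] += w * latent_of_roi[r]
            groups[g].append(RoiTimeSeriesSet(
                data=data, subject=f"{label}{s + 1:03d}", group=label))
    return groups
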