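"""Entropy-based functional connectivity and edgewise group comparison.

ROI mean time series are extracted from a labeled parcellation; pairwise
dependence between regions is quantified by histogram plug-in mutual
information I(R1;R2) = H(R1) + H(R2) - H(R1,R2) in bits, assembled into a
symmetric R x R connectivity matrix (marginal entropies on the diagonal).
Subject-level matrices are compared edge by edge between two groups with a
linear model (group indicator plus optional covariates — an ANCOVA; with no
covariates it reduces exactly to the two-sample pooled-variance t-test), and
the resulting p-values receive Benjamini–Hochberg FDR correction.

The joint histogram reuses the per-axis marginal bin edges, which guarantees
the plug-in MI is non-negative and that I(X;X) = H(X).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

SUBNETWORKS = ("DMN", "AN", "VN", "SMN", "BiN", "SCN", "CCN", "Cerebellum")


# ---------------------------------------------------------------------------
# parcellation and ROI series

@dataclass
class Parcellation:
    """Integer label volume (0 = background, labels 1..R) plus subnetwork map."""

    labels: np.ndarray
    subnet_map: Dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3-dimensional")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if self.labels.min() < 0:
            raise ValueError("negative labels are not allowed")
        self.subnet_map = {int(k): str(v) for k, v in self.subnet_map.items()}
        present = set(np.unique(self.labels)) - {0}
        expected = set(range(1, self.n_rois + 1))
        missing = expected - present
        if missing:
            raise ValueError(f"ROIs with zero voxels: {sorted(missing)[:10]}")
        unmapped = expected - set(self.subnet_map)
        if unmapped:
            raise ValueError(f"ROIs without subnetwork assignment: {sorted(unmapped)[:10]}")

    @property
    def n_rois(self) -> int:
        return int(self.labels.max())

    @property
    def subnetworks(self) -> Tuple[str, ...]:
        """Subnetwork names in canonical order, restricted to those present."""
        present = set(self.subnet_map.values())
        ordered = [s for s in SUBNETWORKS if s in present]
        ordered += sorted(present - set(SUBNETWORKS))
        return tuple(ordered)

    def map_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi_id": sorted(self.subnet_map),
            "subnetwork": [self.subnet_map[k] for k in sorted(self.subnet_map)],
        })

    def save(self, labels_path, map_path) -> None:
        import nibabel as nib
        nib.Nifti1Image(self.labels.astype(np.int32), np.eye(4)).to_filename(str(labels_path))
        self.map_table().to_csv(map_path, sep="\t", index=False)

    @classmethod
    def load(cls, labels_path, map_path) -> "Parcellation":
        import nibabel as nib
        labels = np.asarray(nib.load(str(labels_path)).dataobj).astype(np.int32)
        table = pd.read_csv(map_path, sep="\t")
        subnet = dict(zip(table["roi_id"].astype(int), table["subnetwork"]))
        return cls(labels=labels, subnet_map=subnet)


@dataclass
class RoiTimeSeriesSet:
    """R x T matrix of per-ROI mean signals for one subject."""

    data: np.ndarray
    subject: str = ""
    group: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ROI time series must be an R x T matrix")
        if self.data.shape[1] < 2:
            raise ValueError("need at least T = 2 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ROI time series contain non-finite values")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def extract_roi_timeseries(tensor4d: np.ndarray,
                           parcellation: Parcellation,
                           subject: str = "", group: str = "") -> RoiTimeSeriesSet:
    """Mean signal over each ROI's voxels, per frame."""
    tensor4d = np.asarray(tensor4d, dtype=float)
    if tensor4d.ndim != 4:
        raise ValueError("expected a 4-way tensor")
    if tensor4d.shape[:3] != parcellation.labels.shape:
        raise ValueError(
            f"spatial extents {tensor4d.shape[:3]} do not match the label "
            f"volume {parcellation.labels.shape}")
    R = parcellation.n_rois
    flat = parcellation.labels.ravel()
    mask = flat > 0
    lab = flat[mask]
    counts = np.bincount(lab, minlength=R + 1)[1:]
    voxels = tensor4d.reshape(-1, tensor4d.shape[3])[mask]
    T = voxels.shape[1]
    data = np.empty((R, T))
    for t in range(T):
        sums = np.bincount(lab, weights=voxels[:, t], minlength=R + 1)[1:]
        data[:, t] = sums / counts
    return RoiTimeSeriesSet(data=data, subject=subject, group=group)


# ---------------------------------------------------------------------------
# plug-in entropies

def _bin_codes(series: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width bin index over [min, max]; a constant series occupies one bin."""
    series = np.asarray(series, dtype=float).reshape(-1)
    if len(series) < 2:
        raise ValueError("need at least 2 samples")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    lo, hi = series.min(), series.max()
    if hi == lo:
        return np.zeros(len(series), dtype=np.int64)
    codes = ((series - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(codes, 0, bins - 1)


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def marginal_entropy(series, bins: int = 16) -> float:
    """Shannon entropy (bits) of the equal-width histogram of a series."""
    codes = _bin_codes(series, bins)
    return _entropy_from_counts(np.bincount(codes, minlength=bins))


def joint_entropy(s1, s2, bins: int = 16) -> float:
    """Entropy (bits) of the 2D histogram using each axis' marginal edges."""
    s1 = np.asarray(s1, dtype=float).reshape(-1)
    s2 = np.asarray(s2, dtype=float).reshape(-1)
    if len(s1) != len(s2):
        raise ValueError("series length mismatch")
    c1 = _bin_codes(s1, bins)
    c2 = _bin_codes(s2, bins)
    return _entropy_from_counts(np.bincount(c1 * bins + c2, minlength=bins * bins))


def mutual_information(s1, s2, bins: int = 16) -> float:
    """I(s1;s2) = H(s1) + H(s2) - H(s1,s2) in bits; symmetric, >= 0."""
    mi = (marginal_entropy(s1, bins) + marginal_entropy(s2, bins)
          - joint_entropy(s1, s2, bins))
    return max(mi, 0.0)


# ---------------------------------------------------------------------------
# connectivity matrices

@dataclass
class ConnectivityMatrix:
    """Symmetric R x R mutual-information matrix.

    Diagonal convention: each ROI's marginal entropy (excluded from
    thresholding and from group testing).
    """

    values: np.ndarray
    bins: int
    subject: str = ""
    group: str = ""
    threshold: Optional[float] = None
    adjacency: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n_rois, k=1)
        return self.values[iu]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values).to_csv(path, sep="\t", index=False, header=False)


def build_connectivity(ts: RoiTimeSeriesSet, bins: int = 16) -> ConnectivityMatrix:
    """All R(R-1)/2 pairwise MI values, mirrored; marginal entropies on the diagonal."""
    R = ts.n_rois
    if R < 2:
        raise ValueError("need at least 2 ROIs")
    codes = np.vstack([_bin_codes(ts.data[r], bins) for r in range(R)])
    marg = np.array([_entropy_from_counts(np.bincount(codes[r], minlength=bins))
                     for r in range(R)])
    M = np.zeros((R, R))
    np.fill_diagonal(M, marg)
    for p in range(R):
        joint_codes = codes[p] * bins + codes[p + 1:]
        for q in range(p + 1, R):
            h12 = _entropy_from_counts(
                np.bincount(joint_codes[q - p - 1], minlength=bins * bins))
            mi = max(marg[p] + marg[q] - h12, 0.0)
            M[p, q] = M[q, p] = mi
    return ConnectivityMatrix(values=M, bins=bins, subject=ts.subject, group=ts.group)


def apply_threshold(matrix: ConnectivityMatrix, threshold: float) -> np.ndarray:
    """Binary adjacency: edge present iff MI > threshold (strict); no self-loops."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    adj = matrix.values > threshold
    np.fill_diagonal(adj, False)
    matrix.threshold = float(threshold)
    matrix.adjacency = adj
    return adj


def pooled_median_threshold(matrices: Sequence[ConnectivityMatrix]) -> float:
    """Default edge threshold: median off-diagonal MI pooled over subjects."""
    return float(np.median(np.concatenate([m.off_diagonal() for m in matrices])))


# ---------------------------------------------------------------------------
# group comparison

@dataclass
class GroupComparisonResult:
    """Edgewise ANCOVA output over all unordered ROI pairs.

    Arrays are condensed over the upper triangle (``edge_index`` gives the
    (p, q) ROI pair of each entry, 0-based).  ``mask`` marks edges significant
    after Benjamini–Hochberg correction at level ``q_level``.
    """

    n_rois: int
    edge_index: np.ndarray        # (m, 2)
    stat: np.ndarray              # F statistic of the group effect
    pvalues: np.ndarray
    qvalues: np.ndarray
    mask: np.ndarray
    q_level: float
    covariates: Tuple[str, ...] = ()

    def _to_matrix(self, vec, fill=0.0) -> np.ndarray:
        M = np.full((self.n_rois, self.n_rois), fill, dtype=float)
        p, q = self.edge_index.T
        M[p, q] = M[q, p] = vec
        return M

    def p_matrix(self) -> np.ndarray:
        return self._to_matrix(self.pvalues, fill=1.0)

    def q_matrix(self) -> np.ndarray:
        return self._to_matrix(self.qvalues, fill=1.0)

    def significance_matrix(self) -> np.ndarray:
        return self._to_matrix(self.mask.astype(float)) > 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi_p": self.edge_index[:, 0] + 1,
            "roi_q": self.edge_index[:, 1] + 1,
            "stat": self.stat,
            "p": self.pvalues,
            "q": self.qvalues,
            "significant": self.mask,
        })


def fdr_correct(pvalues, q: float = 0.05):
    """Benjamini–Hochberg step-up; returns (adjusted q-values, mask at level q)."""
    p = np.asarray(pvalues, dtype=float).reshape(-1)
    if len(p) == 0:
        raise ValueError("no p-values supplied")
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    _, qvalues, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    mask = qvalues <= q
    return qvalues, mask


def _edge_vectors(matrices) -> Tuple[np.ndarray, np.ndarray, int]:
    mats = [m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
            for m in matrices]
    R = mats[0].shape[0]
    for m in mats:
        if m.shape != (R, R):
            raise ValueError("all connectivity matrices must share the ROI count")
    iu = np.triu_indices(R, k=1)
    return np.vstack([m[iu] for m in mats]), np.column_stack(iu), R


def edgewise_group_comparison(group_a, group_b,
                              covariates: Optional[pd.DataFrame] = None,
                              q_level: float = 0.05) -> GroupComparisonResult:
    """Per-edge linear model of MI on a group indicator plus covariates.

    ``covariates`` (optional) is a per-subject table, rows ordered as
    group A subjects followed by group B subjects.  The group-effect F
    statistic has 1 numerator degree of freedom; with no covariates the test
    is exactly the one-way ANOVA / pooled two-sample t-test.  P-values are
    FDR-corrected over all edges.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    Ya, edges, R = _edge_vectors(group_a)
    Yb, _, Rb = _edge_vectors(group_b)
    if R != Rb:
        raise ValueError("groups have different ROI counts")
    Y = np.vstack([Ya, Yb])
    n = Y.shape[0]
    indicator = np.concatenate([np.zeros(len(group_a)), np.ones(len(group_b))])
    design = [np.ones(n), indicator]
    cov_names: Tuple[str, ...] = ()
    if covariates is not None:
        covariates = pd.DataFrame(covariates)
        if len(covariates) != n:
            raise ValueError(
                f"covariate table has {len(covariates)} rows for {n} subjects")
        for name in covariates.columns:
            design.append(covariates[name].to_numpy(dtype=float))
        cov_names = tuple(str(c) for c in covariates.columns)
    X = np.column_stack(design)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates?)")
    df = n - X.shape[1]
    if df < 1:
        raise ValueError("not enough subjects for the requested covariates")

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    rss = np.sum(resid ** 2, axis=0)
    sigma2 = rss / df
    var_g = sigma2 * XtX_inv[1, 1]
    beta_g = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta_g / np.sqrt(var_g)
    # degenerate edges with zero residual variance
    tstat = np.where(var_g == 0, np.where(beta_g == 0, 0.0, np.inf), tstat)
    pvalues = 2.0 * sp_stats.t.sf(np.abs(tstat), df)
    qvalues, mask = fdr_correct(pvalues, q=q_level)
    return GroupComparisonResult(
        n_rois=R, edge_index=edges, stat=tstat ** 2, pvalues=pvalues,
        qvalues=qvalues, mask=mask, q_level=q_level, covariates=cov_names)


# ---------------------------------------------------------------------------
# subnetwork blocks

def subnetwork_summary(obj, parcellation: Parcellation,
                       metric: Optional[str] = None) -> pd.DataFrame:
    """Block summary over subnetwork pairs.

    For a :class:`GroupComparisonResult` the default metric is the count of
    significant edges per block; for a :class:`ConnectivityMatrix` it is the
    mean MI over the block's distinct ROI pairs.  The output is a symmetric
    S x S table indexed by subnetwork name.
    """
    nets = parcellation.subnetworks
    net_of_roi = np.array([nets.index(parcellation.subnet_map[r])
                           for r in range(1, parcellation.n_rois + 1)])
    S = len(nets)
    out = np.zeros((S, S))

    if isinstance(obj, GroupComparisonResult):
        if metric not in (None, "count"):
            raise ValueError("comparison results summarize by significant-edge count")
        if obj.n_rois != parcellation.n_rois:
            raise ValueError("ROI count mismatch between result and parcellation")
        for (p, q), sig in zip(obj.edge_index, obj.mask):
            if sig:
                a, b = net_of_roi[p], net_of_roi[q]
                out[a, b] += 1
                if a != b:
                    out[b, a] += 1
    else:
        if metric not in (None, "mean_mi"):
            raise ValueError("connectivity matrices summarize by mean MI")
        matrix = obj.values if isinstance(obj, ConnectivityMatrix) else np.asarray(obj)
        if matrix.shape[0] != parcellation.n_rois:
            raise ValueError("ROI count mismatch between matrix and parcellation")
        counts = np.zeros((S, S))
        R = matrix.shape[0]
        for p in range(R):
            for q in range(p + 1, R):
                a, b = net_of_roi[p], net_of_roi[q]
                out[a, b] += matrix[p, q]
                counts[a, b] += 1
                if a != b:
                    out[b, a] += matrix[p, q]
                    counts[b, a] += 1
        with np.errstate(invalid="ignore"):
            out = np.where(counts > 0, out / np.maximum(counts, 1), 0.0)
    return pd.DataFrame(out, index=list(nets), columns=list(nets))
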