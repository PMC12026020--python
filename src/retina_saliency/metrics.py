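"""Saliency-evaluation metrics.

Implements the eight standard fixation-prediction metrics: distribution-based
comparisons against a ground-truth fixation density (Pearson CC, histogram
similarity/intersection, earth mover's distance, KL divergence) and
location-based comparisons against discrete fixation points (NSS and the
Judd, Borji and shuffled variants of the ROC AUC).

Conventions fixed here (and configurable where noted):

* KL divergence is ``KL(density ‖ prediction)`` in nats, with ``1e-12`` added
  to the prediction before renormalisation.
* EMD is exact optimal transport with Euclidean ground distance, computed on
  a mass-preserving block-sum downsampling to at most ``grid×grid`` cells
  (default 32) and reported in downsampled-cell units.
* NSS z-scores with the population standard deviation.
* Degenerate constant maps score their chance level: CC 0, NSS 0, AUC 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import csr_matrix, identity, kron, vstack
from scipy.spatial.distance import cdist

from .baseline import SaliencyMap

#: Small constant added to predicted distributions before the KL ratio.
KL_EPS = 1e-12

#: Default side length of the downsampled grid used for EMD.
EMD_GRID = 32

HIGHER_BETTER = ("cc", "similarity", "nss", "auc_borji", "auc_judd", "auc_shuffled")
LOWER_BETTER = ("emd", "kldiv")
METRIC_NAMES = ("cc", "similarity", "emd", "kldiv", "nss", "auc_borji", "auc_judd", "auc_shuffled")


@dataclass(frozen=True)
class FixationSet:
    """Discrete eye-fixation coordinates on a pixel grid.

    ``points`` is an ``N×2`` integer array of 0-based ``(row, col)`` pairs;
    ``image_h``/``image_w`` give the grid the coordinates refer to.
    """

    points: np.ndarray
    image_h: int
    image_w: int

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=np.int64))
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be N×2 (row, col), got shape {pts.shape}")
        if self.image_h < 1 or self.image_w < 1:
            raise ValueError("image dimensions must be positive")
        if pts.shape[0] > 0:
            if pts[:, 0].min() < 0 or pts[:, 0].max() >= self.image_h:
                raise ValueError("fixation row out of bounds")
            if pts[:, 1].min() < 0 or pts[:, 1].max() >= self.image_w:
                raise ValueError("fixation column out of bounds")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    def values_at(self, raster: np.ndarray) -> np.ndarray:
        """Raster values sampled at the fixation locations."""
        return raster[self.points[:, 0], self.points[:, 1]]

    def flat_indices(self) -> np.ndarray:
        return self.points[:, 0] * self.image_w + self.points[:, 1]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.points, columns=["row", "col"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, image_h: int, image_w: int) -> "FixationSet":
        df = pd.read_csv(path)
        return cls(df[["row", "col"]].to_numpy(dtype=np.int64), image_h, image_w)


@dataclass(frozen=True)
class MetricReport:
    """One score per metric, with ``auc_shuffled`` optional (it needs
    fixations from other images to draw negatives from)."""

    cc: float
    similarity: float
    emd: float
    kldiv: float
    nss: float
    auc_borji: float
    auc_judd: float
    auc_shuffled: Optional[float] = None

    def to_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    @staticmethod
    def is_improvement(metric: str, original: float, processed: float) -> bool:
        """Strict improvement of ``processed`` over ``original`` honouring the
        metric's direction; ties are not improvements."""
        if metric in LOWER_BETTER:
            return processed < original
        if metric in HIGHER_BETTER:
            return processed > original
        raise KeyError(f"unknown metric {metric!r}")


def _as_array(smap) -> np.ndarray:
    if isinstance(smap, SaliencyMap):
        return smap.values
    arr = np.asarray(smap, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {arr.shape}")
    return arr


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def _unit_mass(arr: np.ndarray) -> np.ndarray:
    arr = arr - min(arr.min(), 0.0)
    total = arr.sum()
    if total == 0.0:
        return np.full_like(arr, 1.0 / arr.size)
    return arr / total


def cc(smap, density) -> float:
    """Pearson correlation between saliency map and fixation density.

    Returns 0 by convention if either raster is constant.
    """
    p = _as_array(smap).ravel()
    q = _as_array(density).ravel()
    _check_shapes(p, q)
    if p.std() == 0.0 or q.std() == 0.0:
        return 0.0
    return float(np.corrcoef(p, q)[0, 1])


def similarity(smap, density) -> float:
    """Histogram intersection Σ min(P, Q) of the two unit-mass rasters.

    1 for identical distributions, 0 for disjoint supports; symmetric.
    """
    p = _unit_mass(_as_array(smap))
    q = _unit_mass(_as_array(density))
    _check_shapes(p, q)
    return float(np.minimum(p, q).sum())


def kldiv(density, smap) -> float:
    """KL(density ‖ prediction) in nats.

    The prediction has ``1e-12`` added per pixel before renormalisation so
    the ratio is defined wherever the ground truth has mass.
    """
    p = _unit_mass(_as_array(density))
    q = _as_array(smap)
    _check_shapes(p, q)
    q = _unit_mass(q) + KL_EPS
    q = q / q.sum()
    support = p > 0
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def nss(smap, fix: FixationSet) -> float:
    """Normalized Scanpath Saliency: mean z-scored map value at fixations.

    The map is standardised with the population standard deviation; a
    constant map scores 0 by convention.
    """
    arr = _as_array(smap)
    if len(fix) < 1:
        raise ValueError("NSS needs at least one fixation")
    std = arr.std()
    if std == 0.0:
        return 0.0
    z = (arr - arr.mean()) / std
    return float(fix.values_at(z).mean())


def _trapezoid_auc(tp: np.ndarray, fp: np.ndarray) -> float:
    fp = np.concatenate(([0.0], fp, [1.0]))
    tp = np.concatenate(([0.0], tp, [1.0]))
    return float(np.trapezoid(tp, fp))


def auc_judd(smap, fix: FixationSet) -> float:
    """AUC, Judd variant: thresholds at the saliency values of the fixations.

    True-positive rate is computed over fixations, false-positive rate over
    all non-fixated pixels, and the ROC area is the trapezoidal integral
    through (0,0) and (1,1).
    """
    arr = _as_array(smap)
    if len(fix) < 1:
        raise ValueError("AUC needs at least one fixation")
    pos = fix.values_at(arr)
    mask = np.ones(arr.size, dtype=bool)
    mask[fix.flat_indices()] = False
    neg = arr.ravel()[mask]
    if neg.size == 0 or arr.std() == 0.0:
        return 0.5
    thresholds = np.sort(np.unique(pos))[::-1]
    tp = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    fp = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    return _trapezoid_auc(tp, fp)


def _roc_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Trapezoidal ROC area with thresholds at every observed value (ties get
    the usual half credit via the diagonal segment)."""
    thresholds = np.sort(np.unique(np.concatenate([pos, neg])))[::-1]
    tp = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    fp = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    return _trapezoid_auc(tp, fp)


def auc_borji(
    smap,
    fix: FixationSet,
    n_splits: int = 100,
    n_neg: Optional[int] = None,
    seed: int = 0,
) -> float:
    """AUC, Borji variant: negatives are uniformly random non-fixated pixels.

    ``n_neg`` negatives (default: the number of fixations) are drawn per
    split and the trapezoidal ROC area is averaged over ``n_splits`` splits.
    """
    arr = _as_array(smap)
    if len(fix) < 1:
        raise ValueError("AUC needs at least one fixation")
    if arr.std() == 0.0:
        return 0.5
    pos = fix.values_at(arr)
    mask = np.ones(arr.size, dtype=bool)
    mask[fix.flat_indices()] = False
    pool = arr.ravel()[mask]
    if pool.size == 0:
        return 0.5
    if n_neg is None:
        n_neg = len(fix)
    rng = np.random.default_rng(seed)
    aucs = [
        _roc_auc(pos, rng.choice(pool, size=n_neg, replace=True))
        for _ in range(n_splits)
    ]
    return float(np.mean(aucs))


def auc_shuffled(
    smap,
    fix: FixationSet,
    other_fix: Sequence[FixationSet],
    n_splits: int = 100,
    n_neg: Optional[int] = None,
    seed: int = 0,
) -> float:
    """Shuffled AUC: negatives are fixation locations from *other* images.

    Because the negatives inherit the spatial (centre) bias of human
    fixations, a map that merely predicts the centre scores at chance. The
    pooled other-image locations are sampled ``n_neg`` per split, otherwise
    as in the Borji variant.
    """
    arr = _as_array(smap)
    if len(fix) < 1:
        raise ValueError("AUC needs at least one fixation")
    other_fix = [f for f in other_fix if len(f) > 0]
    if not other_fix:
        raise ValueError("shuffled AUC needs fixations pooled from other images")
    if arr.std() == 0.0:
        return 0.5
    pos = fix.values_at(arr)
    pooled = np.concatenate([f.points for f in other_fix], axis=0)
    pooled = pooled[(pooled[:, 0] < arr.shape[0]) & (pooled[:, 1] < arr.shape[1])]
    if pooled.shape[0] == 0:
        raise ValueError("no pooled fixation falls inside the map bounds")
    pool_values = arr[pooled[:, 0], pooled[:, 1]]
    if n_neg is None:
        n_neg = len(fix)
    rng = np.random.default_rng(seed)
    aucs = [
        _roc_auc(pos, rng.choice(pool_values, size=n_neg, replace=True))
        for _ in range(n_splits)
    ]
    return float(np.mean(aucs))


def _block_downsample(arr: np.ndarray, grid: int) -> np.ndarray:
    """Mass-preserving block sum to at most ``grid×grid`` cells."""
    h, w = arr.shape
    if h <= grid and w <= grid:
        return arr
    fy = -(-h // grid)  # block height
    fx = -(-w // grid)  # block width
    pad_y = (fy - h % fy) % fy
    pad_x = (fx - w % fx) % fx
    padded = np.pad(arr, ((0, pad_y), (0, pad_x)), mode="constant")
    hh, ww = padded.shape
    return padded.reshape(hh // fy, fy, ww // fx, fx).sum(axis=(1, 3))


def _exact_ot(
    mass_a: np.ndarray, pts_a: np.ndarray, mass_b: np.ndarray, pts_b: np.ndarray
) -> float:
    """Exact optimal-transport cost between two weighted point clouds,
    solved as a linear program (HiGHS) with Euclidean ground distance."""
    cost = cdist(pts_a, pts_b)
    n, m = cost.shape
    row_sums = kron(identity(n, format="csr"), csr_matrix(np.ones((1, m))))
    col_sums = kron(csr_matrix(np.ones((1, n))), identity(m, format="csr"))
    # one marginal constraint is linearly dependent on the rest; dropping it
    # keeps the system full-rank and the solver stable
    a_eq = vstack([row_sums, col_sums], format="csr")[:-1]
    b_eq = np.concatenate([mass_a, mass_b])[:-1]
    res = linprog(cost.ravel(), A_eq=a_eq, b_eq=b_eq, method="highs")
    if not res.success:
        raise RuntimeError(f"optimal-transport LP failed: {res.message}")
    return float(res.fun)


def emd(smap, density, grid: int = EMD_GRID) -> float:
    """Earth mover's distance between the two rasters as unit-mass
    distributions.

    Both rasters are block-summed (mass-preserving) onto at most
    ``grid×grid`` cells, renormalised, and compared by exact optimal
    transport with Euclidean ground distance measured in downsampled-cell
    units. Symmetric; 0 iff the downsampled distributions coincide.
    """
    p = _as_array(smap)
    q = _as_array(density)
    _check_shapes(p, q)
    if grid < 1:
        raise ValueError("grid must be at least 1")
    p = _unit_mass(_block_downsample(_unit_mass(p), grid))
    q = _unit_mass(_block_downsample(_unit_mass(q), grid))
    if np.allclose(p, q):
        return 0.0
    idx_a = np.argwhere(p > 0)
    idx_b = np.argwhere(q > 0)
    return _exact_ot(
        p[p > 0], idx_a.astype(np.float64), q[q > 0], idx_b.astype(np.float64)
    )


def evaluate_all(
    smap,
    density,
    fix: FixationSet,
    other_fix: Sequence[FixationSet] = (),
    seed: int = 0,
    n_splits: int = 100,
    n_neg: Optional[int] = None,
    emd_grid: int = EMD_GRID,
) -> MetricReport:
    """Run every metric with its default configuration; fully seeded.

    ``auc_shuffled`` is reported as None when no other-image fixations are
    supplied (it needs them to draw negatives from).
    """
    shuffled = None
    if any(len(f) > 0 for f in other_fix):
        shuffled = auc_shuffled(
            smap, fix, other_fix, n_splits=n_splits, n_neg=n_neg, seed=seed
        )
    return MetricReport(
        cc=cc(smap, density),
        similarity=similarity(smap, density),
        emd=emd(smap, density, grid=emd_grid),
        kldiv=kldiv(density, smap),
        nss=nss(smap, fix),
        auc_borji=auc_borji(smap, fix, n_splits=n_splits, n_neg=n_neg, seed=seed),
        auc_judd=auc_judd(smap, fix),
        auc_shuffled=shuffled,
    )
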