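"""Intensity normalization by spatial Gaussian-mixture filtering (FGMM).

The image is viewed as an intensity measure over the voxel lattice,

    I_Gauss(x) = I * p(x),        p(x) = sum_n w_n f_n(x | theta_n),

where ``I`` is the total image intensity and ``p`` a k-component Gaussian
mixture over *spatial coordinates*, fitted by expectation-maximization
with each voxel contributing its intensity as a fractional multiplicity.
Filtering then removes mixture components that are irrelevant to the
striatum: a component is pruned (its weight set to zero, with no
renormalization of the others) when its density falls below the uniform
probability threshold ``eta = 1/N`` on at least 75% of the striatal
voxels.  Reconstruction from the surviving components preserves the
striatal signal while suppressing — and thereby normalizing — the
non-specific background, which is dominated by the pruned clusters.

The continuous mixture density is converted to a grid probability by
dividing by ``grid_norm``, the pre-pruning sum of ``p`` over all voxel
centers, so the unpruned reconstruction conserves total intensity exactly
and pruning can only lower voxel values.  ``grid_norm`` is frozen at fit
time and never recomputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .volume_io import BinaryMask, Volume

_LOG_2PI = float(np.log(2.0 * np.pi))

#: minimum covariance eigenvalue (voxel^2); keeps components non-singular
COV_FLOOR = 1e-4


@dataclass
class PruneConfig:
    """Probability threshold and the irrelevance fraction of the 75% rule."""

    eta: float
    irrelevance_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not (0 < self.irrelevance_fraction <= 1):
            raise ValueError("irrelevance_fraction must lie in (0, 1]")


@dataclass
class SpatialGMM:
    """A fitted spatial intensity mixture.

    ``weights`` sum to 1 immediately after fitting; pruning may zero
    entries without renormalizing.  ``total_intensity`` is the sum of all
    voxel intensities of the fitted volume; ``grid_norm`` the pre-pruning
    sum of the mixture density over all voxel centers.
    """

    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, 3) voxel coordinates
    covariances: np.ndarray  # (k, 3, 3) SPD
    total_intensity: float
    grid_norm: float
    shape: tuple[int, int, int]

    @property
    def k(self) -> int:
        return len(self.weights)

    def component_log_density(self, n: int, points: np.ndarray) -> np.ndarray:
        """log f_n at (m, 3) points — the unweighted component density."""
        return _gauss_log_density(self.means[n], self.covariances[n], points)

    def mixture_density(self, points: np.ndarray) -> np.ndarray:
        """p(x) = sum_n w_n f_n(x) at (m, 3) points, current weights."""
        out = np.zeros(len(points))
        for n in range(self.k):
            if self.weights[n] > 0:
                out += self.weights[n] * np.exp(self.component_log_density(n, points))
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "total_intensity": self.total_intensity,
            "grid_norm": self.grid_norm,
            "shape": list(self.shape),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpatialGMM":
        payload = json.loads(Path(path).read_text())
        return cls(
            weights=np.asarray(payload["weights"], dtype=np.float64),
            means=np.asarray(payload["means"], dtype=np.float64),
            covariances=np.asarray(payload["covariances"], dtype=np.float64),
            total_intensity=float(payload["total_intensity"]),
            grid_norm=float(payload["grid_norm"]),
            shape=tuple(payload["shape"]),
        )


def uniform_threshold(shape: tuple[int, int, int]) -> float:
    """1/N: the probability each voxel carries under a uniform intensity."""
    if any(d < 1 for d in shape):
        raise ValueError(f"invalid shape {shape}")
    n = int(np.prod(shape))
    return 1.0 / n


def _gauss_log_density(mean: np.ndarray, cov: np.ndarray, points: np.ndarray) -> np.ndarray:
    chol = np.linalg.cholesky(cov)
    # 3x3 triangular inverse is cheap; a matmul beats a triangular solve here
    inv_chol = solve_triangular(chol, np.eye(3), lower=True)
    half = (points - mean) @ inv_chol.T
    maha = np.einsum("ij,ij->i", half, half)
    log_det = 2.0 * float(np.sum(np.log(np.diag(chol))))
    return -0.5 * (maha + log_det + 3.0 * _LOG_2PI)


def _floor_spd(cov: np.ndarray, floor: float = COV_FLOOR) -> np.ndarray:
    """Clamp eigenvalues below ``floor`` up to it (no-op for healthy SPD)."""
    vals, vecs = np.linalg.eigh(cov)
    if vals[0] >= floor:
        return cov
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def _grid_points(shape: tuple[int, int, int]) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    return idx.reshape(3, -1).T


def fit_spatial_gmm(
    volume: Volume,
    k: int = 64,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SpatialGMM:
    """Weighted EM fit of the spatial mixture to a volume.

    Voxel centers with positive intensity enter as points weighted by
    their intensity (fractional multiplicity); initialization is
    k-means++ on the weighted coordinates, making the whole fit
    deterministic for a fixed seed.  Convergence: relative change of the
    weighted log-likelihood below ``tol``, or ``max_iter`` sweeps.
    """
    data = volume.data
    total_intensity = float(data.sum())
    if total_intensity <= 0:
        raise ValueError("all-zero volume: nothing to fit")
    if k < 1:
        raise ValueError("k must be >= 1")
    flat = data.ravel()
    pos = np.flatnonzero(flat > 0)
    if k > pos.size:
        raise ValueError(
            f"k={k} exceeds the {pos.size} voxels with positive intensity"
        )
    points = np.column_stack(np.unravel_index(pos, data.shape)).astype(np.float64)
    w = flat[pos] / flat[pos].sum()
    n_pts = len(points)

    centers, _ = kmeans_plusplus(points, n_clusters=k, sample_weight=w, random_state=seed)
    # hard-assignment moment start
    assign = np.argmin(cdist(points, centers, "sqeuclidean"), axis=1)
    global_mean = w @ points
    gdiff = points - global_mean
    global_cov = _floor_spd((gdiff * w[:, None]).T @ gdiff)
    weights = np.empty(k)
    means = np.empty((k, 3))
    covs = np.empty((k, 3, 3))
    for n in range(k):
        sel = assign == n
        mass = float(w[sel].sum())
        if mass <= 0:
            weights[n], means[n], covs[n] = 1.0 / n_pts, centers[n], global_cov
            continue
        weights[n] = mass
        means[n] = (w[sel] @ points[sel]) / mass
        diff = points[sel] - means[n]
        covs[n] = _floor_spd((diff * w[sel, None]).T @ diff / mass)
    weights /= weights.sum()

    # second moments x x^T per point, flattened once: (n_pts, 9)
    second = (points[:, :, None] * points[:, None, :]).reshape(n_pts, 9)
    log_resp = np.empty((n_pts, k))
    prev_ll = -np.inf
    for _ in range(max_iter):
        for n in range(k):
            log_resp[:, n] = np.log(weights[n]) + _gauss_log_density(
                means[n], covs[n], points
            )
        peak = log_resp.max(axis=1)
        np.exp(log_resp - peak[:, None], out=log_resp)  # now unnormalized resp.
        norm = log_resp.sum(axis=1)
        ll = float(w @ (peak + np.log(norm)))
        log_resp /= norm[:, None]
        wr = log_resp * w[:, None]
        mass = wr.sum(axis=0)
        live = mass > 1e-12
        new_means = means.copy()
        new_covs = covs.copy()
        new_means[live] = (wr[:, live].T @ points) / mass[live, None]
        raw_second = (wr[:, live].T @ second).reshape(-1, 3, 3) / mass[live, None, None]
        mu = new_means[live]
        scatter = raw_second - mu[:, :, None] * mu[:, None, :]
        for j, n in enumerate(np.flatnonzero(live)):
            new_covs[n] = _floor_spd(scatter[j])
        weights = np.where(live, mass, weights * 1e-12)
        weights /= weights.sum()
        means, covs = new_means, new_covs
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * abs(prev_ll):
            break
        prev_ll = ll

    model = SpatialGMM(
        weights=weights,
        means=means,
        covariances=covs,
        total_intensity=total_intensity,
        grid_norm=1.0,  # provisional; fixed below
        shape=data.shape,
    )
    grid_norm = float(model.mixture_density(_grid_points(data.shape)).sum())
    model.grid_norm = grid_norm
    return model


def prune_clusters(
    model: SpatialGMM,
    striatal: BinaryMask,
    config: PruneConfig,
    weighted_density: bool = False,
) -> SpatialGMM:
    """Zero the weight of components irrelevant to the striatal region.

    A component is irrelevant when its density is *strictly* below
    ``config.eta`` on at least ``config.irrelevance_fraction`` of the
    striatal voxels.  The threshold compares the unweighted component
    density ``f_n`` by default; ``weighted_density=True`` compares
    ``w_n * f_n`` instead.  Surviving weights are not renormalized and
    ``grid_norm`` is left untouched, so striatal intensity is preserved.
    """
    if striatal.shape != model.shape:
        raise ValueError("striatal mask does not match the model grid")
    n_s = striatal.count
    if n_s < 1:
        raise ValueError("empty striatal mask")
    coords = striatal.coordinates()
    new_weights = model.weights.copy()
    for n in range(model.k):
        f = np.exp(model.component_log_density(n, coords))
        if weighted_density:
            f = model.weights[n] * f
        below = int((f < config.eta).sum())
        if below >= config.irrelevance_fraction * n_s:
            new_weights[n] = 0.0
    return replace(model, weights=new_weights)


def reconstruct(model: SpatialGMM) -> Volume:
    """Evaluate I * p(x) / grid_norm at every voxel center.

    With the fit-time ``grid_norm`` this conserves total intensity for an
    unpruned model and is pointwise monotone decreasing under pruning.
    """
    if model.grid_norm <= 0:
        raise ValueError("non-positive grid normalization")
    density = model.mixture_density(_grid_points(model.shape))
    data = model.total_intensity * density / model.grid_norm
    return Volume(data.reshape(model.shape))


def fgmm_normalize(
    volume: Volume,
    striatal: BinaryMask,
    k: int = 64,
    seed: int = 0,
    eta: float | None = None,
    irrelevance_fraction: float = 0.75,
    weighted_density: bool = False,
) -> Volume:
    """Full FGMM pipeline: fit, prune at eta (default 1/N), reconstruct."""
    if eta is None:
        eta = uniform_threshold(volume.shape)
    model = fit_spatial_gmm(volume, k=k, seed=seed)
    pruned = prune_clusters(
        model,
        striatal,
        PruneConfig(eta=eta, irrelevance_fraction=irrelevance_fraction),
        weighted_density=weighted_density,
    )
    return reconstruct(pruned)
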