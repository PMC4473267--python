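"""Synthetic co-registered DaTSCAN-like phantom cohorts with known truth.

Real DaTSCAN SPECT databases are clinical and private; the phantom emulates
the features that matter to intensity normalization so that every
downstream stage can be tested with ground truth in hand:

* an ellipsoidal brain of uniform non-specific uptake;
* two mirrored striatal bodies (a caudate and a putamen blob per
  hemisphere) of much higher specific uptake, reduced — and optionally
  asymmetric — in the Parkinsonian-syndrome (PS) class;
* an isotropic Gaussian point-spread blur (post-reconstruction SPECT
  resolution);
* a per-subject affine calibration corruption ``alpha * I + beta`` applied
  inside the brain support (the camera-calibration artifact the
  normalizers must remove; air stays ~0);
* additive Gaussian voxel noise, clipped at zero.

Geometry is specified in fractions of the grid extents, so the same
anatomy renders at any grid size.  All randomness flows from one
``numpy.random.Generator`` seeded by the config, so a fixed seed yields a
bitwise-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume_io import NC, PS, Cohort, Volume

# Striatal bodies per hemisphere: (center offset, sigma) as fractions of the
# grid extents, relative to the grid center; axis 0 offset is mirrored for
# the two hemispheres.  One caudate-like and one putamen-like blob each.
_STRIATAL_BLOBS = (
    ((0.16, 0.10, 0.0), (0.035, 0.050, 0.050)),
    ((0.22, 0.02, 0.0), (0.040, 0.060, 0.050)),
)

#: brain ellipsoid semi-axes as fractions of the grid extents
_BRAIN_SEMIAXES = (0.42, 0.44, 0.42)


@dataclass
class PhantomConfig:
    """Generation parameters; defaults emulate a realistic DaTSCAN cohort.

    ``background_uptake`` sets the arbitrary count unit (non-specific level
    = 1).  ``striatal_amplitude`` is the extra specific uptake at the blob
    peaks before blurring, giving a specific:non-specific ratio of roughly
    4:1 in controls, typical of healthy DaT binding.  The PS class scales
    the striatal signal by ``ps_uptake_factor`` with hemispheric asymmetry
    (the worse side gets an extra ``asymmetry`` multiplier; the side is
    random per subject).  ``subject_uptake_sd`` adds biological spread to
    the striatal amplitude so classes are not trivially separable.
    """

    shape: tuple[int, int, int] = (73, 73, 45)
    n_nc: int = 20
    n_ps: int = 20
    gain_range: tuple[float, float] = (0.6, 1.4)
    offset_range: tuple[float, float] = (0.0, 0.3)  # in units of background_uptake
    ps_uptake_factor: float = 0.45
    asymmetry: float = 0.7  # worse-hemisphere multiplier; 1.0 = symmetric
    psf_sigma: float = 1.5  # voxels
    noise_sigma: float = 0.05  # in units of background_uptake
    background_uptake: float = 1.0
    striatal_amplitude: float = 3.0
    subject_uptake_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(d < 1 for d in self.shape):
            raise ValueError(f"invalid shape {self.shape}")
        if self.n_nc < 0 or self.n_ps < 0:
            raise ValueError("subject counts must be non-negative")
        if not (0 < self.gain_range[0] <= self.gain_range[1]):
            raise ValueError("gain_range must be strictly positive and ordered")
        if not (0 <= self.offset_range[0] <= self.offset_range[1]):
            raise ValueError("offset_range must be non-negative and ordered")
        if not (0 < self.ps_uptake_factor < 1):
            raise ValueError("ps_uptake_factor must lie in (0, 1)")
        if not (0 < self.asymmetry <= 1):
            raise ValueError("asymmetry must lie in (0, 1]")
        if self.psf_sigma < 0 or self.noise_sigma < 0 or self.subject_uptake_sd < 0:
            raise ValueError("sigmas must be non-negative")


@dataclass
class PhantomTruth:
    """Per-subject ground truth: one record per generated volume."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["id", "label", "gain", "offset", "factor_left", "factor_right"]
        )
    )

    def __len__(self) -> int:
        return len(self.table)


def _grids(shape: tuple[int, int, int]) -> tuple[list[np.ndarray], np.ndarray]:
    axes = [np.arange(d, dtype=np.float64) for d in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    return grids, center


def _brain_indicator(config: PhantomConfig, dilate: float = 1.0) -> np.ndarray:
    grids, center = _grids(config.shape)
    semi = np.asarray(_BRAIN_SEMIAXES) * np.asarray(config.shape)
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return r2 <= dilate


def brain_support(config: PhantomConfig) -> np.ndarray:
    """Boolean support inside which calibration drift and noise act.

    Slightly dilated beyond the brain ellipsoid so the blur skirt is
    included; air outside stays ~0.
    """
    return _brain_indicator(config, dilate=1.25)


def _clean_image(config: PhantomConfig, hemi_factors: tuple[float, float]) -> np.ndarray:
    """Noiseless, uncorrupted subject image for given hemisphere factors.

    ``hemi_factors`` scale the striatal (specific) signal of the (left,
    right) hemispheres, left = low axis-0 indices.
    """
    grids, center = _grids(config.shape)
    shape_arr = np.asarray(config.shape, dtype=np.float64)
    img = np.where(_brain_indicator(config), config.background_uptake, 0.0)
    for sign, factor in ((-1.0, hemi_factors[0]), (+1.0, hemi_factors[1])):
        for offset_frac, sigma_frac in _STRIATAL_BLOBS:
            offs = np.asarray(offset_frac) * shape_arr
            offs[0] *= sign
            sig = np.asarray(sigma_frac) * shape_arr
            d2 = sum(
                ((g - c - o) / s) ** 2
                for g, c, o, s in zip(grids, center, offs, sig)
            )
            img += factor * config.striatal_amplitude * np.exp(-0.5 * d2)
    # tracer only inside the head: truncate the analytic blob tails so air
    # is exactly zero beyond the blur reach of the brain
    img[~_brain_indicator(config)] = 0.0
    if config.psf_sigma > 0:
        img = gaussian_filter(img, config.psf_sigma, mode="constant")
    return img


def _ps_factors(config: PhantomConfig) -> tuple[float, float]:
    f = config.ps_uptake_factor
    return (f * config.asymmetry, f)


def archetypes(config: PhantomConfig) -> tuple[Volume, Volume]:
    """The noiseless, uncorrupted NC and PS reference phantoms.

    The PS archetype places the worse hemisphere on the left; with
    ``asymmetry == 1`` both archetypes are symmetric under the hemisphere
    reflection.
    """
    nc = Volume(_clean_image(config, (1.0, 1.0)))
    ps = Volume(_clean_image(config, _ps_factors(config)))
    return nc, ps


def generate_phantom(config: PhantomConfig) -> tuple[Cohort, PhantomTruth]:
    """Generate a corrupted phantom cohort plus its ground-truth record.

    Each subject is built as: clean anatomy (class-dependent striatal
    factors with per-subject amplitude jitter) -> PSF blur -> affine
    calibration corruption ``alpha * I + beta`` inside the brain support ->
    additive Gaussian noise (inside the support), clipped at 0.
    """
    rng = np.random.default_rng(config.seed)
    support = brain_support(config)
    volumes: list[Volume] = []
    labels: list[str] = []
    ids: list[str] = []
    rows = []
    classes = [NC] * config.n_nc + [PS] * config.n_ps
    for idx, label in enumerate(classes):
        jitter = max(0.5, 1.0 + config.subject_uptake_sd * rng.standard_normal())
        if label == NC:
            factors = (jitter, jitter)
        else:
            worse, better = _ps_factors(config)
            if rng.random() < 0.5:
                worse, better = better, worse
            factors = (worse * jitter, better * jitter)
        clean = _clean_image(config, factors)
        gain = rng.uniform(*config.gain_range)
        offset = rng.uniform(*config.offset_range) * config.background_uptake
        img = clean.copy()
        img[support] = gain * clean[support] + offset
        if config.noise_sigma > 0:
            img[support] += rng.normal(
                0.0, config.noise_sigma * config.background_uptake, size=int(support.sum())
            )
        np.clip(img, 0.0, None, out=img)
        sid = f"S{idx:03d}"
        volumes.append(Volume(img))
        labels.append(label)
        ids.append(sid)
        rows.append(
            {
                "id": sid,
                "label": label,
                "gain": gain,
                "offset": offset,
                "factor_left": factors[0],
                "factor_right": factors[1],
            }
        )
    cohort = Cohort(volumes, labels, ids)
    return cohort, PhantomTruth(pd.DataFrame(rows))
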