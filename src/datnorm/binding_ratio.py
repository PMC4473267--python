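"""Specific-to-non-specific binding-ratio quantification (the baseline).

The binding potential of a volume of interest against a reference region
is

    BP = (C_VOI - C_N) / C_N = C_VOI / C_N - 1,

with ``C_VOI`` and ``C_N`` the mean counts per voxel in the two regions.
``BR_all`` normalization applies the same ratio voxel-wise, with the whole
brain minus the striatum as the reference: it removes a multiplicative
camera gain exactly but cannot remove an additive calibration offset — a
failure mode the test suite demonstrates on phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass

from .volume_io import BinaryMask, Volume, mask_mean


@dataclass
class BindingResult:
    """Binding potential and the two region means it is computed from."""

    bp: float
    c_voi: float
    c_n: float


def binding_potential(volume: Volume, voi: BinaryMask, reference: BinaryMask) -> BindingResult:
    """BP = C_VOI / C_N - 1 with masked means as region counts."""
    c_voi = mask_mean(volume, voi)
    c_n = mask_mean(volume, reference)
    if c_n <= 0:
        raise ValueError("non-positive reference uptake")
    return BindingResult(bp=c_voi / c_n - 1.0, c_voi=c_voi, c_n=c_n)


def normalize_br_all(volume: Volume, nonspecific: BinaryMask, ratio_only: bool = False) -> Volume:
    """Voxel-wise binding-ratio normalization against the non-specific mean.

    Default is the BP convention ``(I - C_N) / C_N`` (non-specific mean
    maps to 0 exactly); ``ratio_only=True`` uses the plain ratio
    ``I / C_N`` (non-specific mean maps to 1).  The two differ by a global
    affine map only.
    """
    c_n = mask_mean(volume, nonspecific)
    if c_n <= 0:
        raise ValueError("non-positive reference uptake")
    if ratio_only:
        data = volume.data / c_n
    else:
        data = (volume.data - c_n) / c_n
    return Volume(data, volume.affine)
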