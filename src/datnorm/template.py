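"""Symmetric control template and the striatal / brain / non-specific masks.

The template is built from normal-control images only: each control is
added to its own hemisphere-midplane reflection and the results are
averaged,

    t = (1/N_c) * sum_i [ I_i(x, y, z) + I_i(-x, y, z) ],

which makes ``t`` symmetric under the reflection by construction.  Note
the prefactor: as written the template is the symmetrized *sum* per
control, i.e. twice the symmetrized mean.  It is implemented exactly in
that form (the downstream linear fit is covariant under a global scale);
``halve=True`` divides by 2 for users expecting a true average.

Masks:

* striatal mask — voxels of a mean-control image at or above a fraction
  (default 0.45) of its maximum; on DaT images this selects the striatum;
* brain mask — support of the template above a small fraction (default
  0.10) of its maximum, reduced to the largest 6-connected component with
  interior holes filled;
* non-specific mask — brain minus striatum, the reference region for the
  normalizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import NC, BinaryMask, Cohort, Volume, reflect_x


@dataclass
class Template:
    """The symmetric control template and the number of controls behind it."""

    volume: Volume
    n_controls: int

    def __post_init__(self) -> None:
        data = self.volume.data
        if not np.allclose(data, reflect_x(data), rtol=1e-10, atol=0.0):
            raise ValueError("template is not symmetric under the hemisphere reflection")


@dataclass
class MaskSet:
    """Striatal (SR), brain and non-specific (NS) masks on one lattice."""

    striatal: BinaryMask
    brain: BinaryMask
    nonspecific: BinaryMask

    def __post_init__(self) -> None:
        sr, br, ns = self.striatal.data, self.brain.data, self.nonspecific.data
        if not (sr.shape == br.shape == ns.shape):
            raise ValueError("masks are not grid-compatible")
        if np.any(sr & ~br):
            raise ValueError("striatal mask extends outside the brain mask")
        if np.any(sr & ns):
            raise ValueError("striatal and non-specific masks overlap")
        if not np.array_equal(ns, br & ~sr):
            raise ValueError("non-specific mask is not brain minus striatum")


def build_template(controls: Cohort, halve: bool = False) -> Template:
    """Average each control with its hemisphere reflection into a template.

    Parameters
    ----------
    controls:
        Cohort of normal-control volumes (any non-NC member is an error).
    halve:
        Divide the literal symmetrized sum by 2, turning the template into
        a true symmetrized average.
    """
    if len(controls) == 0:
        raise ValueError("empty control set")
    if any(lab != NC for lab in controls.labels):
        raise ValueError("template controls must all be labelled NC")
    acc = np.zeros(controls.shape, dtype=np.float64)
    for _, _, vol in controls:
        acc += vol.data + reflect_x(vol.data)
    acc /= len(controls)
    if halve:
        acc /= 2.0
    return Template(Volume(acc, controls.volumes[0].affine), len(controls))


def striatal_mask(mean_nc: Volume, fraction: float = 0.45) -> BinaryMask:
    """Threshold a mean-control image at ``fraction * max`` (inclusive)."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    peak = float(mean_nc.data.max())
    if peak <= 0:
        raise ValueError("degenerate ROI source: non-positive maximum intensity")
    return BinaryMask(mean_nc.data >= fraction * peak, mean_nc.affine)


def brain_mask(template_volume: Volume, brain_fraction: float = 0.10) -> BinaryMask:
    """Brain support: threshold, keep largest 6-connected component, fill holes."""
    if not (0 < brain_fraction <= 1):
        raise ValueError("brain_fraction must lie in (0, 1]")
    peak = float(template_volume.data.max())
    if peak <= 0:
        raise ValueError("degenerate brain source: non-positive maximum intensity")
    support = template_volume.data >= brain_fraction * peak
    labelled, n_comp = ndimage.label(support)  # default structure = 6-connectivity
    if n_comp > 1:
        sizes = ndimage.sum_labels(support, labelled, index=np.arange(1, n_comp + 1))
        support = labelled == (1 + int(np.argmax(sizes)))
    support = ndimage.binary_fill_holes(support)
    return BinaryMask(support, template_volume.affine)


def nonspecific_mask(brain: BinaryMask, striatal: BinaryMask) -> BinaryMask:
    """Set difference brain \\ striatum; the striatum must lie inside the brain."""
    if brain.shape != striatal.shape:
        raise ValueError("grid mismatch between brain and striatal masks")
    outside = int((striatal.data & ~brain.data).sum())
    if outside:
        raise ValueError(f"{outside} striatal voxels lie outside the brain mask")
    return BinaryMask(brain.data & ~striatal.data, brain.affine)


def build_masks(
    template: Template,
    mean_nc: Volume,
    striatal_fraction: float = 0.45,
    brain_fraction: float = 0.10,
) -> MaskSet:
    """Derive the full mask set from a template and a mean-control image.

    The striatal mask is cropped to the brain support (on smooth phantoms
    and real DaT images it already lies inside it).
    """
    brain = brain_mask(template.volume, brain_fraction)
    sr = striatal_mask(mean_nc, striatal_fraction)
    sr = BinaryMask(sr.data & brain.data, sr.affine)
    if sr.count == 0:
        raise ValueError("striatal mask is empty after cropping to the brain")
    return MaskSet(striatal=sr, brain=brain, nonspecific=nonspecific_mask(brain, sr))
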