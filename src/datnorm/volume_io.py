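"""Volume and mask containers with NIfTI-1 I/O on a fixed lattice.

Every image in the toolkit lives on the same voxel lattice (the canonical
co-registered DaTSCAN grid is 73 x 73 x 45, but any shape works).  Array
axis 0 is the left-right (hemisphere) axis; the hemisphere midplane
reflection maps index ``i -> D0 - 1 - i``, so for an odd first extent the
central sagittal column is self-mapped.  Intensities are always held as
double-precision floats regardless of the on-disk dtype, because the
downstream least-squares normalizations are sums over ~1e5 voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: class labels used throughout the toolkit
NC = "NC"
PS = "PS"


def reflect_x(data: np.ndarray) -> np.ndarray:
    """Reflect a 3-D array about the hemisphere midplane (axis 0)."""
    return data[::-1, :, :]


@dataclass
class Volume:
    """A 3-D scalar intensity grid.

    Parameters
    ----------
    data:
        3-D array of finite intensities (arbitrary count units); converted
        to float64 on construction.
    affine:
        Voxel-to-world affine, kept only so that written NIfTI files carry
        sensible geometry.  Identity by default.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def compatible_with(self, other: "Volume | BinaryMask") -> bool:
        """Two grids are compatible iff their shapes are identical."""
        return self.shape == other.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())


@dataclass
class BinaryMask:
    """A boolean region on the volume lattice (striatum, brain, ...)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D mask, got {self.data.ndim}-D")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def count(self) -> int:
        """Number of voxels inside the region."""
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def coordinates(self) -> np.ndarray:
        """(count, 3) voxel indices of the region, in C (lexicographic) order."""
        return np.argwhere(self.data).astype(np.float64)


@dataclass
class Cohort:
    """An ordered set of grid-compatible volumes with class labels and ids."""

    volumes: list[Volume]
    labels: list[str]
    ids: list[str]

    def __post_init__(self) -> None:
        if not (len(self.volumes) == len(self.labels) == len(self.ids)):
            raise ValueError("volumes, labels and ids must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("subject ids must be unique")
        bad = sorted(set(self.labels) - {NC, PS})
        if bad:
            raise ValueError(f"unknown class labels: {bad}")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) > 1:
            raise ValueError(f"volumes are not grid-compatible: shapes {shapes}")

    def __len__(self) -> int:
        return len(self.volumes)

    def __iter__(self) -> Iterator[tuple[str, str, Volume]]:
        return iter(zip(self.ids, self.labels, self.volumes))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    def subset(self, label: str) -> "Cohort":
        """Restrict to one class (e.g. the normal controls)."""
        keep = [i for i, lab in enumerate(self.labels) if lab == label]
        return Cohort(
            [self.volumes[i] for i in keep],
            [self.labels[i] for i in keep],
            [self.ids[i] for i in keep],
        )

    def mean_volume(self) -> Volume:
        """Plain voxel-wise average of all volumes."""
        stack = np.stack([v.data for v in self.volumes])
        return Volume(stack.mean(axis=0), self.volumes[0].affine)

    def with_volumes(self, volumes: Sequence[Volume]) -> "Cohort":
        """Same subjects, replaced images (e.g. after a normalization)."""
        return Cohort(list(volumes), list(self.labels), list(self.ids))


def read_volume(path: str | Path) -> Volume:
    """Read a 3-D NIfTI-1 volume.

    Negative stored values are clipped to 0 (counts cannot be negative); a
    warning is logged when this happens.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various subclasses
        raise IOError(f"unreadable NIfTI file: {path}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"expected 3-D volume, got {data.ndim}-D: {path}")
    n_neg = int((data < 0).sum())
    if n_neg:
        logger.warning("clipped %d negative voxels to 0 in %s", n_neg, path)
        data = np.clip(data, 0.0, None)
    return Volume(data, np.asarray(img.affine))


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (float64 payload)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(volume.data, volume.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a mask stored as a 0/1 integer NIfTI volume."""
    vol = read_volume(path)
    return BinaryMask(vol.data > 0.5, vol.affine)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


def mask_mean(volume: Volume, mask: BinaryMask) -> float:
    """Arithmetic mean of the intensities inside a region.

    This is the "mean count per voxel in the volume of interest" used by the
    binding-ratio quantification.
    """
    if volume.shape != mask.shape:
        raise ValueError(f"grid mismatch: volume {volume.shape} vs mask {mask.shape}")
    if mask.count == 0:
        raise ValueError("empty region")
    return float(volume.data[mask.data].mean())


def read_cohort(csv_path: str | Path) -> Cohort:
    """Load a cohort from a CSV with columns ``id,label,path``.

    Relative image paths are resolved against the CSV's directory.
    """
    csv_path = Path(csv_path)
    table = pd.read_csv(csv_path)
    missing = {"id", "label", "path"} - set(table.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    volumes = []
    for p in table["path"]:
        p = Path(p)
        if not p.is_absolute():
            p = csv_path.parent / p
        volumes.append(read_volume(p))
    return Cohort(volumes, [str(x) for x in table["label"]], [str(x) for x in table["id"]])


def write_cohort(cohort: Cohort, out_dir: str | Path, csv_name: str = "cohort.csv") -> Path:
    """Write each volume as ``<id>.nii.gz`` plus the index CSV; returns CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, label, vol in cohort:
        fname = f"{sid}.nii.gz"
        write_volume(vol, out_dir / fname)
        rows.append({"id": sid, "label": label, "path": fname})
    csv_path = out_dir / csv_name
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path
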