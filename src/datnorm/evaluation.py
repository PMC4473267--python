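"""Cohort intensity-homogeneity metrics: KL divergence and histogram bands.

After a successful intensity normalization, the non-specific-region
histograms of different subjects should collapse onto each other.  Two
summaries quantify this:

* the Kullback-Leibler divergence D_KL(P || Q) = sum_i P(i) ln(P(i)/Q(i))
  of each subject's histogram Q from the mean-image histogram P, averaged
  per class;
* the per-bin mean histogram with a 25th-75th percentile band across
  subjects (the inter-subject variability "error bars").

Histograms share one bin grid over [0, cohort max] inside the evaluation
mask; out-of-range values are clipped into the end bins, and every bin
receives a tiny epsilon before renormalization so the logarithm is always
defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume_io import NC, PS, BinaryMask, Cohort, Volume

#: per-bin additive smoothing applied before renormalization
SMOOTHING = 1e-10


@dataclass
class RegionHistogram:
    """A smoothed, normalized intensity histogram of one region."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.probabilities) != len(self.bin_edges) - 1:
            raise ValueError("need exactly one probability per bin")


def region_histogram(
    volume: Volume, mask: BinaryMask, bin_edges: np.ndarray
) -> RegionHistogram:
    """Histogram of the masked intensities on the given shared bin grid."""
    if volume.shape != mask.shape:
        raise ValueError("grid mismatch between volume and mask")
    if mask.count == 0:
        raise ValueError("empty region")
    edges = np.asarray(bin_edges, dtype=np.float64)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    values = np.clip(volume.data[mask.data], edges[0], edges[-1])
    counts, _ = np.histogram(values, bins=edges)
    probs = counts.astype(np.float64) + SMOOTHING
    probs /= probs.sum()
    return RegionHistogram(edges, probs)


def kl_divergence(p: RegionHistogram, q: RegionHistogram) -> float:
    """D_KL(P || Q) = sum_i P(i) ln(P(i)/Q(i)), natural log."""
    if not np.array_equal(p.bin_edges, q.bin_edges):
        raise ValueError("histograms use different bin edges")
    return float(np.sum(p.probabilities * np.log(p.probabilities / q.probabilities)))


@dataclass
class CohortKLSummary:
    """Per-subject divergences with per-class and pooled mean +- sd."""

    values: np.ndarray  # one D_KL per subject
    labels: list[str]
    ids: list[str]

    def per_subject(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "label": self.labels, "kl": self.values})

    def summary(self) -> pd.DataFrame:
        """Rows NC, PS, NC+PS; columns mean and sd (sample sd, ddof=1)."""
        labels = np.asarray(self.labels)
        rows = []
        for name, sel in ((NC, labels == NC), (PS, labels == PS), ("NC+PS", slice(None))):
            vals = self.values[sel]
            rows.append(
                {
                    "class": name,
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                }
            )
        return pd.DataFrame(rows)

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def shared_bin_edges(cohort: Cohort, mask: BinaryMask, n_bins: int = 50) -> np.ndarray:
    """Bin grid [0, cohort max inside the mask] shared by all subjects."""
    hi = max(float(v.data[mask.data].max()) for v in cohort.volumes)
    if hi <= 0:
        raise ValueError("cohort has no positive intensity inside the mask")
    return np.linspace(0.0, hi, n_bins + 1)


def cohort_kl(
    cohort: Cohort,
    mask: BinaryMask,
    n_bins: int = 50,
    per_class_reference: bool = False,
) -> CohortKLSummary:
    """D_KL of each subject against the cohort mean-image histogram.

    The reference P is the histogram of the voxel-wise mean image (pooled
    across classes by default; ``per_class_reference`` uses each class's
    own mean image instead).  Each subject's histogram is the Q.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects")
    edges = shared_bin_edges(cohort, mask, n_bins)
    references: dict[str, RegionHistogram] = {}
    if per_class_reference:
        for label in (NC, PS):
            sub = cohort.subset(label)
            if len(sub):
                references[label] = region_histogram(sub.mean_volume(), mask, edges)
    else:
        pooled = region_histogram(cohort.mean_volume(), mask, edges)
        references = {NC: pooled, PS: pooled}
    values = np.array(
        [
            kl_divergence(references[label], region_histogram(vol, mask, edges))
            for _, label, vol in cohort
        ]
    )
    return CohortKLSummary(values, list(cohort.labels), list(cohort.ids))


def histogram_band(
    cohort: Cohort, mask: BinaryMask, n_bins: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin mean and 25th/75th percentile voxel counts across subjects.

    Returns ``(bin_edges, mean, p25, p75)``; the band width is the
    inter-subject intensity variability a normalization should shrink.
    """
    edges = shared_bin_edges(cohort, mask, n_bins)
    counts = np.stack(
        [
            np.histogram(np.clip(v.data[mask.data], edges[0], edges[-1]), bins=edges)[0]
            for v in cohort.volumes
        ]
    ).astype(np.float64)
    return (
        edges,
        counts.mean(axis=0),
        np.percentile(counts, 25, axis=0),
        np.percentile(counts, 75, axis=0),
    )
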