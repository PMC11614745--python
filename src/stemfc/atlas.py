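"""Probabilistic-atlas utilities.

Thresholding of probabilistic label volumes into (possibly overlapping) binary
masks, overlap accounting, volume parcellation with a mean reducer, and
temporal signal-to-noise ratio.  Volumes are handled as NIfTI-1 images via
nibabel; in-memory arrays are accepted everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .exceptions import ParameterError
from .preprocess import TimeSeriesMatrix

__all__ = [
    "ProbabilisticAtlas",
    "LabelMasks",
    "ParcellatedMap",
    "threshold_atlas",
    "count_label_overlap",
    "parcellate_volume",
    "compute_tsnr",
    "parcel_centroids",
]


@dataclass
class ProbabilisticAtlas:
    """4-D (x, y, z, label) array of per-voxel label probabilities in [0, 1]."""

    probabilities: np.ndarray
    label_names: list[str]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 4:
            raise ParameterError("probabilities must be a 4-D (x, y, z, label) array")
        if self.probabilities.shape[3] != len(self.label_names):
            raise ParameterError("label_names length must equal the 4th dimension")
        if self.probabilities.min() < 0 or self.probabilities.max() > 1:
            raise ParameterError("probabilities must lie in [0, 1]")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.probabilities.astype(np.float32), self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image | str, label_names: list[str]) -> "ProbabilisticAtlas":
        if isinstance(img, str):
            img = nib.load(img)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float), label_names,
                   voxel_size=zooms, affine=np.asarray(img.affine))


@dataclass
class LabelMasks:
    """Boolean 3-D mask per label, produced by thresholding an atlas."""

    masks: np.ndarray  # (x, y, z, label) boolean
    label_names: list[str]
    threshold_used: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def n_labels(self) -> int:
        return len(self.label_names)


@dataclass
class ParcellatedMap:
    """Per-label reduced values (scalar per label, or label x time for 4-D input)."""

    values: np.ndarray
    label_names: list[str]
    reducer_name: str = "mean"


def threshold_atlas(atlas: ProbabilisticAtlas, threshold: float = 0.35) -> LabelMasks:
    """Binarize each label's probability map at an inclusive threshold.

    A voxel whose probability equals the threshold is included.  Labels may
    overlap: bordering structures can both exceed the threshold at the same
    voxel.  An empty mask triggers a warning naming the label, not an error.
    """
    if not (0.0 < threshold < 1.0):
        raise ParameterError(f"threshold must lie in (0, 1), got {threshold}")
    masks = atlas.probabilities >= threshold
    for li, name in enumerate(atlas.label_names):
        if not masks[..., li].any():
            warnings.warn(f"label {name!r} has an empty mask at threshold {threshold}",
                          stacklevel=2)
    return LabelMasks(masks, list(atlas.label_names), threshold, atlas.affine)


def count_label_overlap(masks: LabelMasks) -> dict[int, int]:
    """Histogram of labels-per-voxel over voxels carrying at least one label.

    Conservation: sum_k k * count(k) equals the summed mask sizes.
    """
    per_voxel = masks.masks.sum(axis=3)
    counts = np.bincount(per_voxel[per_voxel > 0].ravel())
    return {int(k): int(c) for k, c in enumerate(counts) if k >= 1 and c > 0}


def parcellate_volume(volume: np.ndarray | nib.Nifti1Image, masks: LabelMasks,
                      reducer: str = "mean") -> ParcellatedMap:
    """Reduce a 3-D (or 4-D time series) volume to per-label means.

    Overlapping voxels contribute to every label containing them (no
    probabilistic weighting: masks are binary).  An empty mask yields NaN for
    that label; the run continues.
    """
    if reducer != "mean":
        raise ParameterError(f"unsupported reducer {reducer!r}")
    if isinstance(volume, nib.Nifti1Image):
        volume = np.asarray(volume.dataobj, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if volume.shape[:3] != masks.masks.shape[:3]:
        raise ParameterError("volume and mask grids differ")
    is4d = volume.ndim == 4
    out_shape = (masks.n_labels, volume.shape[3]) if is4d else (masks.n_labels,)
    values = np.full(out_shape, np.nan)
    for li in range(masks.n_labels):
        m = masks.masks[..., li]
        if not m.any():
            continue
        values[li] = volume[m].mean(axis=0)
    return ParcellatedMap(values, list(masks.label_names), "mean")


def parcel_centroids(masks: LabelMasks) -> np.ndarray:
    """World-coordinate centroid per label: mean of in-mask voxel coordinates
    pushed through the affine.  Empty masks give NaN rows."""
    cents = np.full((masks.n_labels, 3), np.nan)
    for li in range(masks.n_labels):
        idx = np.argwhere(masks.masks[..., li])
        if idx.size == 0:
            continue
        homog = np.column_stack([idx, np.ones(len(idx))])
        world = homog @ masks.affine.T
        cents[li] = world[:, :3].mean(axis=0)
    return cents


def compute_tsnr(ts: TimeSeriesMatrix) -> np.ndarray:
    """Temporal SNR per node: mean / population standard deviation.

    Must be computed on the raw series before demeaning.  Nodes with zero
    standard deviation return NaN.
    """
    if ts.n_timepoints < 2:
        raise ParameterError("tSNR requires at least 2 timepoints")
    mean = ts.values.mean(axis=1)
    std = ts.values.std(axis=1)  # population (n) convention
    out = np.full(ts.n_nodes, np.nan)
    ok = std > 0
    out[ok] = mean[ok] / std[ok]
    return out
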