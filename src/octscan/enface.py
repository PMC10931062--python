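"""Laterality normalization and en-face projection of segmentation volumes.

Left eyes are mirrored along the fast axis so the nasal side always points
to +x, then each biomarker is projected along depth into a per-column voxel
count and binarized to a presence map: downstream analyses care only about
*whether* fluid is present at an en-face location, not how much.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .volume_io import BIOMARKER_LABELS, Biomarker, ScanGeometry, SegVolume, as_biomarker

__all__ = ["ColumnCountMap", "EnFaceMap", "mirror_if_left", "project", "binarize", "enface_map"]


@dataclass
class ColumnCountMap:
    """Foreground voxels per A-scan column, indexed ``[y=bscan, x=ascan]``."""

    counts: np.ndarray
    biomarker: Biomarker
    eye_id: str
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = (self.geometry.n_bscans, self.geometry.n_ascans)
        if self.counts.shape != expected:
            raise ValidationError(
                f"counts shape {self.counts.shape} != (n_bscans, n_ascans) {expected}"
            )
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")


@dataclass
class EnFaceMap:
    """Binary per-column presence of one biomarker in the en-face plane."""

    presence: np.ndarray
    biomarker: Biomarker
    eye_id: str
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        expected = (self.geometry.n_bscans, self.geometry.n_ascans)
        if self.presence.shape != expected:
            raise ValidationError(
                f"presence shape {self.presence.shape} != (n_bscans, n_ascans) {expected}"
            )
        if self.presence.dtype != bool:
            vals = np.unique(self.presence)
            if not set(vals.tolist()) <= {0, 1}:
                raise ValidationError("presence must be binary")
            self.presence = self.presence.astype(bool)


def mirror_if_left(v: SegVolume) -> SegVolume:
    """Orientation-normalize: flip left eyes along the fast axis (x → n−1−x).

    Right eyes keep their label array untouched; both come back flagged
    ``normalized``, so the operation is idempotent.
    """
    if v.normalized:
        return v
    labels = v.labels[:, :, ::-1].copy() if v.laterality == "left" else v.labels
    return dataclasses.replace(v, labels=labels, normalized=True)


def project(v: SegVolume, biomarker: "Biomarker | str") -> ColumnCountMap:
    """Sum the biomarker's voxels along depth (z) into an en-face count map.

    The pooled IRF∪SRF biomarker counts voxels carrying either fluid label;
    with one label per voxel the two are disjoint, so counts add.
    """
    b = as_biomarker(biomarker)
    codes = BIOMARKER_LABELS[b]
    mask = np.isin(v.labels, codes)
    counts = mask.sum(axis=1)
    return ColumnCountMap(counts=counts, biomarker=b, eye_id=v.eye_id, geometry=v.geometry)


def binarize(m: ColumnCountMap, min_column_voxels: int = 1) -> EnFaceMap:
    """Presence map: 1 where a column holds at least ``min_column_voxels`` voxels.

    The default threshold of one voxel encodes presence-only binarization —
    no minimum-size filtering.
    """
    if min_column_voxels < 1:
        raise ValidationError("min_column_voxels must be >= 1")
    return EnFaceMap(
        presence=m.counts >= min_column_voxels,
        biomarker=m.biomarker,
        eye_id=m.eye_id,
        geometry=m.geometry,
    )


def enface_map(
    v: SegVolume, biomarker: "Biomarker | str", min_column_voxels: int = 1
) -> EnFaceMap:
    """Convenience pipeline: mirror_if_left → project → binarize."""
    return binarize(project(mirror_if_left(v), biomarker), min_column_voxels)
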