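"""Bone segmentation by global thresholding and connected-component cleanup.

The commercial workflow this pipeline reproduces leaves its segmentation
operator unspecified; here the minimal reproducible stand-in is used: a
fixed HU threshold, 26-connected component labelling with small-component
suppression, keep-largest policy, and a one-voxel morphological closing to
seal the subchondral shell.  The default threshold of 250 HU sits above soft
tissue and below trabecular bone on a standard CT scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import CtVolume

#: 26-neighbourhood for component labelling, 6-neighbourhood for surfaces.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)

DEFAULT_THRESHOLD_HU = 250.0


@dataclass
class BoneMask:
    """Binary voxel mask of the segmented bone, congruent with its volume."""

    mask: np.ndarray
    threshold_hu: float
    component_policy: str
    spacing_mm: tuple[float, float, float]
    axis_labels: tuple[str, str, str]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.mask.any():
            raise ValueError("BoneMask must be non-empty")


def segment_bone(
    volume: CtVolume,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    min_component_voxels: int = 27,
    keep: str = "largest",
    closing: bool = True,
) -> BoneMask:
    """Threshold a CT volume and keep the dominant bone component.

    Voxels with HU >= ``threshold_hu`` are candidate bone.  26-connected
    components smaller than ``min_component_voxels`` are dropped; with
    ``keep="largest"`` (default) only the largest surviving component is
    retained, with ``keep="all"`` every survivor is.  A one-voxel binary
    closing (6-connected ball) seals pinholes in the shell.

    Raises
    ------
    ValueError
        If no voxel reaches the threshold or no component survives
        (``"no bone found at threshold ..."``).
    """
    if keep not in ("largest", "all"):
        raise ValueError(f"keep must be 'largest' or 'all', got {keep!r}")
    binary = volume.voxels >= threshold_hu
    if not binary.any():
        raise ValueError(f"no bone found at threshold {threshold_hu} HU")
    labels, n = ndimage.label(binary, structure=_STRUCT_26)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    valid = np.flatnonzero(counts >= min_component_voxels)
    if valid.size == 0:
        raise ValueError(
            f"no bone found at threshold {threshold_hu} HU: all {n} components are "
            f"smaller than {min_component_voxels} voxels"
        )
    if keep == "largest":
        keep_labels = np.array([valid[np.argmax(counts[valid])]])
    else:
        keep_labels = valid
    mask = np.isin(labels, keep_labels)
    if closing:
        mask = ndimage.binary_closing(mask, structure=_STRUCT_6)
    return BoneMask(mask, float(threshold_hu), keep, volume.spacing_mm, volume.axis_labels)


def extract_outer_surface(mask: BoneMask | np.ndarray) -> np.ndarray:
    """Boolean map of mask voxels with at least one 6-connected background
    neighbour (out-of-volume counts as background).

    For a hollow shell this returns both the inner and the outer faces; the
    projection stage distinguishes them by ray order, not here.
    """
    m = mask.mask if isinstance(mask, BoneMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    interior = ndimage.binary_erosion(m, structure=_STRUCT_6, border_value=0)
    return m & ~interior
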