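"""Lesion filling: the counterfactual "no visible lesion" dataset.

Each lesion voxel is replaced by the mean intensity of normal-appearing
white matter (NAWM = white-matter mask minus lesion mask) within the
smallest sphere around it, grown from a configurable initial radius until it
contains a minimum number of reference voxels.  Non-lesion voxels are left
bit-identical; filled voxels never serve as references, so the result does
not depend on fill order.  Optionally, Gaussian noise with the local
reference standard deviation is added to the filled values so their texture
matches the surroundings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .phantoms import CohortManifest, SubjectRecord
from .volume_io import BinaryMask, Volume

__all__ = ["FillConfig", "fill_lesions", "fill_cohort"]


@dataclass(frozen=True)
class FillConfig:
    """Parameters of the growing-sphere local-mean fill."""

    neighborhood_radius: float = 3.0  # initial search radius, voxels
    min_reference_voxels: int = 10
    radius_growth: float = 1.0  # radius increment when too few references
    noise_matching: bool = False  # add N(0, local NAWM sd) to filled values
    seed: int = 0

    def __post_init__(self):
        if self.neighborhood_radius < 1 or self.min_reference_voxels < 1:
            raise ValueError("radius must be >= 1 and min_reference_voxels >= 1")
        if self.radius_growth <= 0:
            raise ValueError("radius_growth must be positive")


def fill_lesions(
    volume: Volume,
    lesion_mask: BinaryMask,
    wm_mask: BinaryMask,
    cfg: FillConfig | None = None,
) -> Volume:
    """Replace lesion voxel intensities by local NAWM means.

    The reference set is ``wm_mask AND NOT lesion_mask``.  For each lesion
    voxel the sphere radius starts at ``neighborhood_radius`` and grows by
    ``radius_growth`` until at least ``min_reference_voxels`` references are
    inside; the voxel gets their mean (plus matched noise if enabled).
    """
    cfg = cfg or FillConfig()
    if lesion_mask.shape != volume.shape or wm_mask.shape != volume.shape:
        raise ValueError("masks must be voxel-aligned with the volume")
    lesion = lesion_mask.data.astype(bool)
    if not lesion.any():
        return Volume(volume.data.copy(), volume.spacing, volume.subject_id)
    reference = wm_mask.data.astype(bool) & ~lesion
    if not reference.any():
        raise ValueError("empty reference set: lesion mask covers all white matter")

    ref_coords = np.argwhere(reference)
    ref_values = volume.data[reference]
    if len(ref_coords) < cfg.min_reference_voxels:
        raise ValueError(
            f"only {len(ref_coords)} reference voxels available, "
            f"{cfg.min_reference_voxels} required"
        )
    tree = cKDTree(ref_coords)
    rng = np.random.default_rng(cfg.seed)

    out = volume.data.copy()
    lesion_coords = np.argwhere(lesion)
    radius = cfg.neighborhood_radius
    # query all lesion voxels at the current radius, growing for stragglers
    pending = np.arange(len(lesion_coords))
    while pending.size:
        hits = tree.query_ball_point(lesion_coords[pending], r=radius)
        still = []
        for row, neighbors in zip(pending, hits):
            if len(neighbors) < cfg.min_reference_voxels:
                still.append(row)
                continue
            vals = ref_values[neighbors]
            fill = float(vals.mean())
            if cfg.noise_matching:
                fill += float(rng.normal(0.0, vals.std()))
            out[tuple(lesion_coords[row])] = fill
        pending = np.asarray(still, dtype=int)
        radius += cfg.radius_growth
    return Volume(out, volume.spacing, volume.subject_id)


def fill_cohort(cohort: CohortManifest, cfg: FillConfig | None = None) -> CohortManifest:
    """Fill every subject's lesions; the result has empty lesion masks.

    White-matter masks come from each record's tissue atlas.  Re-filling an
    already filled cohort is the identity (its lesion masks are empty).
    """
    cfg = cfg or FillConfig()
    filled: list[SubjectRecord] = []
    for rec in cohort.records:
        vol = fill_lesions(rec.volume, rec.lesion_mask, rec.wm_mask(), cfg)
        filled.append(
            SubjectRecord(
                subject_id=rec.subject_id,
                label=rec.label,
                volume=vol,
                lesion_mask=BinaryMask(np.zeros(rec.lesion_mask.shape, dtype=np.uint8)),
                atlas=rec.atlas,
            )
        )
    return CohortManifest(
        records=filled, config=cohort.config, seed=cohort.seed, task=cohort.task + "+filled"
    )
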