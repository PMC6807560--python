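"""Quantitative heatmap analysis.

Implements the lesion-relevance fraction

    lesion_relevance = sum(lm * hm+) / sum(hm+)

with ``lm`` the binary lesion mask and ``hm+`` the positive part of the
relevance map, plus group-average heatmaps, atlas-region relevance profiles
with left/right merging, top-k region ranking by summed absolute group
means, and the lesion-sum vs relevance-sum Pearson correlation with a
permutation test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .relprop import RelevanceMap
from .volume_io import BinaryMask, LabelAtlas

__all__ = [
    "lesion_relevance",
    "relevance_sum",
    "average_heatmap",
    "region_relevance",
    "top_regions",
    "correlate_lesion_relevance",
    "CorrelationResult",
]


def _map_data(heatmap) -> np.ndarray:
    return heatmap.data if isinstance(heatmap, RelevanceMap) else np.asarray(heatmap, float)


def lesion_relevance(heatmap, lesion_mask: BinaryMask | np.ndarray) -> float:
    """Fraction of positive relevance falling inside the lesion mask.

    Always in [0, 1]; 0 for an empty mask.  Raises if the map carries no
    positive relevance at all (nothing to apportion).
    """
    hm = _map_data(heatmap)
    lm = lesion_mask.data if isinstance(lesion_mask, BinaryMask) else np.asarray(lesion_mask)
    if hm.shape != lm.shape:
        raise ValueError(f"shape mismatch: heatmap {hm.shape} vs mask {lm.shape}")
    hm_pos = np.maximum(hm, 0.0)
    total = hm_pos.sum()
    if total <= 0.0:
        raise ValueError("heatmap has no positive relevance to apportion")
    return float((lm * hm_pos).sum() / total)


def relevance_sum(heatmap) -> float:
    """Total signed relevance over all voxels."""
    return float(_map_data(heatmap).sum())


def average_heatmap(heatmaps: list) -> RelevanceMap:
    """Voxelwise arithmetic mean of a non-empty set of same-shaped maps."""
    if not heatmaps:
        raise ValueError("cannot average an empty set of heatmaps")
    arrays = [_map_data(h) for h in heatmaps]
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"heatmaps have mismatching shapes: {shapes}")
    mean = np.mean(arrays, axis=0)
    eps = heatmaps[0].epsilon if isinstance(heatmaps[0], RelevanceMap) else 0.0
    method = heatmaps[0].method if isinstance(heatmaps[0], RelevanceMap) else "mean"
    return RelevanceMap(mean, start_score=float(mean.sum()), method=method, epsilon=eps)


def region_relevance(
    heatmaps: list,
    groups: list,
    atlas: LabelAtlas,
) -> pd.DataFrame:
    """Per-region relevance profile across subjects, split by group.

    For every subject and merged atlas region the mean relevance over the
    region's voxels (all voxels, not only nonzero relevance) is computed;
    the table reports the across-subject mean and sum of these per
    (region, group).  Regions without voxels are excluded with a warning.

    Returns a DataFrame with columns region, group, mean_relevance,
    relevance_sum, n_subjects.
    """
    if len(heatmaps) != len(groups):
        raise ValueError("heatmaps and groups must align")
    # merged region -> member labels -> voxel index
    region_voxels: dict[str, np.ndarray] = {}
    for label in atlas.label_table:
        name = atlas.merged_name(label)
        sel = atlas.data == label
        region_voxels[name] = (
            sel if name not in region_voxels else (region_voxels[name] | sel)
        )
    rows = []
    for name, sel in sorted(region_voxels.items()):
        if not sel.any():
            warnings.warn(f"atlas region {name!r} has zero voxels; excluded")
            continue
        per_subject = {}
        for hm, grp in zip(heatmaps, groups):
            data = _map_data(hm)
            if data.shape != atlas.shape:
                raise ValueError("heatmap not aligned to atlas grid")
            per_subject.setdefault(grp, []).append(float(data[sel].mean()))
        for grp, vals in per_subject.items():
            rows.append(
                dict(
                    region=name,
                    group=grp,
                    mean_relevance=float(np.mean(vals)),
                    relevance_sum=float(np.sum(vals)),
                    n_subjects=len(vals),
                )
            )
    return pd.DataFrame(rows)


def top_regions(table: pd.DataFrame, k: int = 30) -> list[str]:
    """Rank regions by the summed absolute group-mean relevance.

    Sorting key: ``sum over groups of |mean_relevance|`` descending, ties
    broken lexicographically by region name.  ``k=30`` is the conventional
    selection size for region profiles.
    """
    pivot = table.pivot_table(
        index="region", columns="group", values="mean_relevance", aggfunc="mean"
    )
    if pivot.isna().any().any():
        raise ValueError("every region needs a mean for every group")
    score = pivot.abs().sum(axis=1)
    if k > len(score):
        raise ValueError(f"k={k} exceeds the {len(score)} available regions")
    order = sorted(score.index, key=lambda r: (-score[r], r))
    return order[:k]


@dataclass
class CorrelationResult:
    pearson_r: float
    p_value: float
    n_permutations: int
    exact: bool
    pairs: np.ndarray  # (n, 2) lesion_sum, relevance_sum

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12):
            raise ValueError("pearson r outside [-1,1]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value outside (0,1]")


def correlate_lesion_relevance(
    pairs,
    n_perm: int = 1000,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson correlation of per-subject (lesion sum, relevance sum) pairs
    with a two-sided permutation test on |r|.

    The lesion sum is the count of lesion-mask voxels; the relevance sum the
    signed heatmap total.  One margin is randomly permuted; the p-value uses
    the add-one estimator ``(1 + #{|r*| >= |r|}) / (1 + n_perm)`` so it can
    never be zero.  When ``n!`` does not exceed ``n_perm`` all permutations
    are enumerated instead and the p-value is the exact fraction
    ``#{|r*| >= |r|} / n!`` (the identity permutation makes it positive).
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    x, y = arr[:, 0], arr[:, 1]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one margin; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)

    # centred/normalized y so each permuted r is a dot product
    xc = (x - x.mean()) / (np.std(x) * np.sqrt(n))
    yc = (y - y.mean()) / (np.std(y) * np.sqrt(n))
    tol = 1e-12
    if math.factorial(n) <= n_perm:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r_perm = float(xc @ yc[list(perm)])
            if abs(r_perm) >= abs(r) - tol:
                count += 1
            total += 1
        return CorrelationResult(r, count / total, total, True, arr)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r_perm = float(xc @ yc[rng.permutation(n)])
        if abs(r_perm) >= abs(r) - tol:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return CorrelationResult(r, p, n_perm, False, arr)
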