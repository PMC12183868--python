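"""Spatial acidosis-heterogeneity metrics.

Quantifies how acidic a tumor is and how that acidity is arranged in space:

* the **acidity score**, a voxel-fraction-weighted three-bin summary of the
  extracellular-pH distribution (1 = uniformly neutral/mildly acidic, 3 =
  uniformly highly acidic);
* a **rim/core** decomposition of the tumor mask by slice-wise morphological
  erosion, with per-region pH statistics;
* the scalar tumor growth rate (volume difference over elapsed days) and the
  semiquantitative immunohistochemistry product score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = [
    "AcidityBins",
    "AcidityResult",
    "RegionMasks",
    "acidity_score",
    "split_rim_core",
    "regional_stats",
    "tumor_growth_rate",
    "ihc_score",
]


@dataclass
class AcidityBins:
    """Three pH_e bins: neutral/mild [7.0, 7.4], moderate [6.7, 7.0),
    highly acidic [6.0, 6.7).

    Shared edges are assigned to the less-acidic bin (half-open downward),
    a deterministic tie-break for the overlapping printed ranges.
    """

    edges: tuple[float, float, float, float] = (6.0, 6.7, 7.0, 7.4)
    labels: tuple[int, int, int] = (3, 2, 1)  # ascending-pH order

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if sorted(self.labels) != [1, 2, 3]:
            raise ValueError("labels must be a permutation of 1..3")

    def assign(self, ph: np.ndarray) -> np.ndarray:
        """Bin label (1-3) per value; values outside the edge range raise."""
        ph = np.asarray(ph, dtype=float)
        lo, hi = self.edges[0], self.edges[-1]
        if np.any((ph < lo) | (ph > hi)):
            raise ValueError(f"pH values outside [{lo}, {hi}]; clamp upstream")
        # np.digitize(right=False): interior edges go to the upper (less
        # acidic) interval, i.e. 6.7 -> moderate, 7.0 -> neutral/mild.
        idx = np.digitize(ph, self.edges[1:3], right=False)
        return np.asarray(self.labels)[idx]


@dataclass
class AcidityResult:
    """Bin occupancy fractions and the weighted acidity score (1-3)."""

    fractions: tuple[float, float, float]  # (f1, f2, f3) by label
    score: float
    n_voxels: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions)
        if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("fractions must be nonnegative and sum to 1")
        if not 1.0 - 1e-9 <= self.score <= 3.0 + 1e-9:
            raise ValueError("score must lie in [1, 3]")


@dataclass
class RegionMasks:
    """Rim/core partition of a tumor mask (disjoint, union = mask)."""

    rim: np.ndarray
    core: np.ndarray
    depth: int
    core_empty: bool = field(default=False)


def acidity_score(ph_values: np.ndarray, bins: AcidityBins | None = None) -> AcidityResult:
    """Acidity score of a set of valid tumor-voxel pH_e values.

    Each voxel is assigned to one of three bins (neutral/mild = 1, moderate
    = 2, highly acidic = 3) and the score is the voxel-fraction-weighted mean
    of the bin labels, ``score = 1*f1 + 2*f2 + 3*f3``.
    """
    bins = bins or AcidityBins()
    ph_values = np.asarray(ph_values, dtype=float).ravel()
    ph_values = ph_values[np.isfinite(ph_values)]
    if ph_values.size == 0:
        raise ValueError("acidity score undefined on empty input")
    labels = bins.assign(ph_values)
    n = labels.size
    fractions = tuple(float(np.mean(labels == k)) for k in (1, 2, 3))
    score = float(np.dot([1.0, 2.0, 3.0], fractions))
    return AcidityResult(fractions=fractions, score=score, n_voxels=n)


def split_rim_core(mask: np.ndarray, depth: int = 2) -> RegionMasks:
    """Partition a tumor mask into rim and core by slice-wise 2-D erosion.

    The core is the erosion of each axial slice by a Euclidean disk of radius
    ``depth`` voxels; the rim is the remainder. Erosion is 2-D because slices
    are typically much thicker than the in-plane voxel size. A fully eroded
    (empty) core is flagged, not an error.
    """
    mask = np.asarray(mask).astype(bool)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not mask.any():
        raise ValueError("empty tumor mask")
    if mask.ndim == 2:
        mask = mask[..., None]
        squeeze = True
    elif mask.ndim == 3:
        squeeze = False
    else:
        raise ValueError("mask must be 2-D or 3-D")

    if depth == 0:
        core = mask.copy()
    else:
        footprint = disk(depth).astype(bool)
        core = np.zeros_like(mask)
        for k in range(mask.shape[2]):
            core[:, :, k] = ndimage.binary_erosion(mask[:, :, k], structure=footprint)
    rim = mask & ~core
    if squeeze:
        core, rim = core[..., 0], rim[..., 0]
    return RegionMasks(rim=rim, core=core, depth=depth, core_empty=not core.any())


def regional_stats(
    ph_map: np.ndarray,
    regions: RegionMasks,
    valid_mask: np.ndarray | None = None,
    bins: AcidityBins | None = None,
) -> dict:
    """Mean pH_e and acidity score computed independently on rim and core.

    ``valid_mask`` restricts to voxels with a usable pH estimate. A region
    with no valid voxels is reported as missing (``None`` entries) rather
    than raising, unless both regions are empty.
    """
    ph_map = np.asarray(ph_map, dtype=float)
    if valid_mask is None:
        valid_mask = np.isfinite(ph_map)
    out: dict = {}
    any_valid = False
    for name, region in (("rim", regions.rim), ("core", regions.core)):
        sel = region & valid_mask & np.isfinite(ph_map)
        if sel.any():
            any_valid = True
            vals = ph_map[sel]
            res = acidity_score(vals, bins)
            out[name] = {
                "mean_ph": float(vals.mean()),
                "acidity_score": res.score,
                "fractions": res.fractions,
                "n_voxels": int(sel.sum()),
            }
        else:
            out[name] = None
    if not any_valid:
        raise ValueError("no valid voxels in either region")
    return out


def tumor_growth_rate(v1: float, v2: float, day1: float, day2: float) -> float:
    """Tumor growth rate: volume change divided by elapsed days (signed)."""
    if day2 <= day1:
        raise ValueError("day2 must be after day1")
    return (v2 - v1) / (day2 - day1)


def ihc_score(intensity: int, area: int) -> int:
    """Semiquantitative immunohistochemistry score: intensity x area, 0-9.

    Both inputs are ordinal grades in {0, 1, 2, 3}.
    """
    for name, v in (("intensity", intensity), ("area", area)):
        if not isinstance(v, (int, np.integer)) or v not in (0, 1, 2, 3):
            raise ValueError(f"{name} grade must be an integer in 0..3")
    return int(intensity * area)
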