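"""Cord compression-volume morphometry.

A binary cord segmentation is reduced to a 1-D profile of cross-sectional
areas (one value per axial slice, inferior → superior).  The compressed
interval is found from the rate of change of that profile: a region opens
where the area falls faster than a threshold fraction of the baseline area
per slice, and closes where the recovering (positive) slope drops back
below the same threshold.  Two volume metrics are computed inside the
detected interval:

* ``cord_volume_in_region`` — the cord volume remaining inside the region
  (the shaded-area reading of the measurement);
* ``volume_deficit`` — the volume lost relative to the uncompressed
  baseline area.

Both are always reported; a subject-level *total compression volume* is the
sum across detected regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "CordMask",
    "AreaProfile",
    "CompressionRegion",
    "load_cord_mask",
    "compute_area_profile",
    "smooth_profile",
    "detect_compression",
    "compression_volume",
    "analyze_mask",
    "total_compression_volume",
]


@dataclass(frozen=True)
class CordMask:
    """Binary cord segmentation with voxel geometry.

    ``voxels`` is indexed ``(x, y, z)`` with axial slices along the last
    axis ordered inferior → superior; ``voxel_dims`` are mm
    (in-plane, in-plane, slice thickness).
    """

    voxels: np.ndarray
    voxel_dims: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary (values 0/1)")
        if not all(d > 0 for d in self.voxel_dims):
            raise ValueError(f"voxel_dims must be positive, got {self.voxel_dims}")
        object.__setattr__(self, "voxels", arr.astype(bool))


@dataclass(frozen=True)
class AreaProfile:
    """Per-slice cord cross-sectional areas (mm²), inferior → superior."""

    areas: np.ndarray
    slice_thickness: float
    smoothed_areas: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        if areas.ndim != 1:
            raise ValueError("areas must be 1-D")
        if (areas < 0).any():
            raise ValueError("areas must be non-negative")
        object.__setattr__(self, "areas", areas)
        if self.smoothed_areas is not None:
            sm = np.asarray(self.smoothed_areas, dtype=float)
            if sm.shape != areas.shape:
                raise ValueError("smoothed_areas must match areas in length")
            object.__setattr__(self, "smoothed_areas", sm)

    @property
    def working_areas(self) -> np.ndarray:
        """Smoothed areas when present, raw areas otherwise."""
        return self.areas if self.smoothed_areas is None else self.smoothed_areas

    def __len__(self) -> int:
        return self.areas.size


@dataclass(frozen=True)
class CompressionRegion:
    """Detected compressed interval with volume metrics.

    Slice limits are 0-based and inclusive.  Volumes are mm³, filled by
    :func:`compression_volume` (``nan`` until then).
    """

    z_lo: int
    z_hi: int
    baseline_area: float
    cord_volume_in_region: float = float("nan")
    volume_deficit: float = float("nan")
    detection_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.z_lo > self.z_hi:
            raise ValueError(f"z_lo {self.z_lo} > z_hi {self.z_hi}")

    @property
    def n_slices(self) -> int:
        return self.z_hi - self.z_lo + 1


def load_cord_mask(path: str) -> CordMask:
    """Read a binary cord mask from a NIfTI file.

    The volume is reoriented to the canonical right-anterior-superior (RAS)
    convention so axial slices always run inferior → superior along axis 2.
    """
    img = nib.as_closest_canonical(nib.load(path))
    dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj)
    return CordMask(voxels=data > 0.5, voxel_dims=dims)


def compute_area_profile(mask: CordMask, source_id: str = "") -> AreaProfile:
    """Cross-sectional area per axial slice: voxel count × in-plane voxel area."""
    dx, dy, dz = mask.voxel_dims
    if not np.isclose(dx, dy):
        warnings.warn(
            f"anisotropic in-plane voxels ({dx} × {dy} mm); areas use their product",
            stacklevel=2,
        )
    counts = mask.voxels.sum(axis=(0, 1))
    return AreaProfile(areas=counts * dx * dy, slice_thickness=dz, source_id=source_id)


def smooth_profile(profile: AreaProfile, window: int = 3) -> AreaProfile:
    """Moving-average smoothing with an odd window; window 1 is the identity.

    Edges use a shrinking (truncated) window so the profile length is
    preserved and constant profiles pass through unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    a = profile.areas
    if window == 1:
        smoothed = a.copy()
    else:
        kernel = np.ones(window)
        num = np.convolve(a, kernel, mode="same")
        den = np.convolve(np.ones_like(a), kernel, mode="same")
        smoothed = num / den
    return replace(profile, smoothed_areas=smoothed)


def _central_diff(a: np.ndarray) -> np.ndarray:
    """Central differences (one-sided at the ends), units: mm² per slice."""
    return np.gradient(a)


def _scan_regions(
    smoothed: np.ndarray,
    raw: np.ndarray,
    baseline: float,
    slope_threshold: float,
    min_extent: int,
    nonzero: np.ndarray,
) -> list[tuple[int, int]]:
    """State machine over the slope of the smoothed profile.

    Opens a region at the first slice whose negative slope magnitude
    exceeds ``slope_threshold × baseline``; after the slope has turned
    positive past the threshold (recovery), closes where it falls back
    below it.  Because smoothing spreads each notch by half a window, the
    limits are then localized on the *raw* profile: the interval is the
    maximal run of slices around the notch whose raw area sits below
    ``baseline − threshold``.
    """
    d = _central_diff(smoothed)
    thr = slope_threshold * baseline
    n = smoothed.size
    regions: list[tuple[int, int]] = []
    state = "outside"
    z_open = 0
    recovering = False
    for z in range(n):
        if not nonzero[z]:
            continue
        if state == "outside":
            if d[z] < -thr:
                state = "inside"
                z_open = z
                recovering = False
        else:
            if d[z] > thr:
                recovering = True
            elif recovering and d[z] < thr:
                regions.append((z_open, z))
                state = "outside"
                if d[z] < -thr:  # immediately entering the next notch
                    state = "inside"
                    z_open = z
                    recovering = False
    if state == "inside" and recovering:
        regions.append((z_open, n - 1))

    below = nonzero & (raw < baseline - thr)
    snapped = []
    for lo, hi in regions:
        # anchor at the deepest raw slice, then grow the below-baseline run
        anchor = lo + int(np.argmin(raw[lo : hi + 1]))
        if not below[anchor]:
            continue
        a = b = anchor
        while a > 0 and below[a - 1]:
            a -= 1
        while b < n - 1 and below[b + 1]:
            b += 1
        snapped.append((a, b))
    snapped = sorted(set(snapped))
    merged: list[tuple[int, int]] = []
    for lo, hi in snapped:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(hi, merged[-1][1]))
        else:
            merged.append((lo, hi))
    return [(lo, hi) for lo, hi in merged if hi - lo + 1 >= min_extent]


def detect_compression(
    profile: AreaProfile,
    slope_threshold: float = 0.05,
    min_extent: int = 3,
) -> list[CompressionRegion]:
    """Detect compressed intervals from the rate of change of cord area.

    Parameters
    ----------
    profile:
        Area profile; its smoothed copy is used when present.
    slope_threshold:
        Slope cutoff as a fraction of the baseline area per slice.
    min_extent:
        Regions spanning fewer slices are discarded.

    Returns
    -------
    Regions sorted inferior → superior with ``baseline_area`` filled; an
    empty list means no compression was detected.

    Notes
    -----
    The baseline area is the median of areas outside all detected regions,
    estimated iteratively: a first pass uses the global median of nonzero
    slices, then the baseline is re-estimated excluding the detected
    regions and detection is repeated once.
    """
    smoothed = profile.working_areas
    raw = profile.areas
    nonzero = smoothed > 0
    if not nonzero.any():
        raise ValueError("profile has no nonzero slices")
    if nonzero.sum() < 2 * min_extent:
        raise ValueError(
            f"profile needs >= {2 * min_extent} nonzero slices, has {int(nonzero.sum())}"
        )

    baseline = float(np.median(raw[nonzero]))
    for _ in range(2):
        spans = _scan_regions(smoothed, raw, baseline, slope_threshold, min_extent, nonzero)
        outside = nonzero.copy()
        for lo, hi in spans:
            outside[lo : hi + 1] = False
        if outside.any():
            baseline = float(np.median(raw[outside]))

    params = {
        "slope_threshold": slope_threshold,
        "min_extent": min_extent,
        "smoothed": profile.smoothed_areas is not None,
    }
    return [
        CompressionRegion(z_lo=lo, z_hi=hi, baseline_area=baseline, detection_params=params)
        for lo, hi in spans
    ]


def compression_volume(profile: AreaProfile, region: CompressionRegion) -> CompressionRegion:
    """Fill a region's volume metrics from the raw (unsmoothed) areas.

    ``cord_volume_in_region`` sums area × slice thickness over the
    interval; ``volume_deficit`` sums ``max(0, baseline − area) ×
    thickness``.  Slices with an empty mask contribute zero area and hence
    the maximal per-slice deficit.
    """
    if region.z_lo < 0 or region.z_hi >= len(profile):
        raise ValueError(
            f"region [{region.z_lo}, {region.z_hi}] outside profile of length {len(profile)}"
        )
    dz = profile.slice_thickness
    a = profile.areas[region.z_lo : region.z_hi + 1]
    volume = float(a.sum() * dz)
    deficit = float(np.maximum(0.0, region.baseline_area - a).sum() * dz)
    return replace(region, cord_volume_in_region=volume, volume_deficit=deficit)


def analyze_mask(
    mask: CordMask,
    window: int = 3,
    slope_threshold: float = 0.05,
    min_extent: int = 3,
    source_id: str = "",
) -> tuple[AreaProfile, list[CompressionRegion]]:
    """Full morphometry pass: profile → smoothing → detection → volumes."""
    profile = smooth_profile(compute_area_profile(mask, source_id=source_id), window=window)
    regions = detect_compression(profile, slope_threshold=slope_threshold, min_extent=min_extent)
    return profile, [compression_volume(profile, r) for r in regions]


def total_compression_volume(regions: list[CompressionRegion]) -> tuple[float, float]:
    """Subject-level (total cord volume in regions, total volume deficit)."""
    if not regions:
        return 0.0, 0.0
    return (
        float(sum(r.cord_volume_in_region for r in regions)),
        float(sum(r.volume_deficit for r in regions)),
    )
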