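"""Semi-automated hindpaw segmentation.

Pipeline: median filter → fixed-HU bone mask (strict > threshold) →
distance-core seed generation → marker-based watershed constrained to the
mask.  All stages are deterministic; the watershed floods a priority
landscape (gradient magnitude of the filtered image, or the inverted
distance transform) with priority ties broken by insertion age (FIFO),
markers seeded in lexicographic (z, y, x) scan order.

Connectivity is the 26-neighborhood throughout.
"""
from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import BinaryMask, LabelMap, VoxelImage

__all__ = [
    "SegmentationParams",
    "SeedSet",
    "SegmentationResult",
    "median_filter",
    "threshold_mask",
    "generate_seeds",
    "watershed_inside_mask",
    "segment_hindpaw",
    "gradient_magnitude",
    "LANDSCAPES",
]

LANDSCAPES = ("gradient", "inverse-distance")

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Stage parameters; the 2500 HU threshold is strict (>)."""

    hu_threshold: float = 2500.0
    median_radius: int = 1
    seed_core_distance_um: float = 35.0
    landscape: str = "gradient"

    def __post_init__(self) -> None:
        if not np.isfinite(self.hu_threshold):
            raise ValueError("hu_threshold must be finite")
        if self.median_radius < 0:
            raise ValueError("median_radius must be ≥ 0")
        if self.seed_core_distance_um < 0:
            raise ValueError("seed_core_distance_um must be ≥ 0")
        if self.landscape not in LANDSCAPES:
            raise ValueError(f"landscape must be one of {LANDSCAPES}")


@dataclass
class SeedSet:
    """Marker voxels as a label image (0 = no marker)."""

    markers: np.ndarray
    provenance: str = "automatic"  # automatic | user-supplied | mixed

    def __post_init__(self) -> None:
        self.markers = np.asarray(self.markers)
        if not np.issubdtype(self.markers.dtype, np.integer):
            raise ValueError("markers must be integer-typed")

    def labels(self) -> np.ndarray:
        u = np.unique(self.markers)
        return u[u > 0]

    @property
    def n_markers(self) -> int:
        return len(self.labels())

    @classmethod
    def from_points(
        cls, shape: tuple[int, int, int], points: list[tuple[int, tuple[int, int, int]]],
        provenance: str = "user-supplied",
    ) -> "SeedSet":
        """Build from (label, (z, y, x)) pairs."""
        m = np.zeros(shape, dtype=np.int32)
        for label, (z, y, x) in points:
            if label < 1:
                raise ValueError(f"marker labels must be ≥ 1, got {label}")
            if m[z, y, x] not in (0, label):
                raise ValueError(f"conflicting markers at voxel {(z, y, x)}")
            m[z, y, x] = label
        return cls(m, provenance)


@dataclass
class SegmentationResult:
    label_map: LabelMap
    seeds: SeedSet
    params: SegmentationParams
    mask_voxel_count: int


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------
def median_filter(image: VoxelImage, median_radius: int = 1) -> VoxelImage:
    """Median over the (2r+1)³ neighborhood, nearest-value edge padding."""
    if median_radius < 0:
        raise ValueError("median_radius must be ≥ 0")
    if median_radius == 0:
        return VoxelImage(image.values.copy(), image.spacing_um)
    size = 2 * median_radius + 1
    out = ndimage.median_filter(image.values, size=size, mode="nearest")
    return VoxelImage(out, image.spacing_um)


def threshold_mask(image: VoxelImage, hu_threshold: float = 2500.0) -> BinaryMask:
    """Bone mask: voxel is bone iff value > hu_threshold (strict)."""
    return BinaryMask(image.values > hu_threshold, image.spacing_um)


def generate_seeds(
    mask: BinaryMask,
    seed_core_distance_um: float = 35.0,
    spacing_um: float | None = None,
    user_seeds: SeedSet | None = None,
    ensure_component_coverage: bool = False,
) -> SeedSet:
    """Distance-core markers.

    Voxels whose Euclidean distance to background is ≥
    ``seed_core_distance_um`` form cores; 26-connected core components
    become markers labeled 1..k in array scan order.  User-supplied markers,
    when given, keep their labels and take precedence; automatic cores that
    touch a user marker's component are dropped and the provenance is
    recorded as ``mixed``.

    With ``ensure_component_coverage`` every mask component that would end
    up without any marker receives one at its interior distance maximum
    (first in scan order), so the subsequent flood labels the whole mask.
    """
    spacing = spacing_um if spacing_um is not None else mask.spacing_um
    m = mask.values
    if not m.any():
        return SeedSet(np.zeros(m.shape, dtype=np.int32), "automatic")
    dist = ndimage.distance_transform_edt(m, sampling=spacing)
    cores = m & (dist >= seed_core_distance_um)
    markers, k = ndimage.label(cores, structure=_STRUCT26)
    markers = markers.astype(np.int32)
    provenance = "automatic"
    if k == 0 and user_seeds is None and not ensure_component_coverage:
        warnings.warn(
            "seed_core_distance leaves no core voxels; returning empty SeedSet",
            stacklevel=2,
        )
        return SeedSet(markers, provenance)

    if user_seeds is not None:
        user = user_seeds.markers
        if user.shape != m.shape:
            raise ValueError("user seed grid shape does not match mask")
        if np.any((user > 0) & ~m):
            raise ValueError("user-supplied marker voxels fall outside the mask")
        # drop automatic markers overlapping any user marker, then renumber
        # the surviving ones above the user label range
        drop = np.unique(markers[(user > 0) & (markers > 0)])
        offset = int(user.max())
        out = np.where(user > 0, user, 0).astype(np.int32)
        next_label = offset + 1
        for auto_label in range(1, k + 1):
            if auto_label in drop:
                continue
            sel = markers == auto_label
            out[sel & (out == 0)] = next_label
            next_label += 1
        markers = out
        provenance = "mixed" if k > 0 else "user-supplied"

    if ensure_component_coverage:
        comp, nc = ndimage.label(m, structure=_STRUCT26)
        covered = np.unique(comp[markers > 0])
        next_label = int(markers.max()) + 1
        for c in range(1, nc + 1):
            if c in covered:
                continue
            sel = comp == c
            flat = np.flatnonzero(sel.ravel())
            best = flat[np.argmax(dist.ravel()[flat])]
            markers.ravel()[best] = next_label
            next_label += 1

    return SeedSet(markers, provenance)


def gradient_magnitude(image: VoxelImage) -> np.ndarray:
    gz, gy, gx = np.gradient(image.values.astype(np.float64))
    return np.sqrt(gz**2 + gy**2 + gx**2)


def _landscape(image: VoxelImage | None, mask: BinaryMask, kind: str) -> np.ndarray:
    if kind == "gradient":
        if image is None:
            raise ValueError("gradient landscape requires an image")
        return gradient_magnitude(image)
    if kind == "inverse-distance":
        return -ndimage.distance_transform_edt(mask.values, sampling=mask.spacing_um)
    raise ValueError(f"unknown landscape {kind!r}")


def priority_flood(
    landscape: np.ndarray, mask: np.ndarray, markers: np.ndarray
) -> np.ndarray:
    """Deterministic marker-based flood of ``landscape`` inside ``mask``.

    Entries are popped in ascending (priority, insertion age) order; a voxel
    takes the label of its first-popped queue entry.  Marker voxels are
    enqueued first, in lexicographic (z, y, x) scan order, so equal-priority
    basins advance in lock step and meet midway (the FIFO age tie-break of
    conventional marker-based watershed); a contested voxel goes to the
    basin whose frontier reached it first.
    """
    shape = mask.shape
    land = np.ascontiguousarray(landscape, dtype=np.float64).ravel()
    mflat = np.ascontiguousarray(mask).ravel()
    out = np.zeros(mask.size, dtype=np.int32)

    nz, ny, nx = shape
    heap: list[tuple[float, int, int, int]] = []
    age = 0
    seed_idx = np.flatnonzero(markers.ravel() > 0)
    mk = markers.ravel()
    for i in seed_idx:
        heapq.heappush(heap, (land[i], age, int(mk[i]), int(i)))
        age += 1

    stride_z, stride_y = ny * nx, nx
    while heap:
        prio, _, label, i = heapq.heappop(heap)
        if out[i]:
            continue
        out[i] = label
        z, rem = divmod(i, stride_z)
        y, x = divmod(rem, stride_y)
        for dz in (-1, 0, 1):
            zz = z + dz
            if zz < 0 or zz >= nz:
                continue
            for dy in (-1, 0, 1):
                yy = y + dy
                if yy < 0 or yy >= ny:
                    continue
                for dx in (-1, 0, 1):
                    if dz == 0 and dy == 0 and dx == 0:
                        continue
                    xx = x + dx
                    if xx < 0 or xx >= nx:
                        continue
                    j = zz * stride_z + yy * stride_y + xx
                    if mflat[j] and not out[j]:
                        heapq.heappush(heap, (land[j], age, label, j))
                        age += 1
    return out.reshape(shape)


def watershed_inside_mask(
    image: VoxelImage | None,
    mask: BinaryMask,
    seeds: SeedSet,
    landscape: str = "gradient",
) -> LabelMap:
    """Expand markers to the edges of each bone, constrained to the mask."""
    if seeds.n_markers == 0:
        raise ValueError("no markers: watershed requires at least one seed")
    if seeds.markers.shape != mask.values.shape:
        raise ValueError("seed grid shape does not match mask")
    outside = (seeds.markers > 0) & ~mask.values
    if outside.any():
        bad = sorted(int(v) for v in np.unique(seeds.markers[outside]))
        raise ValueError(f"markers outside mask: labels {bad}")
    land = _landscape(image, mask, landscape)
    out = priority_flood(land, mask.values, seeds.markers)
    return LabelMap(out, mask.spacing_um)


def segment_hindpaw(
    image: VoxelImage,
    params: SegmentationParams | None = None,
    user_seeds: SeedSet | None = None,
) -> SegmentationResult:
    """Full stage composition with provenance.

    median filter → strict-threshold mask → distance-core seeds (merged
    with any user seeds; every mask component is guaranteed a marker) →
    watershed inside the mask.
    """
    params = params or SegmentationParams()
    filtered = median_filter(image, params.median_radius)
    mask = threshold_mask(filtered, params.hu_threshold)
    seeds = generate_seeds(
        mask,
        params.seed_core_distance_um,
        spacing_um=image.spacing_um,
        user_seeds=user_seeds,
        ensure_component_coverage=True,
    )
    label_map = watershed_inside_mask(filtered, mask, seeds, params.landscape)
    return SegmentationResult(
        label_map=label_map,
        seeds=seeds,
        params=params,
        mask_voxel_count=mask.voxel_count,
    )
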