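"""Synthetic hindpaw micro-CT phantom with known per-bone ground truth.

The phantom is a stylized paw: every bone is a union of spheres/capsules
placed in a hindpaw-like topology (five compartments, medial→lateral digit
ordering, an anterolateral tarsal cluster), not an anatomical mesh.  The
analysis pipeline consumes volumes and labels, so only counts, adjacency
and programmable per-bone volume trajectories need to be faithful.

Erosion is realized by scaling primitive radii; a monotone bisection on the
scale factor calibrates the rasterized voxel count to the requested
fractional volume (±2 %).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import FUSED, UNFUSED, BoneCatalog
from .grid import DEFAULT_SPACING_UM, LabelMap, VoxelImage

__all__ = [
    "Sphere",
    "Capsule",
    "AtlasBone",
    "PhantomAtlas",
    "ErosionTrajectory",
    "GroupSpec",
    "CohortSpec",
    "CohortMember",
    "CohortDataset",
    "build_bone_atlas",
    "apply_erosion_trajectory",
    "render_image",
    "generate_cohort",
    "default_cohort_spec",
    "study_trajectory",
    "DEFAULT_GRID_SHAPE",
    "DEFAULT_BONE_HU",
    "DEFAULT_TISSUE_HU",
    "DEFAULT_NOISE_SD",
    "DEFAULT_BLUR_SIGMA_UM",
]

#: Default phantom grid, (z, y, x) voxels.
DEFAULT_GRID_SHAPE = (100, 160, 120)
# The bone plateau is set well above the 2500 HU mask threshold so that,
# after partial-volume blur, the threshold surface sits ~0.25 voxel outside
# the true bone surface — compensating the ~0.2-voxel convex-surface
# erosion of the 3³ median filter so masks track truth without bias.
DEFAULT_BONE_HU = 7200.0
DEFAULT_TISSUE_HU = 200.0
DEFAULT_NOISE_SD = 100.0
DEFAULT_BLUR_SIGMA_UM = 12.5


# ---------------------------------------------------------------------------
# geometric primitives (coordinates and radii in µm, axis order (z, y, x))
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def scaled(self, s: float) -> "Sphere":
        return Sphere(self.center, self.radius * s)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center)
        return c - self.radius, c + self.radius


@dataclass(frozen=True)
class Capsule:
    """Cylinder with hemispherical caps, from ``a`` to ``b``."""

    a: tuple[float, float, float]
    b: tuple[float, float, float]
    radius: float

    def scaled(self, s: float) -> "Capsule":
        return Capsule(self.a, self.b, self.radius * s)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        p = np.minimum(self.a, self.b)
        q = np.maximum(self.a, self.b)
        return p - self.radius, q + self.radius


Primitive = Sphere | Capsule


def _point_segment_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def _segment_segment_dist(
    a0: np.ndarray, a1: np.ndarray, b0: np.ndarray, b1: np.ndarray
) -> float:
    # dense parametric sampling is robust and plenty accurate for layout QA
    ts = np.linspace(0.0, 1.0, 33)
    pa = a0[None, :] + ts[:, None] * (a1 - a0)[None, :]
    best = math.inf
    for p in pa:
        best = min(best, _point_segment_dist(p, b0, b1))
    pb = b0[None, :] + ts[:, None] * (b1 - b0)[None, :]
    for p in pb:
        best = min(best, _point_segment_dist(p, a0, a1))
    return best


def primitive_distance(p: Primitive, q: Primitive) -> float:
    """Surface-to-surface distance (µm); negative means overlap."""
    if isinstance(p, Sphere) and isinstance(q, Sphere):
        d = float(np.linalg.norm(np.subtract(p.center, q.center)))
    elif isinstance(p, Sphere):
        d = _point_segment_dist(np.asarray(p.center), np.asarray(q.a), np.asarray(q.b))
    elif isinstance(q, Sphere):
        d = _point_segment_dist(np.asarray(q.center), np.asarray(p.a), np.asarray(p.b))
    else:
        d = _segment_segment_dist(
            np.asarray(p.a), np.asarray(p.b), np.asarray(q.a), np.asarray(q.b)
        )
    return d - p.radius - q.radius


def _rasterize(
    prims: tuple[Primitive, ...], shape: tuple[int, int, int], spacing_um: float
) -> np.ndarray:
    """Boolean occupancy of a primitive union on the voxel grid.

    A voxel belongs to the bone iff its center (index * spacing) lies inside
    a primitive.
    """
    out = np.zeros(shape, dtype=bool)
    for prim in prims:
        lo, hi = prim.bounds()
        i0 = np.maximum(np.floor(lo / spacing_um).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / spacing_um).astype(int) + 1, shape)
        if np.any(i0 >= i1):
            continue
        zz = np.arange(i0[0], i1[0])[:, None, None] * spacing_um
        yy = np.arange(i0[1], i1[1])[None, :, None] * spacing_um
        xx = np.arange(i0[2], i1[2])[None, None, :] * spacing_um
        if isinstance(prim, Sphere):
            cz, cy, cx = prim.center
            d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
            inside = d2 <= prim.radius**2
        else:
            a = np.asarray(prim.a, dtype=float)
            ab = np.asarray(prim.b, dtype=float) - a
            denom = float(ab @ ab)
            pz, py, px = zz - a[0], yy - a[1], xx - a[2]
            if denom == 0.0:
                t = 0.0
                d2 = pz**2 + py**2 + px**2
            else:
                t = np.clip((pz * ab[0] + py * ab[1] + px * ab[2]) / denom, 0.0, 1.0)
                d2 = (pz - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (px - t * ab[2]) ** 2
            inside = d2 <= prim.radius**2
        out[i0[0]: i1[0], i0[1]: i1[1], i0[2]: i1[2]] |= inside
    return out


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class AtlasBone:
    bone_id: str
    label: int
    primitives: tuple[Primitive, ...]


@dataclass
class PhantomAtlas:
    bones: tuple[AtlasBone, ...]
    fusion_variant: str
    grid_shape: tuple[int, int, int]
    spacing_um: float = DEFAULT_SPACING_UM
    #: pairs allowed to articulate (placed closer than the 1-voxel rule)
    contact_pairs: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def catalog(self) -> BoneCatalog:
        return BoneCatalog(self.fusion_variant)

    def bone(self, bone_id: str) -> AtlasBone:
        for b in self.bones:
            if b.bone_id == bone_id:
                return b
        raise KeyError(f"atlas has no bone {bone_id!r}")

    def rasterize_bone(self, bone_id: str) -> np.ndarray:
        return _rasterize(self.bone(bone_id).primitives, self.grid_shape, self.spacing_um)

    def rasterize_labels(self) -> LabelMap:
        """Truth label map; bone voxel sets are guaranteed disjoint."""
        out = np.zeros(self.grid_shape, dtype=np.uint16)
        for b in self.bones:
            m = _rasterize(b.primitives, self.grid_shape, self.spacing_um)
            if np.any(out[m] != 0):
                clash = int(np.unique(out[m & (out != 0)])[0])
                raise ValueError(
                    f"bone {b.bone_id!r} overlaps voxels of label {clash}"
                )
            out[m] = b.label
        return LabelMap(out, self.spacing_um)

    def voxel_counts(self) -> dict[str, int]:
        return {
            b.bone_id: int(
                _rasterize(b.primitives, self.grid_shape, self.spacing_um).sum()
            )
            for b in self.bones
        }


def _layout(spacing_um: float) -> dict[str, list[Primitive]]:
    """Stylized hindpaw layout in voxel units, converted to µm.

    Proximal→distal runs along +y, medial→lateral along +x; the tarsal
    cluster sits proximally with the cuboid/calcaneus anterolateral.
    Sesamoid pairs sit plantar (lower z) to each metatarsal head.
    """
    s = spacing_um
    digit_x = [20.0, 40.0, 60.0, 80.0, 100.0]

    def sph(z, y, x, r):
        return Sphere((z * s, y * s, x * s), r * s)

    def cap(z0, y0, x0, z1, y1, x1, r):
        # tilt the axis ~0.5 voxel off-grid in the perpendicular directions:
        # axis-aligned capsules make whole voxel rings flip together as the
        # radius changes, which ruins sub-percent volume control
        a = [z0, y0, x0]
        b = [z1, y1, x1]
        deltas = iter((0.6, 0.4))
        for ax in range(3):
            if a[ax] == b[ax]:
                d = next(deltas, 0.0)
                a[ax] -= d
                b[ax] += d
        return Capsule(
            (a[0] * s, a[1] * s, a[2] * s), (b[0] * s, b[1] * s, b[2] * s), r * s
        )

    prim: dict[str, list[Primitive]] = {
        "Calc": [cap(50, 10, 78, 50, 34, 78, 8.0)],
        "Tal": [sph(50, 22, 52, 8.0)],
        "Cub": [sph(50, 50, 92, 7.0)],
        "Med": [sph(50, 52, 14, 6.0)],
        "Tib": [sph(50, 16, 28, 5.0)],
        "NavLat": [cap(50, 44, 48, 50, 44, 62, 6.0)],
        "IntC": [sph(50, 48, 34, 5.0)],
    }
    for d, x in enumerate(digit_x, start=1):
        y0 = 66 if d == 1 else 64
        y1 = 84 if d == 1 else 86
        prim[f"Met{d}"] = [cap(50, y0, x, 50, y1, x, 5.0)]
        prim[f"PP{d}"] = [cap(50, 106, x, 50, 122, x, 4.5)]
        if d >= 2:
            prim[f"DP{d}"] = [cap(50, 134, x, 50, 144, x, 4.0)]
        prim[f"S{2 * d - 1}"] = [sph(30, 96, x, 4.5)]
        prim[f"S{2 * d}"] = [sph(42, 96, x, 4.5)]
    return prim


_GOLDEN = 0.6180339887498949


def _jitter(label: int, spacing_um: float) -> np.ndarray:
    """Deterministic sub-voxel offset (±0.25 voxel) that de-aligns bone
    centers from the grid so rasterized volume varies smoothly with radius."""
    f = np.array(
        [
            (label * _GOLDEN) % 1.0,
            (label * _GOLDEN * 7) % 1.0,
            (label * _GOLDEN * 13) % 1.0,
        ]
    )
    return (f - 0.5) * 0.5 * spacing_um


def _shift(prim: Primitive, off: np.ndarray) -> Primitive:
    if isinstance(prim, Sphere):
        return Sphere(tuple(np.asarray(prim.center) + off), prim.radius)
    return Capsule(
        tuple(np.asarray(prim.a) + off), tuple(np.asarray(prim.b) + off), prim.radius
    )


def build_bone_atlas(
    fusion_variant: str = UNFUSED,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    spacing_um: float = DEFAULT_SPACING_UM,
    articulate: bool = False,
) -> PhantomAtlas:
    """Build the stylized hindpaw atlas.

    Parameters
    ----------
    fusion_variant:
        ``"unfused"`` gives 31 bones; ``"fused"`` merges the intermediate
        cuneiform geometry into the NavLat entity (30 bones).
    articulate:
        When True the talus is pulled toward the calcaneus so the pair
        articulates within ~2 voxels (hard watershed regime); the pair is
        recorded in ``contact_pairs``.
    """
    catalog = BoneCatalog(fusion_variant)
    prim = _layout(spacing_um)
    if articulate:
        # close the talus-calcaneus gap from ~10 voxels to ~1.5 voxels
        tal = prim["Tal"][0]
        assert isinstance(tal, Sphere)
        prim["Tal"] = [
            Sphere(
                (tal.center[0], tal.center[1], (78 - 8 - 8 - 1.5) * spacing_um),
                tal.radius,
            )
        ]
    contact = frozenset({frozenset({"Tal", "Calc"})}) if articulate else frozenset()

    if fusion_variant == FUSED:
        # relocate the intermediate cuneiform into contact with NavLat and
        # absorb it into that entity
        fused_intc = Sphere(
            (50.0 * spacing_um, 46.0 * spacing_um, 42.0 * spacing_um), 5.0 * spacing_um
        )
        prim["NavLat"] = prim["NavLat"] + [fused_intc]
        prim.pop("IntC")

    bones: list[AtlasBone] = []
    for bone_id in catalog.bone_ids():
        label = catalog.labels[bone_id]
        off = _jitter(label, spacing_um)
        bones.append(
            AtlasBone(bone_id, label, tuple(_shift(p, off) for p in prim[bone_id]))
        )

    atlas = PhantomAtlas(
        tuple(bones), fusion_variant, tuple(grid_shape), spacing_um, contact
    )
    _validate_atlas(atlas)
    return atlas


def _validate_atlas(atlas: PhantomAtlas) -> None:
    extent = (np.asarray(atlas.grid_shape) - 1) * atlas.spacing_um
    for b in atlas.bones:
        for prim in b.primitives:
            lo, hi = prim.bounds()
            if np.any(lo < 0) or np.any(hi > extent):
                raise ValueError(
                    f"grid {atlas.grid_shape} too small for bone {b.bone_id!r}: "
                    f"extent [{lo}, {hi}] µm exceeds grid extent {extent} µm"
                )
        if not _rasterize(b.primitives, atlas.grid_shape, atlas.spacing_um).any():
            raise ValueError(f"bone {b.bone_id!r} rasterizes to zero voxels")
    # pairwise separation: ≥1 voxel of background unless articulating
    for i, p in enumerate(atlas.bones):
        for q in atlas.bones[i + 1:]:
            pair = frozenset({p.bone_id, q.bone_id})
            if pair in atlas.contact_pairs:
                continue
            d = min(
                primitive_distance(pp, qq)
                for pp in p.primitives
                for qq in q.primitives
            )
            if d < atlas.spacing_um:
                raise ValueError(
                    f"bones {p.bone_id!r} and {q.bone_id!r} are separated by "
                    f"{d / atlas.spacing_um:.2f} voxels (<1) and are not a "
                    "declared articulating pair"
                )


# ---------------------------------------------------------------------------
# erosion trajectories
# ---------------------------------------------------------------------------
_SHAPES = ("free", "monotone-decreasing", "u-shaped")


@dataclass
class ErosionTrajectory:
    """Per (group, sex, bone) fractional volume relative to baseline.

    ``fractions`` maps ``(group, sex, bone_id)`` to one fraction per
    timepoint; the first entry must be exactly 1.0.  Bones not listed fall
    back to ``fill_value`` at every timepoint (set ``fill_value=None`` to
    make missing bones an error instead).
    """

    timepoints: tuple[float, ...]
    fractions: dict[tuple[str, str, str], tuple[float, ...]]
    shapes: dict[tuple[str, str, str], str] = field(default_factory=dict)
    fill_value: float | None = 1.0

    def __post_init__(self) -> None:
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValueError("timepoints must be strictly increasing")
        for key, fr in self.fractions.items():
            fr = tuple(float(f) for f in fr)
            self.fractions[key] = fr
            if len(fr) != len(self.timepoints):
                raise ValueError(f"{key}: {len(fr)} fractions for {len(self.timepoints)} timepoints")
            if fr[0] != 1.0:
                raise ValueError(f"{key}: baseline fraction must be exactly 1.0, got {fr[0]}")
            if any(f <= 0 for f in fr):
                raise ValueError(f"{key}: fractions must be > 0")
            shape = self.shapes.get(key, "free")
            if shape not in _SHAPES:
                raise ValueError(f"{key}: unknown shape {shape!r}")
            if shape == "monotone-decreasing" and any(
                b > a for a, b in zip(fr, fr[1:])
            ):
                raise ValueError(f"{key}: not monotone decreasing: {fr}")
            if shape == "u-shaped":
                k = int(np.argmin(fr))
                ok = (
                    0 < k < len(fr) - 1
                    and all(fr[i] > fr[i + 1] for i in range(k))
                    and all(fr[i] < fr[i + 1] for i in range(k, len(fr) - 1))
                )
                if not ok:
                    raise ValueError(
                        f"{key}: u-shaped trajectory needs exactly one interior minimum: {fr}"
                    )

    def fraction(self, group: str, sex: str, bone_id: str, timepoint: float) -> float:
        try:
            ti = self.timepoints.index(float(timepoint))
        except ValueError:
            raise KeyError(f"timepoint {timepoint} not in trajectory") from None
        key = (group, sex, bone_id)
        if key in self.fractions:
            return self.fractions[key][ti]
        if self.fill_value is None:
            raise KeyError(f"no trajectory defined for {key}")
        return self.fill_value


def apply_erosion_trajectory(
    atlas: PhantomAtlas,
    trajectory: ErosionTrajectory,
    group: str,
    sex: str,
    timepoint: float,
    volume_tolerance: float = 0.02,
) -> PhantomAtlas:
    """Scale each bone's primitive radii so its rasterized volume hits the
    trajectory fraction of baseline within ``volume_tolerance``.

    Positions are unchanged; only radii shrink/grow.  The scale factor is
    found by bisection on the (monotone) rasterized voxel count.
    """
    new_bones: list[AtlasBone] = []
    for b in atlas.bones:
        f = trajectory.fraction(group, sex, b.bone_id, timepoint)
        if f <= 0:
            raise ValueError(f"fraction must be > 0, got {f} for {b.bone_id}")
        if f == 1.0:
            new_bones.append(b)
            continue
        base = int(_rasterize(b.primitives, atlas.grid_shape, atlas.spacing_um).sum())
        target = f * base
        scale = _calibrate_scale(b.primitives, atlas.grid_shape, atlas.spacing_um, target)
        prims = tuple(p.scaled(scale) for p in b.primitives)
        got = int(_rasterize(prims, atlas.grid_shape, atlas.spacing_um).sum())
        if got < 1:
            raise ValueError(f"bone {b.bone_id!r} eroded to zero voxels (f={f})")
        if abs(got / base - f) > volume_tolerance:
            raise ValueError(
                f"bone {b.bone_id!r}: achieved fraction {got / base:.4f} outside "
                f"±{volume_tolerance:.0%} of target {f:.4f}"
            )
        new_bones.append(AtlasBone(b.bone_id, b.label, prims))
    return replace(atlas, bones=tuple(new_bones))


def _calibrate_scale(
    prims: tuple[Primitive, ...],
    grid_shape: tuple[int, int, int],
    spacing_um: float,
    target: float,
    iters: int = 40,
) -> float:
    def count(s: float) -> int:
        return int(_rasterize(tuple(p.scaled(s) for p in prims), grid_shape, spacing_um).sum())

    lo, hi = 0.05, 1.8
    best_s, best_err = 1.0, abs(count(1.0) - target)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        c = count(mid)
        err = abs(c - target)
        if err < best_err:
            best_s, best_err = mid, err
        if c < target:
            lo = mid
        else:
            hi = mid
        if best_err == 0:
            break
    return best_s


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------
def render_image(
    atlas: PhantomAtlas,
    noise_sd: float = DEFAULT_NOISE_SD,
    blur_sigma_um: float = DEFAULT_BLUR_SIGMA_UM,
    bone_hu: float = DEFAULT_BONE_HU,
    tissue_hu: float = DEFAULT_TISSUE_HU,
    rng_seed: int = 0,
) -> VoxelImage:
    """Render the atlas to an HU image: binary bone/tissue field, Gaussian
    partial-volume blur, then additive Gaussian noise.  Bit-deterministic
    for a fixed seed."""
    from scipy.ndimage import gaussian_filter

    if bone_hu <= tissue_hu:
        raise ValueError("bone_hu must exceed tissue_hu")
    mask = np.zeros(atlas.grid_shape, dtype=bool)
    for b in atlas.bones:
        mask |= _rasterize(b.primitives, atlas.grid_shape, atlas.spacing_um)
    img = np.where(mask, np.float32(bone_hu), np.float32(tissue_hu)).astype(np.float32)
    if blur_sigma_um > 0:
        img = gaussian_filter(img, sigma=blur_sigma_um / atlas.spacing_um)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape).astype(np.float32)
    return VoxelImage(img.astype(np.float32), atlas.spacing_um)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class GroupSpec:
    name: str
    sex: str
    n_limbs: int


@dataclass
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    timepoints: tuple[float, ...]
    trajectory: ErosionTrajectory
    noise_sd: float = DEFAULT_NOISE_SD
    blur_sigma_um: float = DEFAULT_BLUR_SIGMA_UM
    bone_hu_mean: float = DEFAULT_BONE_HU
    tissue_hu_mean: float = DEFAULT_TISSUE_HU
    fusion_probability: float = 0.5
    rng_seed: int = 0
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    spacing_um: float = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        for g in self.groups:
            if g.n_limbs < 1:
                raise ValueError(f"group {g.name!r}: n_limbs must be ≥ 1")
        tp = tuple(float(t) for t in self.timepoints)
        if list(tp) != sorted(set(tp)):
            raise ValueError("timepoints must be strictly increasing")
        self.timepoints = tp
        if not (self.tissue_hu_mean < 2500.0 < self.bone_hu_mean):
            raise ValueError(
                "bone/tissue HU means must straddle the 2500 HU threshold "
                f"(got tissue {self.tissue_hu_mean}, bone {self.bone_hu_mean})"
            )
        if not 0.0 <= self.fusion_probability <= 1.0:
            raise ValueError("fusion_probability must be in [0, 1]")

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "groups": [
                {"name": g.name, "sex": g.sex, "n_limbs": g.n_limbs}
                for g in self.groups
            ],
            "timepoints": list(self.timepoints),
            "trajectory": {
                "timepoints": list(self.trajectory.timepoints),
                "fill_value": self.trajectory.fill_value,
                "fractions": [
                    {
                        "group": k[0],
                        "sex": k[1],
                        "bone_id": k[2],
                        "fractions": list(v),
                        "shape": self.trajectory.shapes.get(k, "free"),
                    }
                    for k, v in self.trajectory.fractions.items()
                ],
            },
            "noise_sd": self.noise_sd,
            "blur_sigma_um": self.blur_sigma_um,
            "bone_hu_mean": self.bone_hu_mean,
            "tissue_hu_mean": self.tissue_hu_mean,
            "fusion_probability": self.fusion_probability,
            "rng_seed": self.rng_seed,
            "grid_shape": list(self.grid_shape),
            "spacing_um": self.spacing_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        traj = d["trajectory"]
        fractions = {}
        shapes = {}
        for row in traj.get("fractions", []):
            key = (row["group"], row["sex"], row["bone_id"])
            fractions[key] = tuple(row["fractions"])
            if row.get("shape", "free") != "free":
                shapes[key] = row["shape"]
        trajectory = ErosionTrajectory(
            timepoints=tuple(traj["timepoints"]),
            fractions=fractions,
            shapes=shapes,
            fill_value=traj.get("fill_value", 1.0),
        )
        return cls(
            groups=tuple(
                GroupSpec(g["name"], g["sex"], int(g["n_limbs"])) for g in d["groups"]
            ),
            timepoints=tuple(d["timepoints"]),
            trajectory=trajectory,
            noise_sd=float(d.get("noise_sd", DEFAULT_NOISE_SD)),
            blur_sigma_um=float(d.get("blur_sigma_um", DEFAULT_BLUR_SIGMA_UM)),
            bone_hu_mean=float(d.get("bone_hu_mean", DEFAULT_BONE_HU)),
            tissue_hu_mean=float(d.get("tissue_hu_mean", DEFAULT_TISSUE_HU)),
            fusion_probability=float(d.get("fusion_probability", 0.5)),
            rng_seed=int(d.get("rng_seed", 0)),
            grid_shape=tuple(d.get("grid_shape", DEFAULT_GRID_SHAPE)),
            spacing_um=float(d.get("spacing_um", DEFAULT_SPACING_UM)),
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CohortMember:
    limb_id: str
    group: str
    sex: str
    timepoint: float
    fusion_variant: str
    image: VoxelImage
    truth_labels: LabelMap


@dataclass
class CohortDataset:
    members: list[CohortMember]
    design: pd.DataFrame
    truth_volumes: pd.DataFrame
    spec: CohortSpec


def _truth_volume_rows(
    member_meta: dict, label_map: LabelMap, catalog: BoneCatalog
) -> list[dict]:
    counts = label_map.voxel_counts()
    unit_voxels: dict[str, int] = {u: 0 for u in catalog.report_units()}
    for bone_id, label in catalog.labels.items():
        unit_voxels[catalog.report_unit(bone_id)] += counts.get(label, 0)
    vv = label_map.voxel_volume_mm3
    return [
        {**member_meta, "bone_id": u, "voxels": n, "volume_mm3": n * vv}
        for u, n in unit_voxels.items()
    ]


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Generate one image + truth label map per limb × timepoint.

    The whole dataset is a pure function of the spec: the per-limb fusion
    draw and every noise realization come from a single seeded stream.
    """
    master = np.random.default_rng(spec.rng_seed)
    base_atlases = {
        v: build_bone_atlas(v, spec.grid_shape, spec.spacing_um)
        for v in (UNFUSED, FUSED)
    }
    eroded_cache: dict[tuple, PhantomAtlas] = {}

    members: list[CohortMember] = []
    design_rows: list[dict] = []
    volume_rows: list[dict] = []
    for g in spec.groups:
        for li in range(g.n_limbs):
            limb_id = f"{g.name}-{g.sex}-{li + 1:02d}"
            variant = FUSED if master.random() < spec.fusion_probability else UNFUSED
            catalog = base_atlases[variant].catalog()
            for t in spec.timepoints:
                key = (variant, g.name, g.sex, t)
                if key not in eroded_cache:
                    eroded_cache[key] = apply_erosion_trajectory(
                        base_atlases[variant], spec.trajectory, g.name, g.sex, t
                    )
                atlas = eroded_cache[key]
                noise_seed = int(master.integers(0, 2**31 - 1))
                image = render_image(
                    atlas,
                    noise_sd=spec.noise_sd,
                    blur_sigma_um=spec.blur_sigma_um,
                    bone_hu=spec.bone_hu_mean,
                    tissue_hu=spec.tissue_hu_mean,
                    rng_seed=noise_seed,
                )
                truth = atlas.rasterize_labels()
                meta = {
                    "limb_id": limb_id,
                    "group": g.name,
                    "sex": g.sex,
                    "timepoint": t,
                }
                members.append(
                    CohortMember(limb_id, g.name, g.sex, t, variant, image, truth)
                )
                design_rows.append({**meta, "fusion_variant": variant})
                volume_rows.extend(_truth_volume_rows(meta, truth, catalog))

    return CohortDataset(
        members=members,
        design=pd.DataFrame(design_rows),
        truth_volumes=pd.DataFrame(volume_rows),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# stylized study trajectories
# ---------------------------------------------------------------------------
def study_trajectory(timepoints: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)) -> ErosionTrajectory:
    """Programmable erosion patterns echoing the study's qualitative
    structure: healthy controls stay flat; diseased females show an early
    cuboid decline and a late (4→5 month) tarsal collapse; diseased males
    progress slowly with a U-shaped sesamoid course."""
    if len(timepoints) != 4:
        raise ValueError("the stylized study trajectory uses 4 timepoints")
    fr: dict[tuple[str, str, str], tuple[float, ...]] = {}
    shapes: dict[tuple[str, str, str], str] = {}

    # diseased females: early cuboid decline, late tarsal collapse
    fr[("TNF", "F", "Cub")] = (1.0, 0.90, 0.80, 0.60)
    shapes[("TNF", "F", "Cub")] = "monotone-decreasing"
    fr[("TNF", "F", "Tal")] = (1.0, 0.95, 0.88, 0.65)
    shapes[("TNF", "F", "Tal")] = "monotone-decreasing"
    fr[("TNF", "F", "NavLat")] = (1.0, 0.95, 0.90, 0.70)
    fr[("TNF", "F", "IntC")] = (1.0, 0.95, 0.90, 0.70)
    for d in range(1, 6):
        fr[("TNF", "F", f"PP{d}")] = (1.0, 0.85, 0.75, 0.72)
        fr[("TNF", "F", f"Met{d}")] = (1.0, 0.92, 0.85, 0.78)

    # diseased males: slow, shallow declines; sesamoid "U"
    fr[("TNF", "M", "Cub")] = (1.0, 0.95, 0.90, 0.85)
    fr[("TNF", "M", "Tal")] = (1.0, 0.96, 0.92, 0.88)
    for d in range(1, 6):
        fr[("TNF", "M", f"Met{d}")] = (1.0, 0.93, 0.88, 0.84)
    for i in range(1, 11):
        fr[("TNF", "M", f"S{i}")] = (1.0, 0.80, 0.70, 0.82)
        shapes[("TNF", "M", f"S{i}")] = "u-shaped"

    return ErosionTrajectory(
        timepoints=tuple(float(t) for t in timepoints),
        fractions=fr,
        shapes=shapes,
        fill_value=1.0,
    )


def default_cohort_spec(
    rng_seed: int = 0,
    n_limbs: int = 2,
    timepoints: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0),
) -> CohortSpec:
    """Small 2-group × 2-sex demo cohort with the stylized trajectories."""
    traj = study_trajectory(timepoints)
    return CohortSpec(
        groups=(
            GroupSpec("WT", "F", n_limbs),
            GroupSpec("TNF", "F", n_limbs),
            GroupSpec("WT", "M", n_limbs),
            GroupSpec("TNF", "M", n_limbs),
        ),
        timepoints=timepoints,
        trajectory=traj,
        rng_seed=rng_seed,
    )
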