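"""Enumeration of the mouse hindpaw bones and their reporting rules.

The hindpaw carries 30 or 31 individually ossified bones depending on
whether the intermediate cuneiform is fused with the navicular / lateral
cuneiform (which are themselves consistently fused and segmented as one
entity, ``NavLat``).  Regardless of the fusion state, volumes for the
navicular, lateral cuneiform and intermediate cuneiform are always reported
combined under the shorthand ``NAVLATINT`` so every limb yields the same 30
analysis units.

Digit-associated bones (Met, PP, DP, S) are numbered in increasing order
from medial to lateral.
"""
from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Bone",
    "BoneCatalog",
    "COMPARTMENTS",
    "NAVLATINT",
    "FUSED",
    "UNFUSED",
]

FUSED = "fused"
UNFUSED = "unfused"

#: Reporting unit that absorbs the navicular/lateral/intermediate cuneiform.
NAVLATINT = "NAVLATINT"

COMPARTMENTS = (
    "tarsals",
    "metatarsals",
    "proximal_phalanges",
    "distal_phalanges",
    "sesamoids",
)


@dataclass(frozen=True)
class Bone:
    """A segmentable bone entity.

    ``bone_id`` is the shorthand code; ``digit`` is 1 (medial) .. 5
    (lateral) for digit-associated bones, else None.
    """

    bone_id: str
    compartment: str
    digit: int | None = None


def _digit_bones() -> list[Bone]:
    bones = [Bone(f"Met{d}", "metatarsals", d) for d in range(1, 6)]
    bones += [Bone(f"PP{d}", "proximal_phalanges", d) for d in range(1, 6)]
    bones += [Bone(f"DP{d}", "distal_phalanges", d) for d in range(2, 6)]
    # two sesamoids per digit at each metatarsophalangeal joint
    bones += [Bone(f"S{i}", "sesamoids", (i + 1) // 2) for i in range(1, 11)]
    return bones


_TARSALS_COMMON = [
    Bone("Calc", "tarsals"),
    Bone("Tal", "tarsals"),
    Bone("Cub", "tarsals"),
    Bone("Med", "tarsals"),
    Bone("Tib", "tarsals"),
    Bone("NavLat", "tarsals"),
]
_INTC = Bone("IntC", "tarsals")


class BoneCatalog:
    """Bone enumeration for one fusion variant.

    Parameters
    ----------
    fusion_variant:
        ``"unfused"`` — the intermediate cuneiform is a separate bone
        (31 entities); ``"fused"`` — it is merged into the NavLat entity
        (30 entities).
    """

    def __init__(self, fusion_variant: str = UNFUSED) -> None:
        if fusion_variant not in (FUSED, UNFUSED):
            raise ValueError(f"unknown fusion variant {fusion_variant!r}")
        self.fusion_variant = fusion_variant
        tarsals = list(_TARSALS_COMMON)
        if fusion_variant == UNFUSED:
            tarsals.append(_INTC)
        self.bones: tuple[Bone, ...] = tuple(tarsals + _digit_bones())
        self._by_id = {b.bone_id: b for b in self.bones}
        # stable label assignment: 1..n in catalog order
        self.labels: dict[str, int] = {
            b.bone_id: i + 1 for i, b in enumerate(self.bones)
        }

    # -- basic queries ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.bones)

    def __contains__(self, bone_id: str) -> bool:
        return bone_id in self._by_id

    def bone(self, bone_id: str) -> Bone:
        try:
            return self._by_id[bone_id]
        except KeyError:
            raise KeyError(f"unknown bone id {bone_id!r}") from None

    def bone_ids(self) -> list[str]:
        return [b.bone_id for b in self.bones]

    def bone_for_label(self, label: int) -> str:
        for bone_id, lab in self.labels.items():
            if lab == label:
                return bone_id
        raise KeyError(f"no bone carries label {label}")

    # -- reporting rules -------------------------------------------------
    def report_unit(self, bone_id: str) -> str:
        """Reporting unit for a bone; NavLat and IntC fold into NAVLATINT."""
        if bone_id in ("NavLat", "IntC"):
            return NAVLATINT
        if bone_id not in self._by_id and bone_id != NAVLATINT:
            raise KeyError(f"unknown bone id {bone_id!r}")
        return bone_id

    def report_units(self) -> list[str]:
        """The 30 analysis units, in catalog order (NAVLATINT once)."""
        units: list[str] = []
        for b in self.bones:
            u = self.report_unit(b.bone_id)
            if u not in units:
                units.append(u)
        return units

    def compartment_of(self, unit: str) -> str:
        if unit == NAVLATINT:
            return "tarsals"
        return self.bone(unit).compartment

    def units_in_compartment(self, compartment: str) -> list[str]:
        if compartment not in COMPARTMENTS:
            raise KeyError(f"unknown compartment {compartment!r}")
        return [u for u in self.report_units() if self.compartment_of(u) == compartment]
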