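"""Segmentation accuracy accounting and correction operators.

Errors are counted per reference bone: *oversplit* (one bone split across
several predicted labels), *overconnected* (several bones sharing one
predicted label), or a *combination* of both on the same bone.  The error
rate is the number of incorrectly segmented bones as a percentage of total
bones.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import BinaryMask, LabelMap, VoxelImage
from .imgseg import SeedSet, watershed_inside_mask

__all__ = [
    "LabelCorrespondence",
    "ErrorReport",
    "match_labels",
    "classify_errors",
    "merge_labels",
    "resplit_label",
    "per_bone_dice",
    "STATUSES",
]

STATUSES = ("correct", "oversplit", "overconnected", "combination")


@dataclass
class LabelCorrespondence:
    """Voxel-overlap bookkeeping between a reference and a prediction.

    ``overlap`` is indexed by reference bone label (rows) × predicted label
    (columns), background excluded on both sides.  ``majority`` maps each
    predicted label to the reference bone holding its plurality (ties to
    the lower reference label).
    """

    overlap: pd.DataFrame
    majority: dict[int, int]
    reference_sizes: dict[int, int]
    predicted_sizes: dict[int, int]


def match_labels(predicted: LabelMap, reference: LabelMap) -> LabelCorrespondence:
    """Exact overlap counts for every (reference, predicted) label pair."""
    if predicted.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs reference {reference.shape}"
        )
    ref = reference.values.ravel()
    pred = predicted.values.ravel()
    sel = (ref > 0) | (pred > 0)
    ref, pred = ref[sel], pred[sel]
    pairs = ref.astype(np.int64) * (int(pred.max()) + 1) + pred
    uniq, counts = np.unique(pairs, return_counts=True)
    base = int(pred.max()) + 1
    r_labels = sorted(reference.voxel_counts())
    p_labels = sorted(predicted.voxel_counts())
    overlap = pd.DataFrame(0, index=r_labels, columns=p_labels, dtype=np.int64)
    for key, n in zip(uniq, counts):
        r, p = int(key // base), int(key % base)
        if r > 0 and p > 0:
            overlap.loc[r, p] = int(n)
    majority: dict[int, int] = {}
    for p in p_labels:
        col = overlap[p]
        if col.sum() == 0:
            continue  # predicted label is all background in the reference
        best = col.max()
        majority[p] = int(min(r for r in col.index if col[r] == best))
    return LabelCorrespondence(
        overlap=overlap,
        majority=majority,
        reference_sizes=reference.voxel_counts(),
        predicted_sizes=predicted.voxel_counts(),
    )


@dataclass
class ErrorReport:
    status: dict[int, str]  # reference bone label -> status
    counts: dict[str, int]
    error_rate: float  # % of total bones segmented incorrectly
    accuracy: float  # 100 - error_rate
    total_bones: int
    min_overlap_fraction: float

    def to_dict(self) -> dict:
        return {
            "status": {str(k): v for k, v in self.status.items()},
            "counts": self.counts,
            "error_rate_pct": self.error_rate,
            "accuracy_pct": self.accuracy,
            "total_bones": self.total_bones,
            "min_overlap_fraction": self.min_overlap_fraction,
        }


def classify_errors(
    correspondence: LabelCorrespondence,
    min_overlap_fraction: float = 0.05,
    total_bones: int | None = None,
) -> ErrorReport:
    """Classify each reference bone.

    A bone is *oversplit* when ≥2 predicted labels each hold at least
    ``min_overlap_fraction`` of its voxels (smaller slivers are boundary
    noise, not splits); *overconnected* when its plurality predicted label
    is also the plurality label of another bone; *combination* when both.
    A bone whose voxels land entirely in predicted background is counted as
    overconnected (absorbed into background).

    ``total_bones`` is the error-rate denominator (the expected bone count
    for the limb's fusion variant); defaults to the number of reference
    bones present.
    """
    ov = correspondence.overlap
    bones = list(ov.index)
    if total_bones is None:
        total_bones = len(bones)

    # plurality predicted label per bone (ties to lower predicted label)
    bone_major: dict[int, int] = {}
    for b in bones:
        row = ov.loc[b]
        if row.sum() == 0:
            bone_major[b] = 0
        else:
            best = row.max()
            bone_major[b] = int(min(p for p in row.index if row[p] == best))

    status: dict[int, str] = {}
    for b in bones:
        size = correspondence.reference_sizes[b]
        row = ov.loc[b]
        n_split = int((row >= min_overlap_fraction * size).sum())
        oversplit = n_split >= 2
        p = bone_major[b]
        if p == 0:
            overconnected = True  # merged into background
        else:
            shared = [bb for bb, pp in bone_major.items() if pp == p]
            overconnected = len(shared) >= 2
        if oversplit and overconnected:
            status[b] = "combination"
        elif oversplit:
            status[b] = "oversplit"
        elif overconnected:
            status[b] = "overconnected"
        else:
            status[b] = "correct"

    counts = {s: sum(1 for v in status.values() if v == s) for s in STATUSES}
    # bones absent from the reference also count as incorrect against the
    # expected denominator
    incorrect = sum(counts[s] for s in STATUSES if s != "correct")
    incorrect += max(0, total_bones - len(bones))
    error_rate = 100.0 * incorrect / total_bones
    return ErrorReport(
        status=status,
        counts=counts,
        error_rate=float(np.clip(error_rate, 0.0, 100.0)),
        accuracy=float(100.0 - np.clip(error_rate, 0.0, 100.0)),
        total_bones=total_bones,
        min_overlap_fraction=min_overlap_fraction,
    )


def merge_labels(label_map: LabelMap, label_ids: list[int], target_id: int) -> LabelMap:
    """Rewrite the listed labels to ``target_id`` (split-error fix).

    Conserves the total labeled voxel count exactly.
    """
    present = set(int(v) for v in label_map.labels())
    missing = [l for l in label_ids if l not in present]
    if missing:
        raise ValueError(f"labels not present in map: {missing}")
    out = label_map.values.copy()
    for l in label_ids:
        out[out == l] = target_id
    return LabelMap(out, label_map.spacing_um)


def resplit_label(
    label_map: LabelMap,
    image: VoxelImage | None,
    target_id: int,
    extra_seeds: list[tuple[int, int, int]],
    landscape: str | None = None,
) -> LabelMap:
    """Re-run the watershed on one label's region (overconnected fix).

    ``extra_seeds`` are (z, y, x) voxels inside the target region; they
    become new labels numbered from max(label)+1.  Other labels are
    untouched and the region's voxel count is conserved exactly.
    """
    values = label_map.values
    if target_id not in label_map.labels():
        raise ValueError(f"label {target_id} not present")
    region = values == target_id
    for v in extra_seeds:
        if not region[v]:
            raise ValueError(f"seed {v} lies outside the region of label {target_id}")
    if landscape is None:
        landscape = "gradient" if image is not None else "inverse-distance"
    next_label = int(values.max()) + 1
    points = [(next_label + i, v) for i, v in enumerate(extra_seeds)]
    seeds = SeedSet.from_points(values.shape, points)
    mask = BinaryMask(region, label_map.spacing_um)
    sub = watershed_inside_mask(image, mask, seeds, landscape)
    out = values.copy()
    out[region] = sub.values[region]
    return LabelMap(out, label_map.spacing_um)


def per_bone_dice(predicted: LabelMap, reference: LabelMap) -> pd.DataFrame:
    """Dice = 2|A∩B| / (|A|+|B|) per reference bone via majority assignment.

    Each reference bone is scored against the union of predicted labels
    whose plurality owner it is; a bone owning no predicted label gets
    Dice 0 and ``missing=True``.
    """
    corr = match_labels(predicted, reference)
    rows = []
    for b in sorted(corr.reference_sizes):
        mine = [p for p, owner in corr.majority.items() if owner == b]
        size_b = corr.reference_sizes[b]
        if not mine:
            rows.append({"bone": b, "dice": 0.0, "missing": True})
            continue
        inter = int(corr.overlap.loc[b, mine].sum())
        size_p = sum(corr.predicted_sizes[p] for p in mine)
        rows.append(
            {
                "bone": b,
                "dice": 2.0 * inter / (size_b + size_p),
                "missing": False,
            }
        )
    return pd.DataFrame(rows)
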