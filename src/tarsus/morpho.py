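"""Per-bone volume extraction and longitudinal normalization.

Volumes are voxel counts × (spacing in mm)³; the navicular / lateral /
intermediate cuneiform complex is always reported as the single combined
unit NAVLATINT.  Percent change is computed per limb against a baseline
timepoint (the first available one by default); limbs lacking a baseline
are excluded, never imputed.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .catalog import COMPARTMENTS, NAVLATINT, BoneCatalog
from .grid import LabelMap
from .qc import match_labels

__all__ = [
    "material_statistics",
    "assign_labels_to_catalog",
    "aggregate_compartments",
    "percent_change",
    "heatmap_matrix",
]

log = logging.getLogger(__name__)

VOLUME_COLUMNS = ["bone_id", "voxels", "volume_mm3"]


def material_statistics(
    label_map: LabelMap,
    catalog_assignment: dict[int, str],
    catalog: BoneCatalog,
) -> pd.DataFrame:
    """Extract per-bone volumes from a label map.

    ``catalog_assignment`` maps every positive label to a bone id; bones
    folding into NAVLATINT are summed into one row.  Volumes are in mm³
    (voxel count × (spacing/1000)³), with raw voxel counts kept alongside
    for exact checks.
    """
    counts = label_map.voxel_counts()
    unassigned = sorted(set(counts) - set(catalog_assignment))
    if unassigned:
        raise ValueError(f"labels without a bone assignment: {unassigned}")
    unit_voxels: dict[str, int] = {}
    for label, n in counts.items():
        unit = catalog.report_unit(catalog_assignment[label])
        unit_voxels[unit] = unit_voxels.get(unit, 0) + n
    vv = label_map.voxel_volume_mm3
    order = {u: i for i, u in enumerate(catalog.report_units())}
    rows = [
        {"bone_id": u, "voxels": n, "volume_mm3": n * vv}
        for u, n in sorted(unit_voxels.items(), key=lambda kv: order.get(kv[0], 99))
    ]
    return pd.DataFrame(rows, columns=VOLUME_COLUMNS)


def assign_labels_to_catalog(
    predicted: LabelMap,
    reference: LabelMap,
    reference_assignment: dict[int, str],
) -> dict[int, str]:
    """Map each predicted label to the bone holding its plurality overlap.

    ``reference_assignment`` maps reference labels to bone ids (for phantom
    truth this is the catalog labeling).  A tied plurality is ambiguous and
    raises, demanding an explicit user mapping; labels overlapping no
    reference bone are reported in the error as unmapped.
    """
    corr = match_labels(predicted, reference)
    out: dict[int, str] = {}
    unmapped = []
    for p in sorted(corr.predicted_sizes):
        col = corr.overlap[p] if p in corr.overlap.columns else None
        if col is None or col.sum() == 0:
            unmapped.append(p)
            continue
        best = col.max()
        winners = [r for r in col.index if col[r] == best]
        if len(winners) > 1:
            raise ValueError(
                f"predicted label {p} ties between reference bones {winners}; "
                "supply an explicit label→bone mapping"
            )
        out[p] = reference_assignment[winners[0]]
    if unmapped:
        raise ValueError(f"predicted labels overlap no reference bone: {unmapped}")
    return out


def aggregate_compartments(
    volume_table: pd.DataFrame, catalog: BoneCatalog
) -> pd.DataFrame:
    """Per limb × timepoint compartment sums plus the grand total.

    Output rows carry ``compartment`` ∈ the five compartments or
    ``"total"`` (= sum of the five).
    """
    unknown = sorted(
        set(volume_table["bone_id"]) - set(catalog.report_units()) - {NAVLATINT}
    )
    if unknown:
        raise ValueError(f"unknown bone ids: {unknown}")
    df = volume_table.copy()
    df["compartment"] = df["bone_id"].map(catalog.compartment_of)
    keys = [c for c in ("limb_id", "group", "sex", "timepoint") if c in df.columns]
    agg_cols = {"volume_mm3": "sum"}
    if "voxels" in df.columns:
        agg_cols["voxels"] = "sum"
    per_comp = df.groupby(keys + ["compartment"], as_index=False).agg(agg_cols)
    total = df.groupby(keys, as_index=False).agg(agg_cols)
    total["compartment"] = "total"
    out = pd.concat([per_comp, total], ignore_index=True)
    cat_order = {c: i for i, c in enumerate(COMPARTMENTS + ("total",))}
    out = out.sort_values(keys + ["compartment"], key=lambda s: s.map(cat_order) if s.name == "compartment" else s)
    return out.reset_index(drop=True)


def percent_change(
    volume_table: pd.DataFrame,
    baseline_timepoint: float | None = None,
    value_column: str = "volume_mm3",
    unit_column: str = "bone_id",
) -> pd.DataFrame:
    """Percent change from baseline per limb × bone (or compartment).

    ``100 × (V_t − V_baseline) / V_baseline``.  The baseline defaults to
    each limb's first available timepoint; limbs lacking a measurement at
    the requested baseline are excluded with a logged reason.  Baseline
    rows are exactly 0 %.  Zero baseline volumes yield NaN with
    ``undefined_baseline=True``.
    """
    rows = []
    for (limb, unit), sub in volume_table.groupby(["limb_id", unit_column]):
        sub = sub.sort_values("timepoint")
        base_t = baseline_timepoint
        if base_t is None:
            base_t = float(sub["timepoint"].iloc[0])
        base = sub[sub["timepoint"] == base_t]
        if base.empty:
            log.info(
                "excluding limb %s / %s: no measurement at baseline %s",
                limb, unit, base_t,
            )
            continue
        v0 = float(base[value_column].iloc[0])
        meta_cols = [c for c in ("group", "sex") if c in sub.columns]
        for _, r in sub.iterrows():
            undefined = v0 == 0.0
            pct = np.nan if undefined else 100.0 * (r[value_column] - v0) / v0
            rows.append(
                {
                    "limb_id": limb,
                    unit_column: unit,
                    **{c: r[c] for c in meta_cols},
                    "timepoint": r["timepoint"],
                    "baseline_timepoint": base_t,
                    "pct_change_pct": pct,
                    "undefined_baseline": undefined,
                }
            )
    return pd.DataFrame(rows)


def heatmap_matrix(
    pct_table: pd.DataFrame,
    group: str,
    sex: str | None = None,
    unit_column: str = "bone_id",
) -> pd.DataFrame:
    """Bones (rows) × timepoints (columns) of mean percent change across
    the limbs of one group.  Missing cells stay NaN, never imputed."""
    sel = pct_table[pct_table["group"] == group]
    if sex is not None:
        sel = sel[sel["sex"] == sex]
    if sel.empty:
        raise ValueError(f"no limbs for group={group!r} sex={sex!r}")
    mat = sel.pivot_table(
        index=unit_column, columns="timepoint", values="pct_change_pct", aggfunc="mean"
    )
    return mat
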