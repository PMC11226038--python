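import numpy as np
import pytest

from tarsus import phantom
from tarsus.catalog import NAVLATINT, BoneCatalog
from tarsus.phantom import (
    CohortSpec,
    ErosionTrajectory,
    GroupSpec,
    apply_erosion_trajectory,
    build_bone_atlas,
    generate_cohort,
    primitive_distance,
    render_image,
)


class TestAtlas:
    def test_unfused_has_31_bones(self, unfused_atlas):
        assert len(unfused_atlas.bones) == 31
        labels = [b.label for b in unfused_atlas.bones]
        assert sorted(labels) == list(range(1, 32))

    def test_fused_has_30_bones_without_separate_intc(self, fused_atlas):
        assert len(fused_atlas.bones) == 30
        assert "IntC" not in [b.bone_id for b in fused_atlas.bones]
        # the NavLat entity carries the extra geometry
        unf = build_bone_atlas("unfused")
        assert len(fused_atlas.bone("NavLat").primitives) > len(
            unf.bone("NavLat").primitives
        )

    def test_deterministic(self):
        a1 = build_bone_atlas("unfused")
        a2 = build_bone_atlas("unfused")
        assert a1 == a2
        np.testing.assert_array_equal(
            a1.rasterize_labels().values, a2.rasterize_labels().values
        )

    def test_compartment_counts(self, unfused_atlas):
        cat = unfused_atlas.catalog()
        by_comp = {}
        for b in unfused_atlas.bones:
            by_comp.setdefault(cat.bone(b.bone_id).compartment, []).append(b.bone_id)
        assert len(by_comp["tarsals"]) == 7
        assert len(by_comp["metatarsals"]) == 5
        assert len(by_comp["proximal_phalanges"]) == 5
        assert len(by_comp["distal_phalanges"]) == 4
        assert len(by_comp["sesamoids"]) == 10

    def test_medial_to_lateral_ordering(self, unfused_atlas):
        # digit bones are ordered by increasing x (medial→lateral)
        for prefix in ("Met", "PP"):
            xs = [
                unfused_atlas.bone(f"{prefix}{d}").primitives[0].a[2]
                for d in range(1, 6)
            ]
            assert xs == sorted(xs)

    def test_labels_partition_bone_voxels(self, unfused_atlas, truth_labels):
        total = sum(
            unfused_atlas.rasterize_bone(b.bone_id).sum() for b in unfused_atlas.bones
        )
        assert int((truth_labels.values > 0).sum()) == int(total)
        # disjoint by construction: rasterize_labels would have raised

    def test_every_bone_separated_or_articulating(self, unfused_atlas):
        for i, p in enumerate(unfused_atlas.bones):
            for q in unfused_atlas.bones[i + 1:]:
                d = min(
                    primitive_distance(pp, qq)
                    for pp in p.primitives
                    for qq in q.primitives
                )
                assert d >= unfused_atlas.spacing_um

    def test_articulated_variant_closes_talus_calcaneus(self):
        art = build_bone_atlas("unfused", articulate=True)
        d = min(
            primitive_distance(pp, qq)
            for pp in art.bone("Tal").primitives
            for qq in art.bone("Calc").primitives
        )
        assert d < 2 * art.spacing_um
        assert frozenset({"Tal", "Calc"}) in art.contact_pairs

    def test_grid_too_small_names_bone(self):
        with pytest.raises(ValueError, match="too small for bone"):
            build_bone_atlas("unfused", grid_shape=(100, 160, 60))


class TestErosionTrajectory:
    def test_baseline_must_be_one(self):
        with pytest.raises(ValueError, match="baseline fraction"):
            ErosionTrajectory((0.0, 1.0), {("G", "F", "Cub"): (0.9, 0.8)})

    def test_fractions_positive(self):
        with pytest.raises(ValueError, match="> 0"):
            ErosionTrajectory((0.0, 1.0), {("G", "F", "Cub"): (1.0, -0.1)})

    def test_u_shape_validation(self):
        ErosionTrajectory(
            (0.0, 1.0, 2.0, 3.0),
            {("G", "M", "S1"): (1.0, 0.8, 0.7, 0.9)},
            shapes={("G", "M", "S1"): "u-shaped"},
        )
        with pytest.raises(ValueError, match="interior minimum"):
            ErosionTrajectory(
                (0.0, 1.0, 2.0, 3.0),
                {("G", "M", "S1"): (1.0, 0.9, 0.8, 0.7)},
                shapes={("G", "M", "S1"): "u-shaped"},
            )

    def test_monotone_validation(self):
        with pytest.raises(ValueError, match="monotone"):
            ErosionTrajectory(
                (0.0, 1.0, 2.0),
                {("G", "F", "Tal"): (1.0, 0.8, 0.9)},
                shapes={("G", "F", "Tal"): "monotone-decreasing"},
            )

    def test_fill_value_none_requires_definition(self):
        traj = ErosionTrajectory((0.0, 1.0), {}, fill_value=None)
        with pytest.raises(KeyError):
            traj.fraction("G", "F", "Cub", 1.0)


class TestApplyErosion:
    def test_identity_at_baseline(self, unfused_atlas):
        traj = ErosionTrajectory((2.0, 3.0), {("G", "F", "Cub"): (1.0, 0.8)})
        out = apply_erosion_trajectory(unfused_atlas, traj, "G", "F", 2.0)
        np.testing.assert_array_equal(
            out.rasterize_labels().values, unfused_atlas.rasterize_labels().values
        )

    def test_single_bone_fraction(self, unfused_atlas):
        traj = ErosionTrajectory((2.0, 3.0), {("G", "F", "Cub"): (1.0, 0.75)})
        out = apply_erosion_trajectory(unfused_atlas, traj, "G", "F", 3.0)
        base = unfused_atlas.voxel_counts()
        after = out.voxel_counts()
        assert after["Cub"] / base["Cub"] == pytest.approx(0.75, abs=0.02)
        for bone_id in base:
            if bone_id != "Cub":
                assert after[bone_id] == base[bone_id]

    def test_global_half_volume(self, unfused_atlas):
        fr = {
            ("G", "F", b.bone_id): (1.0, 0.5) for b in unfused_atlas.bones
        }
        traj = ErosionTrajectory((2.0, 3.0), fr)
        out = apply_erosion_trajectory(unfused_atlas, traj, "G", "F", 3.0)
        base = sum(unfused_atlas.voxel_counts().values())
        after = sum(out.voxel_counts().values())
        assert after / base == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("f", [0.3, 0.55, 0.9])
    def test_fraction_tolerance_range(self, unfused_atlas, f):
        for bone_id in ("Tal", "Met3"):
            traj = ErosionTrajectory((0.0, 1.0), {("G", "F", bone_id): (1.0, f)})
            out = apply_erosion_trajectory(unfused_atlas, traj, "G", "F", 1.0)
            ratio = out.voxel_counts()[bone_id] / unfused_atlas.voxel_counts()[bone_id]
            assert abs(ratio - f) <= 0.02

    def test_positions_unchanged(self, unfused_atlas):
        traj = ErosionTrajectory((0.0, 1.0), {("G", "F", "Tal"): (1.0, 0.6)})
        out = apply_erosion_trajectory(unfused_atlas, traj, "G", "F", 1.0)
        assert out.bone("Tal").primitives[0].center == unfused_atlas.bone("Tal").primitives[0].center


class TestRender:
    def test_two_values_without_blur_or_noise(self, unfused_atlas):
        img = render_image(unfused_atlas, noise_sd=0, blur_sigma_um=0)
        assert set(np.unique(img.values)) == {200.0, 7200.0}

    def test_seed_determinism(self, unfused_atlas):
        i1 = render_image(unfused_atlas, rng_seed=5)
        i2 = render_image(unfused_atlas, rng_seed=5)
        i3 = render_image(unfused_atlas, rng_seed=6)
        np.testing.assert_array_equal(i1.values, i2.values)
        assert not np.array_equal(i1.values, i3.values)

    def test_threshold_recovers_truth(self, unfused_atlas, truth_labels, noisy_image):
        from tarsus.imgseg import median_filter, threshold_mask

        truth = truth_labels.values > 0
        mask = threshold_mask(median_filter(noisy_image, 1), 2500.0).values
        recall = (mask & truth).sum() / truth.sum()
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert recall >= 0.98
        assert jaccard >= 0.95

    def test_bone_hu_must_exceed_tissue(self, unfused_atlas):
        with pytest.raises(ValueError, match="bone_hu"):
            render_image(unfused_atlas, bone_hu=100.0, tissue_hu=200.0)


def tiny_spec(seed=0, n_limbs=1, groups=None):
    traj = ErosionTrajectory(
        (2.0, 3.0), {("TNF", "F", "Cub"): (1.0, 0.75)}
    )
    return CohortSpec(
        groups=groups or (GroupSpec("WT", "F", n_limbs), GroupSpec("TNF", "F", n_limbs)),
        timepoints=(2.0, 3.0),
        trajectory=traj,
        rng_seed=seed,
    )


class TestCohort:
    def test_counts(self):
        ds = generate_cohort(tiny_spec(n_limbs=2))
        assert len(ds.members) == 2 * 2 * 2  # groups × limbs × timepoints
        assert len(ds.design) == len(ds.members)
        # one truth-volume row per member per report unit
        assert len(ds.truth_volumes) == len(ds.members) * 30

    def test_flat_trajectory_constant_truth_volumes(self):
        spec = tiny_spec()
        ds = generate_cohort(spec)
        wt = ds.truth_volumes[ds.truth_volumes.group == "WT"]
        piv = wt.pivot_table(index="bone_id", columns="timepoint", values="voxels")
        np.testing.assert_array_equal(piv[2.0].to_numpy(), piv[3.0].to_numpy())

    def test_programmed_decline_in_truth_table(self):
        ds = generate_cohort(tiny_spec())
        cub = ds.truth_volumes[
            (ds.truth_volumes.group == "TNF") & (ds.truth_volumes.bone_id == "Cub")
        ].set_index("timepoint")
        frac = cub.loc[3.0, "voxels"] / cub.loc[2.0, "voxels"]
        assert frac == pytest.approx(0.75, abs=0.02)

    def test_pure_function_of_spec(self):
        d1 = generate_cohort(tiny_spec(seed=3))
        d2 = generate_cohort(tiny_spec(seed=3))
        assert d1.design.equals(d2.design)
        assert d1.truth_volumes.equals(d2.truth_volumes)
        for m1, m2 in zip(d1.members, d2.members):
            np.testing.assert_array_equal(m1.image.values, m2.image.values)
            np.testing.assert_array_equal(m1.truth_labels.values, m2.truth_labels.values)

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError, match="at least one group"):
            CohortSpec(groups=(), timepoints=(2.0,), trajectory=ErosionTrajectory((2.0,), {}))

    def test_hu_straddle_enforced(self):
        with pytest.raises(ValueError, match="2500"):
            CohortSpec(
                groups=(GroupSpec("WT", "F", 1),),
                timepoints=(2.0,),
                trajectory=ErosionTrajectory((2.0,), {}),
                bone_hu_mean=2000.0,
            )

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = phantom.default_cohort_spec(rng_seed=9)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        loaded = CohortSpec.from_yaml(path)
        assert loaded == spec

    def test_navlatint_always_reported(self):
        ds = generate_cohort(tiny_spec())
        assert set(ds.truth_volumes.bone_id).issuperset({NAVLATINT, "Tal", "S10"})
        assert "NavLat" not in set(ds.truth_volumes.bone_id)


def test_study_trajectory_patterns():
    traj = phantom.study_trajectory()
    # sesamoid U-shape for diseased males
    fr = traj.fractions[("TNF", "M", "S1")]
    k = int(np.argmin(fr))
    assert 0 < k < len(fr) - 1
    # late tarsal collapse for diseased females: worst drop on last interval
    cub = traj.fractions[("TNF", "F", "Cub")]
    drops = [a - b for a, b in zip(cub, cub[1:])]
    assert max(drops) == drops[-1]
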