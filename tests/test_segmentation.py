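"""Lesion thresholding, cleanup, fate algebra, mirroring and volumes."""

import numpy as np
import pytest

from strokefate.image import VolumeImage, hemisphere_masks
from strokefate.phantom import LABELS, make_phantom
from strokefate.segmentation import (
    classify_fate,
    clean_mask,
    lesion_location,
    mirror_homologue,
    reference_stats,
    threshold_lesion,
    volume_change,
    volume_metrics,
)


@pytest.fixture(scope="module")
def atlas():
    return make_phantom(seed=0).label_volume


def ref_map(atlas, values):
    return VolumeImage(values.astype(float), (0.3, 0.3, 1.2), "adc")


class TestReferenceStats:
    def test_mean_sd_closed_form(self, atlas):
        left, _ = hemisphere_masks(atlas.shape)
        ref_mask = (
            np.isin(atlas, [LABELS["s1fl"], LABELS["s2"], LABELS["cpu"]]) & left
        )
        vals = np.zeros(atlas.shape)
        seq = np.arange(1, ref_mask.sum() + 1, dtype=float)
        vals[ref_mask] = seq * 1e-7  # stays below the free-water CSF cutoff
        img = ref_map(atlas, vals)
        stats = reference_stats(img, atlas, "adc")
        assert stats.mean == pytest.approx(seq.mean() * 1e-7)
        assert stats.sd == pytest.approx(seq.std(ddof=1) * 1e-7)
        assert stats.median == pytest.approx(np.median(seq) * 1e-7)

    def test_constant_region_rejected(self, atlas):
        vals = np.full(atlas.shape, 7e-4)
        with pytest.raises(ValueError, match="standard deviation"):
            reference_stats(ref_map(atlas, vals), atlas, "adc")

    def test_csf_like_voxels_excluded_by_cutoff(self, atlas, rng):
        left, _ = hemisphere_masks(atlas.shape)
        ref_mask = (
            np.isin(atlas, [LABELS["s1fl"], LABELS["s2"], LABELS["cpu"]]) & left
        )
        vals = np.zeros(atlas.shape)
        vals[ref_mask] = rng.normal(7e-4, 2e-5, ref_mask.sum())
        base = reference_stats(ref_map(atlas, vals), atlas, "adc")
        # push a third of the reference voxels to free-water ADC
        idx = np.argwhere(ref_mask)[:: 3]
        vals2 = vals.copy()
        vals2[idx[:, 0], idx[:, 1], idx[:, 2]] = 2.5e-3
        with_csf = reference_stats(ref_map(atlas, vals2), atlas, "adc")
        kept = ref_mask.copy()
        kept[idx[:, 0], idx[:, 1], idx[:, 2]] = False
        assert with_csf.mean == pytest.approx(vals[kept].mean())
        assert with_csf.n_voxels == int(kept.sum())

    def test_voxel_floor_enforced(self, atlas, rng):
        vals = rng.normal(7e-4, 2e-5, atlas.shape)
        with pytest.raises(ValueError, match="floor"):
            reference_stats(
                ref_map(atlas, vals), atlas, "adc", min_voxels=10**6
            )


class TestThreshold:
    def test_strict_two_sd_rule(self, atlas, rng):
        left, right = hemisphere_masks(atlas.shape)
        vals = np.full(atlas.shape, 7e-4)
        ref_mask = (
            np.isin(atlas, [LABELS["s1fl"], LABELS["s2"], LABELS["cpu"]]) & left
        )
        vals[ref_mask] += rng.normal(0, 2e-5, ref_mask.sum())
        img = ref_map(atlas, vals)
        stats = reference_stats(img, atlas, "adc")
        probe = vals.copy()
        ix = np.argwhere(right & (atlas == LABELS["cortex"]))[:3]
        probe[tuple(ix[0])] = stats.mean - 2.5 * stats.sd  # in
        probe[tuple(ix[1])] = stats.mean  # out
        probe[tuple(ix[2])] = stats.mean - 2.0 * stats.sd  # boundary: out
        mask = threshold_lesion(ref_map(atlas, probe), stats, "adc", atlas)
        assert mask[tuple(ix[0])]
        assert not mask[tuple(ix[1])]
        assert not mask[tuple(ix[2])]

    def test_t2_direction_and_monotonicity(self, atlas, rng):
        left, right = hemisphere_masks(atlas.shape)
        vals = np.full(atlas.shape, 47.0)
        ref_mask = (
            np.isin(atlas, [LABELS["s1fl"], LABELS["s2"], LABELS["cpu"]]) & left
        )
        vals[ref_mask] += rng.normal(0, 1.0, ref_mask.sum())
        stats = reference_stats(ref_map(atlas, vals), atlas, "t2")
        probe = vals + rng.normal(0, 3.0, vals.shape)
        m1 = threshold_lesion(ref_map(atlas, probe), stats, "t2", atlas)
        raised = probe.copy()
        bump = right & (atlas == LABELS["cortex"])
        raised[bump] += 5.0
        m2 = threshold_lesion(ref_map(atlas, raised), stats, "t2", atlas)
        # raising T2 never removes a voxel from the subacute mask
        assert np.all(m2[m1])

    def test_mode_mismatch_rejected(self, atlas):
        vals = np.full(atlas.shape, 47.0)
        vals[atlas == LABELS["s1fl"]] += np.linspace(0, 1, (atlas == 4).sum())
        stats = reference_stats(ref_map(atlas, vals), atlas, "t2")
        with pytest.raises(ValueError):
            threshold_lesion(ref_map(atlas, vals), stats, "adc", atlas)


class TestCleanMask:
    def test_empty_in_empty_out(self):
        m = np.zeros((10, 10, 4), dtype=bool)
        assert not clean_mask(m).any()

    def test_single_voxel_removed(self):
        m = np.zeros((10, 10, 4), dtype=bool)
        m[5, 5, 2] = True
        assert not clean_mask(m, min_cluster_voxels=2, closing_radius=0).any()

    def test_idempotent_on_random_masks(self, rng):
        for _ in range(100):
            m = rng.random((16, 16, 6)) < rng.uniform(0.05, 0.5)
            once = clean_mask(m, min_cluster_voxels=5, closing_radius=1)
            twice = clean_mask(once, min_cluster_voxels=5, closing_radius=1)
            assert np.array_equal(once, twice)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            clean_mask(np.zeros((4, 4, 4), dtype=bool), min_cluster_voxels=-1)


class TestFateAlgebra:
    def test_equal_masks_all_core(self):
        m = np.zeros((6, 6, 2), dtype=bool)
        m[4, 2:4, :] = True
        f = classify_fate(m, m)
        assert np.array_equal(f.core, m)
        assert not f.salvageable.any() and not f.delayed.any()

    def test_enumerated_example(self):
        a = np.zeros((4, 2, 1), dtype=bool)
        s = np.zeros((4, 2, 1), dtype=bool)
        a[2, 0, 0] = a[2, 1, 0] = True  # {a, b}
        s[2, 1, 0] = s[3, 0, 0] = True  # {b, c}
        f = classify_fate(a, s)
        assert f.core.sum() == 1 and f.core[2, 1, 0]
        assert f.salvageable.sum() == 1 and f.salvageable[2, 0, 0]
        assert f.delayed.sum() == 1 and f.delayed[3, 0, 0]

    def test_partition_identities_on_random_pairs(self, rng):
        for _ in range(1000):
            a = rng.random((8, 8, 3)) < 0.3
            s = rng.random((8, 8, 3)) < 0.3
            f = classify_fate(a, s)
            assert f.core.sum() + f.salvageable.sum() == a.sum()
            assert f.core.sum() + f.delayed.sum() == s.sum()
            assert np.array_equal(f.core | f.salvageable, a)
            assert np.array_equal(f.core | f.delayed, s)
            assert not (f.salvageable & f.delayed).any()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_fate(np.zeros((4, 4, 2), bool), np.zeros((4, 4, 3), bool))


class TestMirror:
    def test_single_voxel_maps_to_homologue(self):
        m = np.zeros((8, 6, 2), dtype=bool)
        m[5, 3, 1] = True
        out = mirror_homologue(m)
        assert out.sum() == 1 and out[2, 3, 1]

    def test_involution_and_volume(self, rng):
        m = rng.random((10, 8, 4)) < 0.2
        mm = mirror_homologue(mirror_homologue(m, warn_on_overlap=False),
                              warn_on_overlap=False)
        assert np.array_equal(m, mm)
        assert mirror_homologue(m, warn_on_overlap=False).sum() == m.sum()

    def test_midline_overlap_warns(self):
        m = np.ones((4, 2, 1), dtype=bool)
        with pytest.warns(UserWarning, match="mirror"):
            mirror_homologue(m)


class TestVolumes:
    def test_arithmetic_example(self):
        shape = (50, 20, 20)  # right hemisphere: 10,000 voxels
        acute = np.zeros(shape, dtype=bool)
        acute[30, :5, :10] = acute[31, :5, :10] = True  # 100 voxels
        f = classify_fate(acute, acute)
        _, right = hemisphere_masks(shape)
        vols = volume_metrics(f, right, voxel_volume_ul=0.0135)
        row = vols[vols.roi == "acute"].iloc[0]
        assert row.volume_ul == pytest.approx(1.35)
        assert row.hemispheric_fraction == pytest.approx(0.01)
        assert not row.included  # below the 30 uL rule

    def test_empty_lesion_all_zero_excluded(self):
        f = classify_fate(np.zeros((8, 4, 2), bool), np.zeros((8, 4, 2), bool))
        _, right = hemisphere_masks((8, 4, 2))
        vols = volume_metrics(f, right, 0.108)
        assert (vols.volume_ul == 0).all()
        assert not vols.included.any()

    def test_fraction_additivity_on_random_masks(self, rng):
        shape = (12, 10, 4)
        _, right = hemisphere_masks(shape)
        for _ in range(50):
            a = (rng.random(shape) < 0.3) & right
            s = (rng.random(shape) < 0.3) & right
            f = classify_fate(a, s)
            vols = volume_metrics(f, right, 0.108).set_index("roi")
            assert vols.loc["core", "hemispheric_fraction"] + vols.loc[
                "salvageable", "hemispheric_fraction"
            ] == pytest.approx(vols.loc["acute", "hemispheric_fraction"])

    def test_zero_hemisphere_rejected(self):
        f = classify_fate(np.zeros((4, 4, 2), bool), np.zeros((4, 4, 2), bool))
        with pytest.raises(ValueError):
            volume_metrics(f, np.zeros((4, 4, 2), bool), 0.1)


class TestVolumeChange:
    @pytest.mark.parametrize(
        "adc,t2,expected", [(100, 100, 0.0), (100, 50, -50.0), (80, 100, 25.0)]
    )
    def test_closed_form(self, adc, t2, expected):
        assert volume_change(adc, t2) == pytest.approx(expected)

    def test_zero_acute_rejected(self):
        with pytest.raises(ValueError):
            volume_change(0.0, 10.0)


def test_lesion_location_majority_rule(atlas):
    cortex_mask = (atlas == LABELS["cortex"])
    cortex_mask &= np.arange(atlas.shape[0])[:, None, None] >= 20
    assert lesion_location(cortex_mask, atlas) == "cortical"
    striatal = np.isin(atlas, [LABELS["striatum"], LABELS["cpu"]])
    assert lesion_location(striatal, atlas) == "subcortical"
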