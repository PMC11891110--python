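"""Multi-atlas method: selection, partial atlases, registration, fusion."""

import numpy as np
import pytest

import axskel.taxonomy as tax
from axskel.atlas import (
    fuse_joint_centers,
    fuse_labels,
    make_partial_atlases,
    percentile_ranks,
    propagate_labels,
    register_similarity,
    select_atlases,
    spinal_length,
)
from axskel.core import ImageVolume, SimilarityTransform
from axskel.errors import InvalidArgumentError, MissingStructureError, RegistrationError
from axskel.phantom import PhantomSpec, apply_known_similarity, generate_phantom_ldct
from axskel.validation import dice


class TestSpinalLength:
    def test_axis_aligned_distance(self):
        from axskel.core import LabelVolume

        vox = np.zeros((5, 5, 130), dtype=np.int32)
        vox[2, 2, 127] = tax.STRUCTURE_IDS["C1"]
        vox[2, 2, 2] = tax.STRUCTURE_IDS[tax.SACRUM]
        lab = LabelVolume(vox, (4.0,) * 3)
        assert spinal_length(lab) == pytest.approx(125 * 4.0)

    def test_three_four_five_triangle(self):
        from axskel.core import LabelVolume

        # COMs offset by (30, 40, 0) mm on a (3, 4, 4) mm grid
        vox = np.zeros((20, 20, 5), dtype=np.int32)
        vox[0, 0, 2] = tax.STRUCTURE_IDS[tax.SACRUM]
        vox[10, 10, 2] = tax.STRUCTURE_IDS["C1"]
        lab = LabelVolume(vox, (3.0, 4.0, 4.0))
        assert spinal_length(lab) == pytest.approx(50.0)

    def test_phantom_matches_construction_geometry(self, phantom_labels):
        from axskel.core import center_of_mass

        expect = np.linalg.norm(
            (center_of_mass(phantom_labels.mask("C1"))
             - center_of_mass(phantom_labels.mask(tax.SACRUM))) * 4.0
        )
        assert spinal_length(phantom_labels) == pytest.approx(expect, abs=2.0)

    def test_missing_structure(self, phantom_labels):
        from axskel.core import LabelVolume

        vox = np.zeros((3, 3, 3), dtype=np.int32)
        with pytest.raises(MissingStructureError):
            spinal_length(LabelVolume(vox, (4.0,) * 3))


class TestAtlasSelection:
    def test_median_rank_n10(self):
        assert percentile_ranks(10, (50,)) == [5]

    def test_ranks_n45(self):
        assert percentile_ranks(45) == [5, 14, 23, 32, 41]

    def test_indices_point_into_original_list(self):
        rng = np.random.default_rng(0)
        lengths = rng.uniform(500, 650, 45).tolist()
        idx = select_atlases(lengths)
        ordered = sorted(lengths)
        assert [lengths[i] for i in idx] == [ordered[r - 1] for r in [5, 14, 23, 32, 41]]

    def test_degenerate_equal_lengths_distinct_indices(self):
        idx = select_atlases([100.0] * 8)
        assert len(set(idx)) == 5

    def test_too_few_lengths_rejected(self):
        with pytest.raises(InvalidArgumentError):
            select_atlases([1.0, 2.0])


class TestPartialAtlases:
    def test_complete_scan_yields_26_units(self, atlas_library):
        library, _ = atlas_library
        for scan in library:
            assert len(scan) == 26

    def test_unit_decomposition(self):
        assert len(tax.VERTEBRA_UNITS) == 24
        assert len(tax.SIJ_UNITS) == 2

    def test_structures_inside_their_boxes(self, atlas_library):
        library, scans = atlas_library
        ct, labels, seg = scans[0]
        for (upper, lower) in tax.ALL_UNITS:
            uid = tax.unit_id(upper, lower)
            at = library[0][uid]
            lo, hi = at.bbox
            for name in (upper, lower):
                idx = np.argwhere(labels.mask(name))
                assert (idx >= np.asarray(lo)).all() and (idx <= np.asarray(hi)).all()

    def test_missing_structure_skips_unit(self, phantom):
        ct, labels = phantom
        from axskel.morph import segment_morph

        vox = labels.voxels.copy()
        vox[vox == tax.STRUCTURE_IDS["ilium_left"]] = 0
        from axskel.core import LabelVolume

        lab2 = LabelVolume(vox, labels.spacing, labels.origin, labels.taxonomy)
        seg = segment_morph(lab2)
        atlases, qc = make_partial_atlases(ct, lab2, seg)
        assert len(atlases) == 25
        assert any("sacrum-ilium_left" in q for q in qc)


@pytest.fixture(scope="module")
def crop():
    ct, _ = generate_phantom_ldct(PhantomSpec(seed=33))
    return ImageVolume(ct.voxels[4:36, 4:40, 58:102].copy(), ct.spacing, (16.0, 16.0, 232.0))


class TestRegistration:
    def test_self_registration_near_identity(self, crop):
        t = register_similarity(crop.voxels, crop.voxels, 4.0, crop.origin, crop.origin)
        center = crop.index_to_mm((np.array(crop.shape) - 1) / 2)
        assert np.linalg.norm(t.apply_points(center) - center) < 1.0
        assert abs(t.scale - 1.0) < 0.02

    def test_translation_recovery(self, crop):
        center = crop.index_to_mm((np.array(crop.shape) - 1) / 2)
        T = SimilarityTransform.from_params(translation_mm=(8.0, 0.0, 0.0), center_mm=center)
        moved = apply_known_similarity(crop, T)
        g = register_similarity(crop.voxels, moved.voxels, 4.0, crop.origin, crop.origin)
        rec = g.apply_points(center) - center
        assert np.linalg.norm(rec - [8.0, 0.0, 0.0]) < 2.0

    def test_scale_recovery(self, crop):
        center = crop.index_to_mm((np.array(crop.shape) - 1) / 2)
        T = SimilarityTransform.from_params(scale=1.1, center_mm=center)
        moved = apply_known_similarity(crop, T)
        g = register_similarity(crop.voxels, moved.voxels, 4.0, crop.origin, crop.origin)
        assert abs(g.scale - 1.1) < 0.03

    def test_constant_image_rejected(self):
        flat = np.zeros((10, 10, 10), dtype=np.float32)
        with pytest.raises(RegistrationError):
            register_similarity(flat, flat, 4.0)


class TestPropagation:
    def test_identity_transform_unchanged(self, atlas_library):
        library, _ = atlas_library
        at = library[0]["T4-T5"]
        out = propagate_labels(at, SimilarityTransform.identity(), at.labels.shape, at.origin)
        np.testing.assert_array_equal(out, at.labels)

    def test_one_voxel_translation_shift(self, atlas_library):
        library, _ = atlas_library
        at = library[0]["T4-T5"]
        # transform maps fixed point p to moving point p + 4mm along z,
        # so the propagated map is the atlas shifted one voxel down
        t = SimilarityTransform.from_params(translation_mm=(0, 0, 4.0))
        out = propagate_labels(at, t, at.labels.shape, at.origin)
        np.testing.assert_array_equal(out[:, :, :-1], at.labels[:, :, 1:])

    def test_label_set_never_augmented(self, atlas_library):
        library, _ = atlas_library
        at = library[0]["L2-L3"]
        t = SimilarityTransform.from_params((3, 2, -4), 1.05, (5, -3, 2), np.asarray(at.origin))
        out = propagate_labels(at, t, at.labels.shape, at.origin)
        assert set(np.unique(out)) <= set(np.unique(at.labels))


class TestFusion:
    def test_unanimity(self):
        m = np.full((3, 3, 3), 2, dtype=np.int16)
        np.testing.assert_array_equal(fuse_labels([m] * 5), m)

    def test_majority_vote_truth_table(self):
        # 3/5 foreground wins, 2/5 loses, per label
        base = np.zeros((2, 2, 2), dtype=np.int16)
        ivd = base.copy()
        ivd[0, 0, 0] = 2
        out3 = fuse_labels([ivd, ivd, ivd, base, base])
        assert out3[0, 0, 0] == 2
        out2 = fuse_labels([ivd, ivd, base, base, base])
        assert out2[0, 0, 0] == 0

    def test_wrong_count_rejected(self):
        m = np.zeros((2, 2, 2), dtype=np.int16)
        with pytest.raises(InvalidArgumentError):
            fuse_labels([m] * 4)

    def test_idempotent_on_copies(self, atlas_library):
        library, _ = atlas_library
        lab = library[1]["C6-C7"].labels
        np.testing.assert_array_equal(fuse_labels([lab] * 5), lab)

    def test_fuse_joint_centers(self):
        pts = [[0, 0, 0]] * 4 + [[20.0, 0, 0]]
        ijk, mm = fuse_joint_centers(pts, 4.0)
        assert ijk == (1, 0, 0)  # mean 4 mm = 1.0 voxel, half-away rounding
        five = [[8.0, 4.0, 0.0]] * 5
        assert fuse_joint_centers(five, 4.0)[0] == (2, 1, 0)


class TestAtlasSegmentation:
    def test_self_atlas_dice(self, atlas_seg):
        out, morph_ref = atlas_seg
        for name, mask in out.vb.items():
            assert dice(mask, morph_ref.vb[name]) >= 0.95, name

    def test_full_voi_inventory(self, atlas_seg):
        from axskel.voi import build_voi_inventory

        out, _ = atlas_seg
        vois, _ = build_voi_inventory(out)
        assert len(vois) == 118
        kinds = [v.kind for v in vois]
        assert kinds.count("DVU") == 24 and kinds.count("FJ") == 48

    def test_fused_labels_only_from_atlas_labels(self, atlas_seg):
        out, _ = atlas_seg
        # all fused structures belong to the output inventory
        assert set(out.vb) <= set(tax.VERTEBRAE)
        assert set(out.ivd) <= set(tax.VERTEBRA_UNIT_IDS)

    def test_joint_centers_close_to_morph_reference(self, atlas_seg):
        out, morph_ref = atlas_seg
        errs = []
        for jc in out.joint_centers:
            ref = morph_ref.find_center(*jc.key)
            assert ref is not None
            errs.append(np.linalg.norm(np.asarray(jc.mm) - np.asarray(ref.mm)))
        assert np.median(errs) <= 4.0  # within one voxel on the self-target
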