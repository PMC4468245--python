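"""Chan-Vese energy, contour evolution, bone splitting, and mask metrics."""

import numpy as np
import pytest

from pibgm import (CVParams, RegionMask, Volume3D, cv_energy, evolve_contour,
                   region_means, seg_metrics, segment_bone_volume,
                   split_cortex_marrow, transfer_mask_to_pet)
from pibgm.errors import (ConfigError, ContourVanishedError, EmptyRegionError,
                          GridMismatchError)


def exhaustive_min_energy(image, params):
    """Independent oracle: enumerate every non-degenerate labeling.

    Energies are computed from first principles with prefix sums over bit
    masks, not via cv_energy, so the check is two-route.
    """
    flat = np.asarray(image, dtype=float).ravel()
    n = flat.size
    masks = ((np.arange(1, 2**n - 1)[:, None] >> np.arange(n)) & 1).astype(bool)
    n1 = masks.sum(axis=1)
    s1 = masks @ flat
    ss1 = masks @ flat**2
    sse_in = ss1 - s1**2 / n1
    n2 = n - n1
    sse_out = (flat**2).sum() - ss1 - (flat.sum() - s1) ** 2 / n2
    const = 0.0
    if params.epsilon > 0:
        const = params.epsilon * np.sum((flat - params.thresh) ** 2)
    return float(np.min(sse_in + sse_out) + const)


class TestRegionMeans:
    def test_piecewise_constant(self):
        img = np.zeros((4, 4))
        img[:2] = 700.0
        mask = np.zeros((4, 4), bool)
        mask[:2] = True
        m = region_means(img, mask)
        assert (m.c1, m.c2) == (700.0, 0.0)

    def test_complement_swaps_means(self, rng):
        img = rng.random((5, 5))
        mask = rng.random((5, 5)) > 0.5
        if not mask.any() or mask.all():
            mask[0, 0], mask[1, 1] = True, False
        a, b = region_means(img, mask), region_means(img, ~mask)
        assert a.c1 == b.c2 and a.c2 == b.c1

    def test_hand_arithmetic_2x2(self):
        img = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.array([[True, True], [False, False]])
        m = region_means(img, mask)
        assert (m.c1, m.c2) == (1.5, 3.5)

    def test_empty_region_named(self):
        img = np.ones((2, 2))
        with pytest.raises(EmptyRegionError, match="inside"):
            region_means(img, np.zeros((2, 2), bool))
        with pytest.raises(EmptyRegionError, match="outside"):
            region_means(img, np.ones((2, 2), bool))


class TestEnergy:
    def test_true_partition_of_two_level_image_is_zero(self):
        img = np.zeros((4, 4))
        img[:, 2:] = 10.0
        mask = img > 5
        assert cv_energy(img, mask, CVParams(epsilon=0.0)) == 0.0

    def test_one_misassigned_voxel_positive(self):
        img = np.zeros((4, 4))
        img[:, 2:] = 10.0
        mask = img > 5
        mask[0, 0] = True
        assert cv_energy(img, mask, CVParams(epsilon=0.0)) > 0.0

    def test_hand_evaluated_augmented_energy(self):
        """[0,0,10,10], inside the two tens, eps=1, Th=5 -> 0 + 4*25 = 100."""
        img = np.array([[0.0, 0.0, 10.0, 10.0]])
        mask = img > 5
        e = cv_energy(img, mask, CVParams(epsilon=1.0, thresh=5.0))
        assert e == pytest.approx(100.0)

    def test_epsilon_zero_reduces_to_classic(self, rng):
        img = rng.random((4, 4)) * 100
        mask = img > 50
        if not mask.any() or mask.all():
            pytest.skip("degenerate draw")
        base = cv_energy(img, mask, CVParams(epsilon=0.0))
        aug = cv_energy(img, mask, CVParams(epsilon=2.0, thresh=30.0))
        assert aug == pytest.approx(base + 2.0 * np.sum((img - 30.0) ** 2))


class TestEvolve:
    def test_dilated_init_converges_to_truth(self):
        from scipy.ndimage import binary_dilation
        img = np.zeros((12, 12))
        truth = np.zeros((12, 12), bool)
        truth[4:8, 4:8] = True
        img[truth] = 10.0
        init = binary_dilation(truth, iterations=2)
        out = evolve_contour(img, init, CVParams(epsilon=0.0, mu=0.0))
        assert np.array_equal(out, truth)

    def test_truth_is_fixed_point(self):
        img = np.zeros((10, 10))
        truth = np.zeros((10, 10), bool)
        truth[3:7, 3:7] = True
        img[truth] = 10.0
        out = evolve_contour(img, truth, CVParams(epsilon=0.0, mu=0.0))
        assert np.array_equal(out, truth)

    def test_energy_never_increases_from_init(self, rng):
        params = CVParams(epsilon=0.0, mu=0.0)
        for _ in range(10):
            img = rng.random((6, 6)) * 50
            init = rng.random((6, 6)) > 0.5
            if not init.any() or init.all():
                continue
            out = evolve_contour(img, init, params)
            assert (cv_energy(img, out, params)
                    <= cv_energy(img, init, params) + 1e-9)

    def test_converged_mask_is_nearest_mean_classification(self, rng):
        img = rng.random((8, 8)) * 100
        init = img > 60
        if not init.any() or init.all():
            init[0, 0], init[-1, -1] = True, False
        out = evolve_contour(img, init, CVParams(epsilon=0.0, mu=0.0))
        m = region_means(img, out)
        reassign = (img - m.c1) ** 2 < (img - m.c2) ** 2
        ties = (img - m.c1) ** 2 == (img - m.c2) ** 2
        assert np.array_equal(out, reassign | (ties & out))

    def test_exhaustive_minimum_small_images(self, rng):
        """mu=0 evolution attains the brute-force optimum (3x3 here)."""
        params = CVParams(epsilon=0.0, mu=0.0)
        for _ in range(5):
            img = np.round(rng.random((3, 3)) * 20, 1)
            init = np.zeros((3, 3), bool)
            init[1, 1] = True
            out = evolve_contour(img, init, params)
            assert cv_energy(img, out, params) == pytest.approx(
                exhaustive_min_energy(img, params), rel=1e-9, abs=1e-6)

    def test_contour_vanishes_on_constant_image_under_curvature(self):
        img = np.full((16, 16), 8.0)
        init = np.zeros((16, 16), bool)
        init[7:9, 7:9] = True
        with pytest.raises(ContourVanishedError) as err:
            evolve_contour(img, init, CVParams(epsilon=0.0, mu=5.0))
        assert err.value.iteration >= 1

    def test_degenerate_init_rejected(self):
        img = np.zeros((4, 4))
        with pytest.raises(ConfigError):
            evolve_contour(img, np.zeros((4, 4), bool), CVParams(mu=0.0, epsilon=0.0))


class TestSegmentVolume:
    @staticmethod
    def _chain(case, sigma=0.0):
        from pibgm import BedRemovalParams, body_mask_from_pet, remove_bed
        body = body_mask_from_pet(case.pet, BedRemovalParams(smooth_sigma=sigma))
        return remove_bed(case.ct, body), body

    def test_noiseless_phantom_dice_one(self, clean_case):
        ct, body = self._chain(clean_case)
        bone = segment_bone_volume(ct, body, 100.0)
        tpr, fpr, dice = seg_metrics(bone, clean_case.truth_bone)
        assert (tpr, fpr, dice) == (1.0, 0.0, 1.0)

    def test_noisy_phantom_dice(self, noisy_case):
        ct, body = self._chain(noisy_case, sigma=1.0)
        bone = segment_bone_volume(ct, body, 75.0)
        _, _, dice = seg_metrics(bone, noisy_case.truth_bone)
        assert dice >= 0.95

    def test_empty_body_gives_empty_bone(self, clean_case):
        empty = RegionMask.like(clean_case.ct, np.zeros(clean_case.ct.shape, np.int16))
        bone = segment_bone_volume(clean_case.ct, empty, 100.0)
        assert bone.count() == 0

    def test_deterministic(self, noisy_case):
        ct, body = self._chain(noisy_case, sigma=1.0)
        a = segment_bone_volume(ct, body, 75.0)
        b = segment_bone_volume(ct, body, 75.0)
        assert np.array_equal(a.labels, b.labels)


class TestSplit:
    def test_noiseless_split_exact(self, clean_case):
        bone = RegionMask.like(clean_case.ct,
                               clean_case.truth_bone.as_bool().astype(np.int16))
        labels = split_cortex_marrow(clean_case.ct, bone)
        assert np.array_equal(labels.labels, clean_case.truth_bone.labels)

    def test_fixed_cutoff_above_all_is_all_marrow(self, clean_case):
        bone = RegionMask.like(clean_case.ct,
                               clean_case.truth_bone.as_bool().astype(np.int16))
        labels = split_cortex_marrow(clean_case.ct, bone, "fixed:5000")
        assert labels.count("cortex") == 0
        assert labels.count("marrow") == bone.count()

    def test_labels_partition_bone(self, noisy_case):
        bone = RegionMask.like(noisy_case.ct,
                               noisy_case.truth_bone.as_bool().astype(np.int16))
        labels = split_cortex_marrow(noisy_case.ct, bone)
        assert labels.count("marrow") + labels.count("cortex") == bone.count()

    def test_single_valued_bone_rejected_for_otsu(self):
        ct = Volume3D(np.full((4, 16, 16), 500.0), (1, 1, 1), "HU")
        bone = RegionMask.like(ct, np.ones(ct.shape, np.int16))
        with pytest.raises(ConfigError):
            split_cortex_marrow(ct, bone, "otsu")


class TestTransferAndMetrics:
    def test_uniform_pet_transfers_uniform_values(self, clean_case):
        pet = clean_case.pet.with_data(np.full(clean_case.pet.shape, 3.25))
        vals = transfer_mask_to_pet(clean_case.truth_bone, pet)
        assert np.all(vals["whole_bone"] == 3.25)
        assert len(vals["whole_bone"]) == clean_case.truth_bone.count()

    def test_empty_label_yields_empty_collection(self, clean_case):
        binary = RegionMask.like(clean_case.ct,
                                 clean_case.truth_bone.select("marrow").astype(np.int16))
        vals = transfer_mask_to_pet(binary, clean_case.pet)
        assert len(vals["cortex"]) == 0

    def test_noiseless_cortex_mean_equals_uptake(self, clean_case):
        from pibgm import suv_map
        suv = suv_map(clean_case.pet, clean_case.meta, "bw")
        vals = transfer_mask_to_pet(clean_case.truth_bone, suv.volume)
        assert np.isclose(vals["cortex"].mean(),
                          clean_case.spec.pet_uptake["cortex"])

    def test_grid_mismatch(self, clean_case):
        pet = Volume3D(np.zeros((2, 4, 4)), clean_case.pet.spacing, "Bq/mL")
        with pytest.raises(GridMismatchError):
            transfer_mask_to_pet(clean_case.truth_bone, pet)

    def test_identity_and_disjoint_metrics(self):
        spacing = (1.0, 1.0, 1.0)
        t = np.zeros((1, 4, 4), np.int16)
        t[0, :2, :2] = 1
        truth = RegionMask(t, spacing)
        assert seg_metrics(truth, truth) == (1.0, 0.0, 1.0)
        p = np.zeros_like(t)
        p[0, 2:, 2:] = 1
        pred = RegionMask(p, spacing)
        tpr, fpr, dice = seg_metrics(pred, truth)
        assert tpr == 0.0 and dice == 0.0 and fpr > 0.0

    def test_dice_half_hand_case(self):
        spacing = (1.0, 1.0, 1.0)
        t = np.zeros((1, 2, 5), np.int16)
        t[0, 0, :2] = 1              # truth: voxels 0,1
        p = np.zeros_like(t)
        p[0, 0, 1:3] = 1             # pred: voxels 1,2 -> overlap 1
        assert seg_metrics(RegionMask(p, spacing), RegionMask(t, spacing))[2] == 0.5

    def test_dice_symmetric(self, rng):
        spacing = (1.0, 1.0, 1.0)
        a = RegionMask((rng.random((2, 5, 5)) > 0.5).astype(np.int16), spacing)
        b = RegionMask((rng.random((2, 5, 5)) > 0.5).astype(np.int16), spacing)
        if not (a.as_bool().any() and b.as_bool().any()):
            pytest.skip("degenerate draw")
        assert seg_metrics(a, b)[2] == seg_metrics(b, a)[2]

    def test_empty_truth_rejected(self):
        spacing = (1.0, 1.0, 1.0)
        empty = RegionMask(np.zeros((1, 3, 3), np.int16), spacing)
        some = RegionMask(np.ones((1, 3, 3), np.int16), spacing)
        with pytest.raises(EmptyRegionError):
            seg_metrics(some, empty)
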