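"""Innervation classification, SYP coverage and peri-NMJ SC counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eomsc import nmj
from eomsc.synth import NMJSceneSpec, gen_nmj_stack


class TestClassifyInnervation:
    @pytest.mark.parametrize(
        "coverage,category",
        [
            (0.70, "well"),
            (0.45, "partial"),
            (0.10, "poor"),
            (0.60, "partial"),  # boundary: 30-60% band is closed
            (0.30, "partial"),
            (1.0, "well"),
            (0.0, "poor"),
        ],
    )
    def test_category_bands(self, coverage, category):
        assert nmj.classify_innervation(coverage) == category

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nmj.classify_innervation(1.2)

    @given(st.floats(0.0, 1.0))
    @settings(deadline=None, derandomize=True)
    def test_monotone_step_function(self, c):
        order = {"poor": 0, "partial": 1, "well": 2}
        cat = nmj.classify_innervation(c)
        assert cat in order
        eps = 1e-9
        if c + eps <= 1.0:
            assert order[nmj.classify_innervation(c + eps)] >= order[cat]


class TestSypCoverage:
    def test_disjoint_masks_give_zero(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert nmj.syp_coverage(a, b) == 0.0

    def test_superset_gives_one(self):
        a = np.zeros((4, 4), bool)
        a[1:3, 1:3] = True
        assert nmj.syp_coverage(a, np.ones((4, 4), bool)) == 1.0

    def test_pixel_count_oracle(self):
        btx = np.zeros((20, 20), bool)
        btx[:10, :10] = True  # 100 px
        syp = np.zeros((20, 20), bool)
        syp[:10, :5] = True  # 50 px overlap
        assert nmj.syp_coverage(btx, syp) == 0.5

    def test_empty_btx_region_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            nmj.syp_coverage(np.zeros((4, 4), bool), np.ones((4, 4), bool))


class TestDetectNmjs:
    def test_recovers_planted_centroids_and_count(self):
        stack, truth = gen_nmj_stack(NMJSceneSpec(n_nmjs=5, seed=11, image_shape=(3, 700, 700)))
        regions = nmj.detect_nmjs(stack)
        assert len(regions) == 5
        got = regions.centroids_um()
        want = truth.nmjs[["centroid_y_um", "centroid_x_um"]].to_numpy()
        # match each planted NMJ to nearest detection, within one pixel
        for w in want:
            d = np.hypot(got[:, 0] - w[0], got[:, 1] - w[1]).min()
            assert d <= stack.pixel_size

    def test_min_area_above_all_patches_gives_empty(self):
        stack, _ = gen_nmj_stack(NMJSceneSpec(n_nmjs=2, seed=12))
        assert len(nmj.detect_nmjs(stack, min_area_um2=1e5)) == 0

    def test_centroids_are_in_physical_units(self):
        # doubling the pixel size doubles µm centroids for the same voxel grid
        from eomsc.imaging import MultiChannelStack

        stack, _ = gen_nmj_stack(NMJSceneSpec(n_nmjs=1, seed=13))
        r1 = nmj.detect_nmjs(stack)
        stack2 = MultiChannelStack(stack.voxels, stack.channel_names, 2 * stack.pixel_size)
        r2 = nmj.detect_nmjs(stack2, min_area_um2=0)
        np.testing.assert_allclose(2 * r1.centroids_um(), r2.centroids_um())


class TestPeriNmjCounting:
    def test_no_nuclei_means_zero_counts(self):
        stack, _ = gen_nmj_stack(
            NMJSceneSpec(n_nmjs=2, planted_sc_counts=0, distractor_nuclei=0, seed=14)
        )
        counts = nmj.count_peri_nmj_scs(stack, np.array([[50.0, 50.0], [150.0, 150.0]]))
        assert counts.tolist() == [0, 0]

    def test_centroid_distance_rule_at_disc_radius(self):
        # one Pax7+ nucleus at 30 µm is counted; moving the disc so the
        # nucleus sits at 40 µm > 37.5 µm radius excludes it
        stack, truth = gen_nmj_stack(
            NMJSceneSpec(n_nmjs=1, planted_sc_counts=1, distractor_nuclei=0, seed=15)
        )
        nucleus = truth.nuclei.iloc[0][["centroid_y_um", "centroid_x_um"]].to_numpy(float)
        at_30 = nucleus + np.array([30.0, 0.0])
        at_40 = nucleus + np.array([40.0, 0.0])
        counts = nmj.count_peri_nmj_scs(stack, np.stack([at_30, at_40]))
        assert counts.tolist() == [1, 0]

    def test_counts_match_planted_truth(self):
        stack, truth = gen_nmj_stack(NMJSceneSpec(n_nmjs=3, seed=16))
        counts = nmj.count_peri_nmj_scs(
            stack, truth.nmjs[["centroid_y_um", "centroid_x_um"]].to_numpy()
        )
        assert counts.tolist() == truth.nmjs["true_peri_sc_count"].tolist()

    def test_translation_invariance(self):
        stack, truth = gen_nmj_stack(NMJSceneSpec(n_nmjs=2, seed=17))
        shifted = np.roll(stack.voxels, shift=(7, 9), axis=(2, 3))
        from eomsc.imaging import MultiChannelStack

        stack2 = MultiChannelStack(shifted, stack.channel_names, stack.pixel_size)
        cents = truth.nmjs[["centroid_y_um", "centroid_x_um"]].to_numpy()
        shift_um = np.array([7, 9]) * stack.pixel_size
        c1 = nmj.count_peri_nmj_scs(stack, cents)
        c2 = nmj.count_peri_nmj_scs(stack2, cents + shift_um)
        assert c1.tolist() == c2.tolist()

    def test_raising_positivity_fraction_never_raises_counts(self):
        stack, truth = gen_nmj_stack(NMJSceneSpec(n_nmjs=2, seed=18, noise_sd=10.0))
        cents = truth.nmjs[["centroid_y_um", "centroid_x_um"]].to_numpy()
        prev = None
        for frac in (0.2, 0.5, 0.8, 0.99):
            c = nmj.count_peri_nmj_scs(stack, cents, positivity_fraction=frac).sum()
            if prev is not None:
                assert c <= prev
            prev = c


class TestSummaries:
    def _rec(self, cat, group):
        return nmj.NMJRecord(
            id=0, centroid_um=(0, 0), area_um2=100, syp_coverage=0.9, category=cat, group=group,
            peri_sc_count=0,
        )

    def test_single_mouse_ratios(self):
        recs = [self._rec("well", "m1")] * 4 + [self._rec("poor", "m1")]
        summaries, _ = nmj.summarize_innervation(recs)
        assert summaries[0].ratios == {"well": 0.8, "partial": 0.0, "poor": 0.2}

    def test_condition_mean_is_mean_of_mouse_ratios(self):
        recs = [self._rec("well", "m1"), self._rec("poor", "m2")]
        _, cond = nmj.summarize_innervation(recs, condition_of={"m1": "WT", "m2": "WT"})
        assert cond.loc[0, "mean_well"] == 0.5

    def test_ratios_sum_to_one_across_random_scenes(self):
        rng = np.random.default_rng(19)
        recs = []
        for i in range(100):
            cat = rng.choice(["well", "partial", "poor"])
            recs.append(self._rec(cat, f"m{rng.integers(5)}"))
        summaries, _ = nmj.summarize_innervation(recs)
        for s in summaries:
            assert sum(s.ratios.values()) == pytest.approx(1.0)
            assert sum(s.counts.values()) == s.n_nmjs
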