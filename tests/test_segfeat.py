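"""Segmentation and MD/ED/WPD feature contracts.

The brute-force discriminant-threshold scan used here is the independent
oracle for the production Otsu implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk
from skimage.measure import perimeter as sk_perimeter

from focusscore import segfeat as sf
from focusscore import synthgen as sg


def brute_force_otsu(hist: np.ndarray) -> int:
    """Exhaustive scan over all 256 candidate thresholds (the oracle)."""
    hist = np.asarray(hist, dtype=float)
    best_t, best_v = -1, -1.0
    bins = np.arange(256)
    for t in range(256):
        w0 = hist[:t + 1].sum()
        w1 = hist[t + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t + 1] * bins[:t + 1]).sum() / w0
        mu1 = (hist[t + 1:] * bins[t + 1:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:  # strict: lowest index wins ties
            best_t, best_v = t, v
    return best_t


class TestOtsuThreshold:
    def test_two_spike_histogram_tie_broken_low(self):
        h = np.zeros(256)
        h[10] = 50
        h[200] = 50
        assert sf.otsu_threshold(h) == 10 == brute_force_otsu(h)

    def test_single_valued_histogram_is_degenerate(self):
        h = np.zeros(256)
        h[42] = 1000
        with pytest.raises(sf.DegenerateImageError):
            sf.otsu_threshold(h)

    def test_balanced_bimodal_threshold_between_modes(self):
        # overlapping tails keep the variance maximizer interior and unique
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(60, 30, 5000), rng.normal(180, 30, 5000)])
        h = np.bincount(np.clip(np.round(x), 0, 255).astype(int), minlength=256)
        t = sf.otsu_threshold(h)
        assert 100 <= t <= 140
        assert t == brute_force_otsu(h)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_scan_on_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.integers(0, 50, size=256)
        if np.count_nonzero(h) < 2:
            h[[3, 200]] = 5
        assert sf.otsu_threshold(h) == brute_force_otsu(h)


class TestSegmentFocus:
    def test_recovers_generated_cluster(self, small_balanced_manifest):
        rows = small_balanced_manifest.records
        row = rows[rows["label"] == 1].iloc[0]
        ph = sg.sample_phenotype(1, row["chemical"], rng_seed=int(row["_seed"]))
        img, mask = sg.render_image_with_mask(ph, canvas=(224, 224),
                                              rng_seed=int(row["_seed"]))
        region = sf.segment_focus(img)
        overlap = (region.region_mask & mask).sum() / mask.sum()
        assert overlap >= 0.8

    def test_largest_component_selected(self):
        # two saturated blobs on a gray background; the bigger one wins
        img = np.full((224, 224, 3), 180, dtype=np.uint8)
        img[20:45, 20:40] = (120, 40, 130)     # 500 px blob
        img[150:170, 150:160] = (120, 40, 130)  # 200 px blob
        region = sf.segment_focus(img)
        assert region.area_px == 500
        assert region.region_mask[25, 25]
        assert not region.region_mask[155, 155]

    def test_uniform_image_degenerate(self):
        img = np.full((224, 224, 3), 128, dtype=np.uint8)
        with pytest.raises(sf.DegenerateImageError):
            sf.segment_focus(img)

    def test_deterministic(self, small_balanced_manifest):
        img = sg.images_for(small_balanced_manifest)[0]
        a = sf.segment_focus(img)
        b = sf.segment_focus(img)
        assert np.array_equal(a.region_mask, b.region_mask)
        assert a.threshold == b.threshold

    def test_region_perimeter_at_least_equal_area_circle(self, small_balanced_manifest):
        # isoperimetric sanity, up to estimator tolerance
        for img in sg.images_for(small_balanced_manifest)[:6]:
            r = sf.segment_focus(img)
            efp = np.pi * np.sqrt(4 * r.area_px / np.pi)
            assert r.perimeter_px >= 0.9 * efp


class TestFeatures:
    def _region_from_mask(self, mask):
        return sf.SegmentedRegion(mask=mask, region_mask=mask,
                                  area_px=int(mask.sum()),
                                  perimeter_px=float(sk_perimeter(mask, neighborhood=4)),
                                  threshold=0)

    def test_equivalent_diameter_closed_form(self):
        mask = np.zeros((50, 50), bool)
        mask[10:20, 10:20] = True  # area 100
        region = self._region_from_mask(mask)
        fv = sf.compute_features(region, np.full((50, 50), 137.0),
                                 sf.FeatureScaler(1, 1000))
        assert fv.ED == pytest.approx(np.sqrt(400 / np.pi))
        assert fv.EFP == pytest.approx(np.pi * fv.ED)
        assert fv.MD == 137

    def test_disk_has_near_zero_perimeter_excess(self):
        mask = np.zeros((100, 100), bool)
        rr, cc = draw_disk((50, 50), 30)
        mask[rr, cc] = True
        region = self._region_from_mask(mask)
        assert abs(region.perimeter_px - np.pi * np.sqrt(4 * region.area_px / np.pi)) \
            < 0.06 * np.pi * np.sqrt(4 * region.area_px / np.pi)
        fv = sf.compute_features(region, np.zeros((100, 100)),
                                 sf.FeatureScaler(100, 10000))
        assert abs(fv.WPD) < 0.06 * fv.EFP

    @pytest.mark.parametrize("side", [20, 50, 100])
    def test_square_perimeter_within_five_percent(self, side):
        mask = np.zeros((side + 20, side + 20), bool)
        mask[10:10 + side, 10:10 + side] = True
        region = self._region_from_mask(mask)
        assert abs(region.perimeter_px - 4 * side) <= 0.05 * 4 * side + 1e-9

    def test_ed_scale_equivariance_on_nested_disks(self):
        areas, eds = [], []
        for r in (20, 40):
            mask = np.zeros((200, 200), bool)
            rr, cc = draw_disk((100, 100), r)
            mask[rr, cc] = True
            region = self._region_from_mask(mask)
            fv = sf.compute_features(region, np.zeros((200, 200)),
                                     sf.FeatureScaler(1, 10**6))
            areas.append(region.area_px)
            eds.append(fv.ED)
        assert areas[1] / areas[0] == pytest.approx(4.0, rel=0.02)
        assert eds[1] / eds[0] == pytest.approx(2.0, rel=0.02)

    def test_wpd_zero_at_area_min_and_weight_clamped(self):
        mask = np.zeros((40, 40), bool)
        mask[5:25, 5:25] = True
        region = self._region_from_mask(mask)
        scaler = sf.FeatureScaler(area_min=region.area_px, area_max=region.area_px + 500)
        fv = sf.compute_features(region, np.zeros((40, 40)), scaler)
        assert fv.WPD == 0.0
        # weight clamps outside the training extremes
        assert sf.FeatureScaler(1000, 2000).weight(100) == 0.0
        assert sf.FeatureScaler(1000, 2000).weight(99999) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1, 1e6), st.floats(0, 1e6), st.floats(1, 1e7))
    def test_weight_always_in_unit_interval(self, amin, extra, area):
        scaler = sf.FeatureScaler(area_min=amin, area_max=amin + extra)
        assert 0.0 <= scaler.weight(area) <= 1.0

    def test_degenerate_scaler_weight_defined_as_zero(self):
        assert sf.FeatureScaler(50, 50).weight(123) == 0.0

    def test_fallback_features_flagged(self):
        fv = sf.fallback_features(np.full((10, 10), 200.0))
        assert fv.fallback and fv.ED == 0.0 and fv.WPD == 0.0 and fv.MD == 200.0


class TestFitScaler:
    def _regions(self, areas):
        out = []
        for a in areas:
            side = int(np.sqrt(a))
            mask = np.zeros((side + 4, side + 4), bool)
            mask[2:2 + side, 2:2 + side] = True
            out.append(sf.SegmentedRegion(mask=mask, region_mask=mask,
                                          area_px=int(mask.sum()),
                                          perimeter_px=4.0 * side, threshold=0))
        return out

    def test_extremes_of_training_areas(self):
        regs = self._regions([121, 400, 81])
        scaler = sf.fit_scaler(regs)
        assert scaler.area_min == 81 and scaler.area_max == 400

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            sf.fit_scaler(self._regions([100]))

    def test_all_equal_areas(self):
        regs = self._regions([49, 49])
        assert sf.fit_scaler(regs).weight(49) == 0.0
        with pytest.raises(ValueError):
            sf.fit_scaler(regs, allow_degenerate=False)

    def test_bounds_bracket_every_training_area(self):
        areas = (np.arange(10, 110) ** 2)[::7]
        scaler = sf.fit_scaler(self._regions(list(areas)))
        for r in self._regions(list(areas)):
            assert scaler.area_min <= r.area_px <= scaler.area_max


class TestBatchExtraction:
    def test_feature_table_schema_and_md_stain_association(self, small_balanced_manifest):
        df, scaler = sf.extract_batch(small_balanced_manifest)
        assert list(df.columns) == ["id", "label", "MD", "ED", "WPD", "area",
                                    "perimeter", "threshold", "fallback_flag"]
        assert len(df) == len(small_balanced_manifest)
        assert scaler.area_min <= scaler.area_max
        # darker stain -> lower median gray among positives
        rows = small_balanced_manifest.records
        pos = rows[rows["label"] == 1]
        stains = [sg.sample_phenotype(1, r["chemical"], rng_seed=int(r["_seed"])).stain_intensity
                  for _, r in pos.iterrows()]
        mds = df[df["label"] == 1]["MD"].to_numpy()
        slope = np.polyfit(stains, mds, 1)[0]
        assert slope < 0
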