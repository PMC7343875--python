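"""Colour conversion, ΔE metric behaviour, and region sampling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skimage import color as skcolor

from elytra import (
    ContrastProfile,
    LabColour,
    contrast_profile,
    costa_cell_contrast,
    delta_e_cie76,
    pattern_distance_summary,
    sample_region,
    srgb_to_lab,
)
from elytra.color import GeometryError, lab_to_srgb

from conftest import random_lab


def de_oracle(c1, c2):
    """One-line Euclidean reference, independent of the implementation."""
    return math.sqrt((c1.L - c2.L) ** 2 + (c1.a - c2.a) ** 2 + (c1.b - c2.b) ** 2)


class TestSrgbToLab:
    @pytest.mark.parametrize(
        "rgb, expected, tol",
        [
            ((255, 255, 255), (100.0, 0.0, 0.0), 0.01),
            ((0, 0, 0), (0.0, 0.0, 0.0), 1e-6),
            ((255, 0, 0), (53.24, 80.09, 67.20), 0.05),
        ],
    )
    def test_reference_colours(self, rgb, expected, tol):
        lab = srgb_to_lab(rgb)
        assert lab.as_array() == pytest.approx(np.array(expected), abs=tol)

    @pytest.mark.parametrize("rgb", [(-1, 0, 0), (0, 256, 0), (0, 0, 300)])
    def test_out_of_range_channel_rejected(self, rgb):
        with pytest.raises(ValueError):
            srgb_to_lab(rgb)

    def test_round_trip_on_grid(self):
        """All {0,128,255}^3 colours survive Lab round-trip within 0.5/channel."""
        for r in (0, 128, 255):
            for g in (0, 128, 255):
                for b in (0, 128, 255):
                    back = lab_to_srgb(srgb_to_lab((r, g, b)))
                    assert max(abs(x - y) for x, y in zip(back, (r, g, b))) <= 0.5


class TestDeltaE:
    def test_printed_pattern_b_lab_positions(self):
        """Humeral vs mid-elytron positions of the yellow/black pattern."""
        d = delta_e_cie76(LabColour(52, 33, 51), LabColour(64, 25, 52))
        assert d == pytest.approx(math.sqrt(209), abs=1e-3)
        assert d == pytest.approx(14.457, abs=1e-3)

    def test_printed_pattern_c_costa_extremes(self):
        d = delta_e_cie76(LabColour(53, 19, 43), LabColour(40, 27, 30))
        assert d == pytest.approx(math.sqrt(402), abs=1e-3)
        assert d == pytest.approx(20.050, abs=1e-3)

    def test_identity(self, rng):
        c = random_lab(rng)
        assert delta_e_cie76(c, c) == 0.0

    def test_matches_oracle_and_skimage_on_random_pairs(self, rng):
        for _ in range(1000):
            c1, c2 = random_lab(rng, 2)
            d = delta_e_cie76(c1, c2)
            assert d == pytest.approx(de_oracle(c1, c2), abs=1e-12)
            assert d == pytest.approx(
                float(skcolor.deltaE_cie76(c1.as_array(), c2.as_array())), rel=1e-9
            )

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(1000):
            a, b, c = random_lab(rng, 3)
            dab, dba = delta_e_cie76(a, b), delta_e_cie76(b, a)
            assert dab >= 0 and dab == dba
            assert delta_e_cie76(a, c) <= dab + delta_e_cie76(b, c) + 1e-9

    @given(
        st.floats(0, 100), st.floats(-100, 100), st.floats(-100, 100),
        st.floats(0, 100), st.floats(-100, 100), st.floats(-100, 100),
    )
    def test_zero_iff_identical(self, L1, a1, b1, L2, a2, b2):
        d = delta_e_cie76(LabColour(L1, a1, b1), LabColour(L2, a2, b2))
        if (L1, a1, b1) == (L2, a2, b2):
            assert d == 0.0
        else:
            assert d > 0.0


class TestLabColour:
    @pytest.mark.parametrize("L", [-0.1, 100.1, float("nan"), float("inf")])
    def test_invalid_lightness_rejected(self, L):
        with pytest.raises(ValueError):
            LabColour(L, 0, 0)


def constant_image(rgb, h=200, w=200):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[:] = rgb
    return img


FULL_RECT = [(0, 0), (199, 0), (199, 199), (0, 199)]


class TestSampleRegion:
    def test_constant_field_is_exact(self):
        img = constant_image((120, 45, 210))
        rs = sample_region(img, FULL_RECT, seed=0)
        expected = srgb_to_lab((120, 45, 210))
        assert rs.mean_lab.as_array() == pytest.approx(expected.as_array(), abs=1e-9)
        assert rs.n_patches == 10 and len(rs.patch_means) == 10

    def test_noisy_region_recovers_planted_mean(self):
        """CLT bound: |mean − μ| ≤ 4σ/√(10·31²) per channel, ≥95% of seeds."""
        mu = np.array([55.0, 10.0, 20.0])
        sigma = 2.0
        bound = 4 * sigma / math.sqrt(10 * 31 * 31)
        ok = 0
        n_seeds = 100
        for seed in range(n_seeds):
            g = np.random.default_rng(seed)
            lab = mu + g.normal(0, sigma, size=(120, 120, 3))
            lab[..., 0] = np.clip(lab[..., 0], 0, 100)
            img = np.clip(skcolor.lab2rgb(lab), 0, 1)
            rs = sample_region(
                img, [(0, 0), (119, 0), (119, 119), (0, 119)], seed=seed
            )
            if np.all(np.abs(rs.mean_lab.as_array() - mu) <= bound):
                ok += 1
        assert ok >= 0.95 * n_seeds

    def test_zero_area_polygon_is_geometry_error(self):
        img = constant_image((100, 100, 100))
        with pytest.raises(GeometryError):
            sample_region(img, [(5, 5), (5, 5), (5, 5)], seed=0)

    def test_polygon_too_small_for_patch(self):
        img = constant_image((100, 100, 100))
        with pytest.raises(GeometryError):
            sample_region(img, [(0, 0), (10, 0), (10, 10), (0, 10)], seed=0)

    def test_invalid_patch_count(self):
        with pytest.raises(ValueError):
            sample_region(constant_image((1, 1, 1)), FULL_RECT, n_patches=0, seed=0)

    def test_seed_reproducibility_and_positions_exposed(self):
        img = constant_image((90, 120, 30))
        a = sample_region(img, FULL_RECT, seed=7)
        b = sample_region(img, FULL_RECT, seed=7)
        assert a.patch_positions == b.patch_positions != ()

    def test_disjoint_flag_yields_nonoverlapping_patches(self):
        img = constant_image((90, 120, 30))
        rs = sample_region(img, FULL_RECT, seed=3, disjoint=True)
        pos = rs.patch_positions
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                dx = abs(pos[i][0] - pos[j][0])
                dy = abs(pos[i][1] - pos[j][1])
                assert max(dx, dy) >= 31


class TestCostaCellContrast:
    def test_identical_colours_give_zero(self):
        img = constant_image((80, 60, 40))
        pts = [(x, 100) for x in range(10, 150, 10)]
        assert costa_cell_contrast(img, pts, pts, seed=0) == pytest.approx(0.0)

    def test_planted_two_colour_image(self):
        """ΔE of the two planted Lab colours, verified by the in-test oracle."""
        costa_lab = LabColour(53, 19, 43)
        cell_lab = LabColour(20, 5, 5)
        lab = np.zeros((100, 200, 3))
        lab[:, :100] = costa_lab.as_array()
        lab[:, 100:] = cell_lab.as_array()
        img = np.clip(skcolor.lab2rgb(lab), 0, 1)
        costa_pts = [(x, y) for x in range(10, 90, 10) for y in (25, 75)]
        cell_pts = [(x, y) for x in range(110, 190, 10) for y in (25, 75)]
        d = costa_cell_contrast(img, costa_pts, cell_pts, seed=1)
        assert d == pytest.approx(de_oracle(costa_lab, cell_lab), abs=1e-3)
        assert d == pytest.approx(math.sqrt(2729), abs=1e-3)

    def test_too_few_positions_rejected(self):
        img = constant_image((80, 60, 40))
        with pytest.raises(ValueError):
            costa_cell_contrast(img, [(50, 50)], [(60, 60)] * 10, seed=0)


class TestContrastProfile:
    def _sample(self, rgb, label):
        img = constant_image(rgb)
        return sample_region(img, FULL_RECT, seed=0, region_label=label)

    def test_identical_regions_give_zero(self):
        s = {
            r: self._sample((77, 66, 55), r) for r in ("humeral", "middle", "apical")
        }
        prof = contrast_profile(s)
        assert prof.delta_humeral_apical == pytest.approx(0.0)
        assert prof.delta_humeral_middle == pytest.approx(0.0)
        assert prof.delta_costa_cell is None

    def test_planted_humeral_apical_pair(self):
        """Planted humeral (52,33,51) vs apical (20,8,6); oracle-computed ΔE."""
        lab_h, lab_a = LabColour(52, 33, 51), LabColour(20, 8, 6)
        imgs = {}
        for label, lab in (("humeral", lab_h), ("apical", lab_a)):
            field = np.tile(lab.as_array(), (200, 200, 1))
            imgs[label] = sample_region(
                np.clip(skcolor.lab2rgb(field), 0, 1), FULL_RECT, seed=0
            )
        prof = contrast_profile(imgs)
        assert prof.delta_humeral_apical == pytest.approx(
            de_oracle(lab_h, lab_a), abs=1e-3
        )
        assert prof.delta_humeral_apical == pytest.approx(math.sqrt(3674), abs=1e-3)

    def test_humeral_only_is_an_error(self):
        s = {"humeral": self._sample((1, 2, 3), "humeral")}
        with pytest.raises(ValueError):
            contrast_profile(s)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            ContrastProfile(delta_humeral_apical=-1.0)


class TestPatternDistanceSummary:
    def test_identical_records_give_zero_within(self):
        lab = LabColour(50, 10, 10)
        groups = {"A": [{"humeral": lab}, {"humeral": lab}]}
        df = pattern_distance_summary(groups)
        row = df[(df.pattern_1 == "A") & (df.pattern_2 == "A")].iloc[0]
        assert row.mean_delta_e == 0.0 and row.max_delta_e == 0.0

    def test_matches_brute_force_over_all_pairs(self, rng):
        groups = {
            "A": [{"humeral": random_lab(rng)} for _ in range(3)],
            "B": [{"humeral": random_lab(rng)} for _ in range(4)],
        }
        df = pattern_distance_summary(groups)
        # within-A brute force
        a = [g["humeral"] for g in groups["A"]]
        within = [de_oracle(a[i], a[j]) for i in range(3) for j in range(i + 1, 3)]
        row = df[(df.pattern_1 == "A") & (df.pattern_2 == "A")].iloc[0]
        assert row.mean_delta_e == pytest.approx(np.mean(within))
        assert row.max_delta_e == pytest.approx(np.max(within))
        # between A-B brute force
        b = [g["humeral"] for g in groups["B"]]
        between = [de_oracle(x, y) for x in a for y in b]
        row = df[(df.pattern_1 == "A") & (df.pattern_2 == "B")].iloc[0]
        assert row.n_pairs == 12
        assert row.mean_delta_e == pytest.approx(np.mean(between))
        assert row.max_delta_e == pytest.approx(np.max(between))

    def test_singleton_group_flagged_missing(self, rng):
        df = pattern_distance_summary({"C": [{"humeral": random_lab(rng)}]})
        row = df.iloc[0]
        assert row.n_pairs == 0 and np.isnan(row.mean_delta_e)
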