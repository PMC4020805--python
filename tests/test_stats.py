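"""Region sampling and the camera-vs-spectrophotometer statistics."""

import itertools

import numpy as np
import pytest

import floralcam as fc
from conftest import uniform_calibrated


class TestPointSample:
    def test_uniform_image_gives_exact_mean_zero_sd(self):
        img = uniform_calibrated(0.4)
        (s,) = fc.point_sample(img, [(32, 32)])
        assert s.mean == 0.4 and s.sd == 0.0

    def test_default_square_is_15x15_225_pixels(self):
        img = uniform_calibrated(0.4)
        (s,) = fc.point_sample(img, [(20, 20)])
        assert s.pixel_count == 225 and len(s.values) == 225

    def test_mean_matches_explicit_pixel_loop(self, rng):
        img = uniform_calibrated(0.0)
        img.channels[...] = rng.uniform(0, 1, img.channels.shape)
        (s,) = fc.point_sample(img, [(30, 30)], half_size=4)
        acc = []
        for r in range(26, 35):
            for c in range(26, 35):
                acc.append(img.channels[r, c, 0])
        assert s.mean == pytest.approx(np.mean(acc), rel=1e-12)
        assert s.sd == pytest.approx(np.std(acc, ddof=1), rel=1e-12)

    def test_clipped_half_is_excluded_and_counted(self):
        img = uniform_calibrated(0.4)
        img.clipped[:33, :, :] = True  # rows 26..32 of a (26..40) square
        (s,) = fc.point_sample(img, [(33, 33)])
        assert s.flags_excluded == 7 * 15
        assert s.pixel_count == 225
        assert s.mean == pytest.approx(0.4)

    def test_out_of_bounds_square_names_the_centre(self):
        img = uniform_calibrated(0.4)
        with pytest.raises(ValueError, match=r"\(3, 32\)"):
            fc.point_sample(img, [(3, 32)])


class TestGridSample:
    def test_same_seed_selects_same_cells(self):
        img = uniform_calibrated(0.4, shape=(220, 220))
        scheme = fc.GridScheme.scheme_a(seed=42)
        a = fc.grid_sample(img, (10, 10), scheme)
        b = fc.grid_sample(img, (10, 10), scheme)
        assert [s.region_id for s in a] == [s.region_id for s in b]

    def test_scheme_a_selects_3_of_12_cells_of_40px(self):
        img = uniform_calibrated(0.4, shape=(220, 220))
        samples = fc.grid_sample(img, (10, 10), fc.GridScheme.scheme_a(seed=1))
        assert len(samples) == 3
        assert all(s.pixel_count == 1600 for s in samples)
        rows, cols = zip(*(map(int, s.region_id.split("_")[1:])
                           for s in samples))
        assert max(rows) <= 3 and max(cols) <= 2

    def test_exhaustive_selection_is_the_full_cell_set(self):
        img = uniform_calibrated(0.4, shape=(220, 220))
        scheme = fc.GridScheme(4, 3, 40, n_selected=12, seed=9)
        samples = fc.grid_sample(img, (10, 10), scheme)
        ids = {s.region_id for s in samples}
        assert ids == {f"cell_{r}_{c}" for r in range(4) for c in range(3)}

    def test_selection_uniform_over_cells(self):
        """Across seeds every cell of scheme A is chosen ~3/12 of the time."""
        img = uniform_calibrated(0.4, shape=(220, 220))
        counts = {f"cell_{r}_{c}": 0 for r in range(4) for c in range(3)}
        n_draws = 4000
        for seed in range(n_draws):
            scheme = fc.GridScheme.scheme_a(seed=seed)
            for s in fc.grid_sample(img, (10, 10), scheme):
                counts[s.region_id] += 1
        freqs = np.array(list(counts.values())) / n_draws
        np.testing.assert_allclose(freqs, 3 / 12, atol=0.02)

    def test_too_small_bbox_reports_max_cell_size(self):
        img = uniform_calibrated(0.4, shape=(220, 220))
        with pytest.raises(ValueError, match="cell size"):
            fc.grid_sample(img, (10, 100, 10, 100),
                           fc.GridScheme.scheme_a())


def _region(values, region_id="r", channel=0):
    values = np.asarray(values, dtype=float)
    return fc.RegionSample(region_id, channel, len(values),
                           float(values.mean()),
                           float(values.std(ddof=1)) if len(values) > 1
                           else 0.0, values, 0)


def exact_rank_sum_p(a, b):
    """Independent oracle: full enumeration of rank assignments."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in a)
    null = [sum(combo) for combo in
            itertools.combinations(range(1, len(pooled) + 1), len(a))]
    mean_null = np.mean(null)
    dev = abs(observed - mean_null)
    extreme = sum(abs(s - mean_null) >= dev - 1e-12 for s in null)
    return extreme / len(null)


class TestCompareMethods:
    def test_well_separated_triples_give_exact_p_0_1(self):
        cam = [_region([v]) for v in (1.0, 2.0, 3.0)]
        # degenerate single-pixel regions: means are the values themselves
        report = fc.compare_methods(cam, [10.0, 11.0, 12.0])
        row = report["channels"][0]
        assert row["p_value"] == pytest.approx(0.1, abs=1e-12)
        assert row["p_value"] == pytest.approx(
            exact_rank_sum_p([1.0, 2.0, 3.0], [10.0, 11.0, 12.0]))
        assert row["direction"] == "camera_lower"

    def test_matches_enumeration_oracle_on_random_sets(self, rng):
        for _ in range(10):
            a = list(np.round(rng.uniform(0, 1, 4), 6))
            b = list(np.round(rng.uniform(0, 1, 5), 6))
            cam = [_region([v]) for v in a]
            report = fc.compare_methods(cam, b)
            assert report["channels"][0]["p_value"] == pytest.approx(
                exact_rank_sum_p(a, b), abs=1e-9)

    def test_symmetric_in_the_two_samples(self, rng):
        a = rng.uniform(0, 1, 6)
        b = rng.uniform(0, 1, 6)
        p_ab = fc.compare_methods([_region([v]) for v in a],
                                  b)["channels"][0]["p_value"]
        p_ba = fc.compare_methods([_region([v]) for v in b],
                                  a)["channels"][0]["p_value"]
        assert p_ab == pytest.approx(p_ba, rel=1e-12)

    def test_identical_tied_samples_report_p_1_with_warning(self):
        cam = [_region([0.5]) for _ in range(3)]
        report = fc.compare_methods(cam, [0.5, 0.5, 0.5])
        row = report["channels"][0]
        assert row["p_value"] == 1.0
        assert row["warning"] is not None

    def test_type_i_error_near_5pct_under_null(self):
        rng = np.random.default_rng(777)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0.5, 0.05, 8)
            b = rng.normal(0.5, 0.05, 8)
            cam = [_region([v]) for v in a]
            p = fc.compare_methods(cam, b)["channels"][0]["p_value"]
            rejections += p < 0.05
        # exact test at n=8+8: attainable alpha just below 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.02)

    def test_pixel_mode_pools_region_values(self):
        cam = [_region([0.1, 0.2, 0.3]), _region([0.4, 0.5, 0.6], "r2")]
        report = fc.compare_methods(cam, [0.15, 0.35, 0.55], mode="pixels")
        assert report["channels"][0]["n_camera"] == 6

    def test_fewer_than_three_values_errors(self):
        cam = [_region([0.1]), _region([0.2])]
        with pytest.raises(ValueError, match=">= 3"):
            fc.compare_methods(cam, [0.1, 0.2, 0.3])

    def test_holm_adjustment_is_monotone_and_bounded(self):
        cam = ([_region([v], channel=0) for v in (0.1, 0.2, 0.3)]
               + [_region([v], channel=1) for v in (10.0, 11.0, 12.0)])
        report = fc.compare_methods(cam, [0.12, 0.22, 0.32])
        for row in report["channels"]:
            assert row["p_holm"] >= row["p_value"]
            assert row["p_holm"] <= 1.0


class TestNormalityCheck:
    def test_gaussian_sample_typically_passes(self, rng):
        s = _region(rng.normal(0.5, 0.1, 500))
        out = fc.normality_check(s)
        assert out["p_value"] > 0.05 and out["normal_at_005"]

    def test_bimodal_sample_rejected(self, rng):
        vals = np.concatenate([rng.normal(0.2, 0.02, 250),
                               rng.normal(0.8, 0.02, 250)])
        out = fc.normality_check(_region(vals))
        assert out["p_value"] < 0.05 and not out["normal_at_005"]

    def test_n_2_violates_precondition(self):
        with pytest.raises(ValueError, match="3 <= n"):
            fc.normality_check(_region([0.1, 0.2]))

    def test_constant_sample_errors(self):
        with pytest.raises(ValueError, match="constant"):
            fc.normality_check(_region([0.4, 0.4, 0.4, 0.4]))


class TestVariabilitySummary:
    def test_identical_channels_declared_tied(self):
        data = [_region([0.1, 0.2]), _region([0.3, 0.4]),
                _region([0.5, 0.6])]
        out = fc.variability_summary({"red": data, "green": data})
        ranks = out["dispersion_rank"]
        assert ranks["red"] == ranks["green"] == 1

    def test_flat_uv_channel_ranks_least_variable(self, rng):
        patterned = [_region(rng.uniform(0.2, 0.9, 50) + off)
                     for off in (0.0, 0.3, -0.1, 0.2)]
        flat = [_region(rng.normal(0.5, 0.005, 50) + off)
                for off in (0.0, 0.002, -0.001, 0.001)]
        out = fc.variability_summary({"red": patterned, "uv": flat})
        assert (out["dispersion_rank"]["uv"]
                > out["dispersion_rank"]["red"])

    def test_single_region_errors(self):
        with pytest.raises(ValueError, match=">= 2 regions"):
            fc.variability_summary({"red": [_region([0.1, 0.2])]})
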