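import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import object_from_coords, weighted_ecdf_percent
from subcelldist.distances import DistanceRecord
from subcelldist.quantify import (
    MoleculeEstimate,
    calibrate_single_molecule,
    cumulative_profile,
    estimate_molecules,
    fraction_by_bin,
    fraction_overlapping,
    restrict_roi,
)


def obj(oid, volume, intensity):
    coords = [(0, 0, i) for i in range(volume)]
    o = object_from_coords(coords, object_id=oid)
    o.total_intensity = float(intensity)
    return o


def rec(oid, d):
    return DistanceRecord("img", oid, 1, d, "heuristic")


class TestCalibration:
    def test_mean_over_qualifying_objects_only(self):
        objects = [obj(1, 30, 90), obj(2, 50, 110), obj(3, 500, 4000)]
        cal = calibrate_single_molecule(objects, (20, 100))
        assert cal.mean_single_molecule_intensity == 100.0
        assert cal.n_calibration_objects == 2

    def test_window_bounds_inclusive(self):
        objects = [obj(1, 20, 50), obj(2, 100, 150), obj(3, 101, 999), obj(4, 19, 999)]
        cal = calibrate_single_molecule(objects, (20, 100))
        assert cal.n_calibration_objects == 2
        assert cal.mean_single_molecule_intensity == 100.0

    def test_no_qualifying_objects_reports_window_and_range(self):
        with pytest.raises(ValueError, match=r"\[20, 100\].*150\.\.300"):
            calibrate_single_molecule([obj(1, 150, 1), obj(2, 300, 1)], (20, 100))

    def test_objects_outside_window_never_change_mean(self):
        base = [obj(1, 40, 80), obj(2, 60, 120)]
        cal0 = calibrate_single_molecule(base, (20, 100))
        extended = base + [obj(3, 5000, 1e6), obj(4, 5, 1e-3)]
        cal1 = calibrate_single_molecule(extended, (20, 100))
        assert cal0.mean_single_molecule_intensity == cal1.mean_single_molecule_intensity


class TestMoleculeEstimates:
    def test_ratio_formula_and_granule_flag(self):
        cal = calibrate_single_molecule([obj(1, 50, 100)], (20, 100))
        est = estimate_molecules([obj(2, 200, 450), obj(3, 50, 100)], cal)
        assert est[0].molecules == 4.5 and est[0].is_granule
        assert est[1].molecules == 1.0 and not est[1].is_granule

    def test_granule_threshold_strict_at_exactly_four(self):
        cal = calibrate_single_molecule([obj(1, 50, 100)], (20, 100))
        (exactly_four,) = estimate_molecules([obj(2, 60, 400)], cal)
        assert exactly_four.molecules == 4.0
        assert not exactly_four.is_granule
        (just_over,) = estimate_molecules([obj(3, 60, 400.0001)], cal)
        assert just_over.is_granule

    def test_estimates_not_rounded(self):
        cal = calibrate_single_molecule([obj(1, 50, 100)], (20, 100))
        (e,) = estimate_molecules([obj(2, 60, 123)], cal)
        assert e.molecules == 1.23


class TestCumulativeProfile:
    def test_two_point_distribution(self):
        records = [rec(1, 0.0), rec(2, 0.3)]
        prof = cumulative_profile(records, weight_mode="object_count", step_um=0.05, max_distance_um=0.5)
        np.testing.assert_allclose(prof.grid[:3], [0, 0.05, 0.1])
        assert prof.cumulative_percent[0] == 50.0
        assert all(prof.cumulative_percent[i] == 50.0 for i in range(6))  # up to 0.25
        assert all(prof.cumulative_percent[i] == 100.0 for i in range(6, 11))

    def test_everything_at_zero_is_flat_100(self):
        prof = cumulative_profile([rec(1, 0.0), rec(2, 0.0)], weight_mode="object_count")
        assert (prof.cumulative_percent == 100.0).all()

    def test_matches_brute_force_weighted_ecdf(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(0, 3, size=40)
        w = rng.uniform(0.5, 5, size=40)
        records = [rec(i + 1, float(di)) for i, di in enumerate(d)]
        estimates = [MoleculeEstimate(i + 1, float(wi), wi > 4) for i, wi in enumerate(w)]
        prof = cumulative_profile(records, estimates=estimates, weight_mode="molecules",
                                  step_um=0.05, max_distance_um=5.0)
        np.testing.assert_allclose(
            prof.cumulative_percent, weighted_ecdf_percent(d, w, prof.grid)
        )

    def test_molecule_mode_requires_estimates(self):
        with pytest.raises(ValueError, match="estimates"):
            cumulative_profile([rec(1, 0.1)], weight_mode="molecules")

    @settings(deadline=None, max_examples=25)
    @given(
        distances=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=30),
        weights=st.lists(st.floats(0.01, 100, allow_nan=False), min_size=30, max_size=30),
    )
    def test_profile_monotone_and_bounded(self, distances, weights):
        records = [rec(i + 1, d) for i, d in enumerate(distances)]
        estimates = [
            MoleculeEstimate(i + 1, w, w > 4) for i, w in enumerate(weights[: len(distances)])
        ]
        prof = cumulative_profile(records, estimates=estimates, weight_mode="molecules",
                                  step_um=0.25, max_distance_um=12.0)
        assert (np.diff(prof.cumulative_percent) >= -1e-9).all()
        assert prof.cumulative_percent[-1] == pytest.approx(100.0)


class TestBins:
    def test_single_object_lands_in_its_bin(self):
        df = fraction_by_bin([rec(1, 0.12)], weight_mode="object_count",
                             step_um=0.05, max_distance_um=0.5)
        hot = df[df.bin_percent > 0]
        assert len(hot) == 1
        assert hot.iloc[0].distance_um == pytest.approx(0.15)  # bin (0.10, 0.15]
        assert hot.iloc[0].bin_percent == 100.0

    def test_bins_plus_remainder_sum_to_100(self):
        rng = np.random.default_rng(8)
        records = [rec(i + 1, float(d)) for i, d in enumerate(rng.uniform(0, 8, size=25))]
        df = fraction_by_bin(records, weight_mode="object_count", step_um=0.05, max_distance_um=5.0)
        assert df.bin_percent.sum() + df.attrs["beyond_max_percent"] == pytest.approx(100.0)

    def test_differencing_cumulative_reproduces_bins(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(0, 2, size=30)
        records = [rec(i + 1, float(x)) for i, x in enumerate(d)]
        prof = cumulative_profile(records, weight_mode="object_count", step_um=0.1, max_distance_um=3.0)
        df = fraction_by_bin(records, weight_mode="object_count", step_um=0.1, max_distance_um=3.0)
        np.testing.assert_allclose(np.cumsum(df.bin_percent.to_numpy()), prof.cumulative_percent)

    def test_uniform_distances_fill_bins_evenly(self):
        # uniform on (0, 1], step 0.1: each bin expects ~10% within 3 sigma
        rng = np.random.default_rng(0)
        n = 10000
        d = rng.uniform(1e-9, 1.0, size=n)
        records = [rec(i + 1, float(x)) for i, x in enumerate(d)]
        df = fraction_by_bin(records, weight_mode="object_count", step_um=0.1, max_distance_um=1.0)
        bins = df.bin_percent.to_numpy()[1:]  # skip the d=0 grid point
        p = 0.1
        sigma = 100 * np.sqrt(p * (1 - p) / n)
        assert np.abs(bins - 10.0).max() < 3 * sigma


class TestFractionOverlapping:
    def test_weighted_overlap_percent(self):
        records = [rec(1, 0.0), rec(2, 0.5), rec(3, 0.0)]
        estimates = [MoleculeEstimate(1, 1, False), MoleculeEstimate(2, 1, False),
                     MoleculeEstimate(3, 2, False)]
        assert fraction_overlapping(records, estimates=estimates) == pytest.approx(75.0)

    def test_no_object_at_zero(self):
        records = [rec(1, 0.5)]
        assert fraction_overlapping(records, weight_mode="object_count") == 0.0

    def test_granules_only_restricts_numerator_not_denominator(self):
        mols = {1: 1.0, 2: 2.0, 3: 6.0, 4: 10.0}
        dists = {1: 0.0, 2: 1.0, 3: 0.0, 4: 1.0}
        records = [rec(i, dists[i]) for i in mols]
        estimates = [MoleculeEstimate(i, m, m > 4) for i, m in mols.items()]
        pct = fraction_overlapping(records, estimates=estimates, granules_only=True)
        assert pct == pytest.approx(100 * 6 / 19)


class TestROI:
    def objects(self):
        return [
            object_from_coords([(1, 1, 1)], object_id=1),
            object_from_coords([(2, 5, 5)], object_id=2),
            object_from_coords([(3, 9, 9)], object_id=3),
        ]

    def test_whole_image_is_identity(self):
        objs = self.objects()
        assert restrict_roi(objs, ((0, 10), (0, 10), (0, 10))) == objs

    def test_boundary_centroid_included(self):
        objs = self.objects()
        kept = restrict_roi(objs, ((1, 2), (1, 5), (1, 5)))
        assert [o.object_id for o in kept] == [1, 2]

    def test_roi_excluding_everything(self):
        assert restrict_roi(self.objects(), ((8, 9), (0, 1), (0, 1))) == []

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="empty"):
            restrict_roi(self.objects(), np.zeros((4, 10, 10), dtype=bool))
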