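import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moeyield import features as ft
from moeyield.errors import (InsufficientCoverageError, InvalidInputError,
                             NotFittedError, UndefinedIndexError)


class TestIndices:
    def test_ndvi_direct(self):
        assert ft.compute_ndvi(0.4, 0.1) == pytest.approx(0.6)

    def test_ndvi_symmetry_zero(self):
        assert ft.compute_ndvi(0.25, 0.25) == 0.0

    def test_ndvi_derived_value(self):
        # (0.35 - 0.07) / (0.35 + 0.07)
        assert ft.compute_ndvi(0.35, 0.07) == pytest.approx(0.666667, abs=1e-4)

    def test_ndvi_zero_denominator(self):
        with pytest.raises(UndefinedIndexError):
            ft.compute_ndvi(0.0, 0.0)

    def test_nirv_product_identity(self, rng):
        nir = rng.uniform(0.05, 0.6, 50)
        red = rng.uniform(0.01, 0.3, 50)
        np.testing.assert_allclose(ft.compute_nirv(nir, red),
                                   nir * ft.compute_ndvi(nir, red))

    def test_nirv_examples(self):
        assert ft.compute_nirv(0.4, 0.1) == pytest.approx(0.24)
        assert ft.compute_nirv(0.3, 0.3) == 0.0
        assert ft.compute_nirv(0.35, 0.07) == pytest.approx(0.233333, abs=1e-4)

    def test_evi_hand_value(self):
        # 2.5 * (0.4 - 0.1) / (0.4 + 0.6 - 0.375 + 1) = 0.75 / 1.625
        assert ft.compute_evi(0.4, 0.1, 0.05) == pytest.approx(0.461538,
                                                               abs=1e-4)

    def test_evi_zero_when_nir_equals_red(self):
        assert ft.compute_evi(0.2, 0.2, 0.05) == 0.0

    def test_evi_missing_blue_raises(self):
        with pytest.raises(UndefinedIndexError):
            ft.compute_evi(0.4, 0.1, np.nan)

    def test_gndvi_examples(self):
        assert ft.compute_gndvi(0.4, 0.1) == pytest.approx(0.6)
        assert ft.compute_gndvi(0.3, 0.3) == 0.0
        assert ft.compute_gndvi(0.5, 0.2) == pytest.approx(0.428571, abs=1e-4)

    @given(nir=st.floats(0.01, 1.0), red=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_ndvi_bounded(self, nir, red):
        assert -1.0 <= ft.compute_ndvi(nir, red) <= 1.0


class TestMagnusHumidity:
    def test_saturation_is_100(self):
        assert ft.relative_humidity_magnus(15.0, 15.0) == pytest.approx(100.0)

    def test_known_value(self):
        # direct evaluation with a=17.625, b=243.04
        a, b = 17.625, 243.04
        expected = 100 * np.exp(a * 10 / (b + 10) - a * 20 / (b + 20))
        got = ft.relative_humidity_magnus(20.0, 10.0)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(52.5, abs=0.1)

    def test_very_dry_air(self):
        rh = ft.relative_humidity_magnus(30.0, -40.0)
        assert 0.0 < rh < 5.0

    def test_dewpoint_above_air_temperature_raises(self):
        with pytest.raises(InvalidInputError):
            ft.relative_humidity_magnus(10.0, 15.0)

    def test_nonfinite_raises(self):
        with pytest.raises(InvalidInputError):
            ft.relative_humidity_magnus(np.nan, 5.0)


def _complete_matrix(rng):
    x = rng.uniform(0.1, 0.9, size=(10, 10))
    x[:, 8] = 1200.0  # DEM constant
    x[:, 9] = 20.0    # SoC constant
    return x


class TestAssembleSeason:
    def test_complete_input_passthrough(self, rng):
        x = _complete_matrix(rng)
        out = ft.assemble_season("C0", 2020, x, 5000.0)
        np.testing.assert_array_equal(out.x, x)

    def test_idempotent_on_complete(self, rng):
        x = _complete_matrix(rng)
        once = ft.assemble_season("C0", 2020, x)
        twice = ft.assemble_season("C0", 2020, once.x)
        np.testing.assert_array_equal(once.x, twice.x)

    def test_interior_gap_linear_midpoint(self, rng):
        x = _complete_matrix(rng)
        x[4, 0] = np.nan  # month 5 NDVI missing; months 4 and 6 present
        out = ft.assemble_season("C0", 2020, x)
        assert out.x[4, 0] == pytest.approx((x[3, 0] + x[5, 0]) / 2)

    def test_end_gap_nearest_extension(self, rng):
        x = _complete_matrix(rng)
        x[0, 0] = np.nan
        out = ft.assemble_season("C0", 2020, x)
        assert out.x[0, 0] == pytest.approx(x[1, 0])

    def test_five_months_dropped(self, rng):
        x = _complete_matrix(rng)
        x[0:5, 1] = np.nan
        with pytest.raises(InsufficientCoverageError):
            ft.assemble_season("C0", 2020, x)

    def test_static_broadcast(self, rng):
        x = _complete_matrix(rng)
        x[1:, 8] = np.nan
        out = ft.assemble_season("C0", 2020, x)
        assert np.all(out.x[:, 8] == 1200.0)


class TestTruncate:
    def test_identity_at_m10(self, rng):
        s = ft.assemble_season("C0", 2020, _complete_matrix(rng), 5000.0)
        np.testing.assert_array_equal(ft.truncate_to_month(s, 10).x, s.x)

    def test_single_month(self, rng):
        s = ft.assemble_season("C0", 2020, _complete_matrix(rng))
        assert ft.truncate_to_month(s, 1).x.shape == (1, 10)

    def test_matches_slice_oracle(self, rng):
        s = ft.assemble_season("C0", 2020, _complete_matrix(rng))
        np.testing.assert_array_equal(ft.truncate_to_month(s, 7).x, s.x[:7])

    def test_out_of_range(self, rng):
        s = ft.assemble_season("C0", 2020, _complete_matrix(rng))
        with pytest.raises(ValueError):
            ft.truncate_to_month(s, 11)


class TestScaler:
    def _samples(self, cols):
        out = []
        for i, val in enumerate(cols):
            x = np.full((10, 10), float(val))
            out.append(ft.SeasonTensor(f"C{i}", 2000 + i, x, 1000.0 * (i + 1)))
        return out

    def test_train_maps_to_unit_interval(self):
        scaler = ft.fit_scaler(self._samples([2, 4, 6]))
        scaled = scaler.transform_x(np.full((10, 10), 4.0))
        np.testing.assert_allclose(scaled, 0.5)

    def test_out_of_range_test_value(self):
        scaler = ft.fit_scaler(self._samples([2, 4, 6]))
        np.testing.assert_allclose(scaler.transform_x(np.full((10, 10), 8.0)),
                                   1.5)

    def test_matches_sklearn_oracle(self, rng):
        sklearn = pytest.importorskip("sklearn.preprocessing")
        samples = []
        for i in range(5):
            samples.append(ft.SeasonTensor(f"C{i}", 2000,
                                           rng.uniform(0, 5, (10, 10)),
                                           100.0))
        scaler = ft.fit_scaler(samples, scale_target=False)
        stacked = np.vstack([s.x for s in samples])
        ref = sklearn.MinMaxScaler().fit(stacked)
        probe = rng.uniform(0, 5, (10, 10))
        np.testing.assert_allclose(scaler.transform_x(probe),
                                   ref.transform(probe), atol=1e-12)

    def test_target_roundtrip(self):
        scaler = ft.fit_scaler(self._samples([2, 4, 6]))
        y = 1234.5
        assert scaler.inverse_transform_y(scaler.transform_y(y)) == \
            pytest.approx(y, abs=1e-9)

    def test_constant_feature_scales_to_zero(self):
        scaler = ft.fit_scaler(self._samples([3, 3, 3]))
        np.testing.assert_allclose(scaler.transform_x(np.full((10, 10), 3.0)),
                                   0.0)

    def test_apply_before_fit_raises(self):
        with pytest.raises(NotFittedError):
            ft.MinMaxScaler().transform_x(np.zeros((10, 10)))

    def test_leakage_sentinel(self):
        """Sentinel extremes in a held-out split must not move the fit."""
        train = self._samples([2, 4, 6])
        scaler = ft.fit_scaler(train)
        test_sentinel = self._samples([1000])
        refit = ft.fit_scaler(train + test_sentinel)
        assert scaler.feature_max[0] == 6.0
        assert refit.feature_max[0] == 1000.0  # refit would have leaked
        # transform of the sentinel with train-only params exits [0, 1]
        assert scaler.transform_x(test_sentinel[0].x).max() > 1.0

    def test_serialization_roundtrip(self):
        scaler = ft.fit_scaler(self._samples([2, 4, 6]))
        clone = ft.MinMaxScaler.from_dict(scaler.to_dict())
        probe = np.full((10, 10), 5.0)
        np.testing.assert_allclose(clone.transform_x(probe),
                                   scaler.transform_x(probe))
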