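import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roiconcord import (
    MeasurementTable,
    ROIMap,
    combine_thickness,
    combine_volume,
    default_roi_map,
    harmonize,
    normalize_tiv,
)
from roiconcord.errors import ConfigError, DataError, DegenerateInputError, MappingError

finite_pos = st.floats(0.1, 1e4, allow_nan=False, allow_infinity=False)


class TestCombineThickness:
    def test_area_weighted_mean(self):
        assert combine_thickness([2.0, 2.6], [100, 50]) == pytest.approx(2.2)

    def test_constant_input(self):
        assert combine_thickness([2.4, 2.4], [37.0, 123.0]) == pytest.approx(2.4)

    def test_zero_weight_side_drops_out(self):
        assert combine_thickness([2.0, 3.0], [1.0, 0.0]) == pytest.approx(2.0)

    def test_zero_total_area_raises(self):
        with pytest.raises(DegenerateInputError):
            combine_thickness([2.0, 3.0], [0.0, 0.0])

    def test_shape_mismatch_raises(self):
        with pytest.raises(DataError):
            combine_thickness([2.0, 3.0], [1.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.tuples(finite_pos, finite_pos), min_size=1, max_size=6),
        st.randoms(use_true_random=False),
    )
    def test_bounds_and_permutation_invariance(self, pairs, rnd):
        thick, area = map(list, zip(*pairs))
        out = combine_thickness(thick, area)
        assert min(thick) - 1e-9 <= out <= max(thick) + 1e-9
        perm = list(range(len(pairs)))
        rnd.shuffle(perm)
        shuffled = combine_thickness([thick[i] for i in perm], [area[i] for i in perm])
        assert out == pytest.approx(shuffled)


class TestVolumeOps:
    @pytest.mark.parametrize(
        "vols,expected", [([1000, 500], 1500), ([42.0], 42.0), ([3800, 3600], 7400)]
    )
    def test_sum(self, vols, expected):
        assert combine_volume(vols) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(DegenerateInputError):
            combine_volume([])

    def test_normalize_tiv(self):
        assert normalize_tiv(1500, 1_500_000) == pytest.approx(0.001)
        # joint rescaling cancels
        assert normalize_tiv(3000, 3_000_000) == pytest.approx(normalize_tiv(1500, 1_500_000))

    def test_nonpositive_tiv_raises(self):
        with pytest.raises(DataError):
            normalize_tiv(1500, 0.0)


class TestROIMap:
    def test_default_map_has_28_masters_per_technique(self):
        m = default_roi_map()
        for tech in ("freesurfer", "freesurfer_volume", "spm"):
            assert len(m.master_rois(tech)) == 28

    def test_duplicate_sub_roi_rejected(self):
        rows = [
            ("a", "t", "x", "left", "volume"),
            ("b", "t", "x", "left", "volume"),
        ]
        with pytest.raises(ConfigError):
            ROIMap(pd.DataFrame(rows, columns=["master_roi", "technique", "sub_roi", "hemisphere", "measure_kind"]))

    def test_mixed_kind_within_master_rejected(self):
        rows = [
            ("a", "t", "x", "left", "volume"),
            ("a", "t", "x", "right", "thickness"),
        ]
        with pytest.raises(ConfigError):
            ROIMap(pd.DataFrame(rows, columns=["master_roi", "technique", "sub_roi", "hemisphere", "measure_kind"]))


def _one_roi_map(kind):
    rows = [("m", "t", "x", h, kind) for h in ("left", "right")]
    return ROIMap(pd.DataFrame(rows, columns=["master_roi", "technique", "sub_roi", "hemisphere", "measure_kind"]))


class TestHarmonize:
    def test_volume_identity_mapping_normalized_by_tiv(self):
        m = _one_roi_map("volume")
        vals = pd.DataFrame(
            {"x_left_volume": [3800.0, 1000.0], "x_right_volume": [3600.0, 500.0]},
            index=pd.Index(["s1", "s2"], name="subject_id"),
        )
        tiv = pd.Series([1.48e6, 1.5e6], index=vals.index)
        out = harmonize(MeasurementTable("t", vals), m, tiv)
        np.testing.assert_allclose(out.values["m"], [7400 / 1.48e6, 1500 / 1.5e6])

    def test_thickness_reproduces_weighted_formula(self):
        m = _one_roi_map("thickness")
        vals = pd.DataFrame(
            {
                "x_left_thickness": [2.0],
                "x_right_thickness": [2.6],
                "x_left_area": [100.0],
                "x_right_area": [50.0],
            },
            index=pd.Index(["s1"], name="subject_id"),
        )
        out = harmonize(MeasurementTable("t", vals), m, pd.Series([1.5e6], index=vals.index))
        assert out.values.loc["s1", "m"] == pytest.approx(2.2)

    def test_default_map_shape_contract(self, small_cohort):
        _, subjects, tables = small_cohort
        out = harmonize(tables["spm"], default_roi_map(), subjects["tiv_spm"])
        assert out.values.shape == (len(subjects), 28)
        assert list(out.values.index) == list(subjects.index)

    def test_thickness_within_constituent_bounds(self, small_cohort):
        _, subjects, tables = small_cohort
        out = harmonize(tables["freesurfer"], default_roi_map(), subjects["tiv_freesurfer"])
        fs = tables["freesurfer"].values
        thick_cols = ["supramarginal_left_thickness", "supramarginal_right_thickness"]
        lo = fs[thick_cols].min(axis=1)
        hi = fs[thick_cols].max(axis=1)
        assert ((lo - 1e-12 <= out.values["supramarginal"]) & (out.values["supramarginal"] <= hi + 1e-12)).all()

    def test_volume_exact_sum_over_tiv(self, small_cohort):
        _, subjects, tables = small_cohort
        out = harmonize(tables["spm"], default_roi_map(), subjects["tiv_spm"])
        spm = tables["spm"].values
        cols = [c for c in spm.columns if c.startswith(("occipital_sup", "occipital_mid", "occipital_inf"))]
        expected = spm[cols].sum(axis=1) / subjects["tiv_spm"]
        np.testing.assert_allclose(out.values["lateral_occipital"], expected, rtol=1e-12)

    def test_column_permutation_invariance(self, small_cohort):
        _, subjects, tables = small_cohort
        t = tables["spm"]
        shuffled = MeasurementTable("spm", t.values[list(reversed(t.values.columns))])
        a = harmonize(t, default_roi_map(), subjects["tiv_spm"]).values
        b = harmonize(shuffled, default_roi_map(), subjects["tiv_spm"]).values
        pd.testing.assert_frame_equal(a, b)

    def test_missing_column_listed_in_error(self, small_cohort):
        _, subjects, tables = small_cohort
        vals = tables["spm"].values.drop(columns=["hippocampus_left_volume"])
        with pytest.raises(MappingError, match="hippocampus_left_volume"):
            harmonize(MeasurementTable("spm", vals), default_roi_map(), subjects["tiv_spm"])

    def test_missing_area_column_raises(self):
        m = _one_roi_map("thickness")
        vals = pd.DataFrame(
            {"x_left_thickness": [2.0], "x_right_thickness": [2.6], "x_left_area": [100.0]},
            index=pd.Index(["s1"], name="subject_id"),
        )
        with pytest.raises(MappingError, match="area"):
            harmonize(MeasurementTable("t", vals), m, pd.Series([1.5e6], index=vals.index))

    def test_nonpositive_measurements_rejected(self):
        with pytest.raises(DataError):
            MeasurementTable("t", pd.DataFrame({"x_left_volume": [0.0]}, index=["s1"]))
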