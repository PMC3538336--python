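import math

import numpy as np
import pytest

from conftest import single_component, mask_to_components
from oracles import digital_disk, digital_ellipse
from seedscan import (
    FilterConfig,
    aspect_filter,
    ellipse_consistency,
    filter_components,
    measure_component,
    model_area,
)
from seedscan.morphometry import ComponentMeasure, records_to_frame, write_records_csv


def measure_mask_single(mask):
    return measure_component(single_component(mask))


class TestMeasureComponent:
    def test_single_pixel_is_isotropic(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        meas = measure_mask_single(m)
        assert meas.area_px == 1
        expected = 4 * math.sqrt(1 / 12)  # ~1.1547
        assert meas.major_px == pytest.approx(expected, rel=1e-12)
        assert meas.minor_px == pytest.approx(expected, rel=1e-12)
        assert meas.centroid == (1.0, 1.0)

    def test_digital_disk_matches_analytic_circle(self):
        meas = measure_mask_single(digital_disk(20))
        assert meas.area_px == pytest.approx(math.pi * 400, rel=0.02)
        assert meas.major_px == pytest.approx(40, rel=0.02)
        assert meas.minor_px == pytest.approx(40, rel=0.02)
        assert (meas.major_px - meas.minor_px) / meas.major_px < 0.01

    def test_digital_ellipse_matches_analytic_axes(self):
        meas = measure_mask_single(digital_ellipse(30, 15))
        assert meas.major_px == pytest.approx(60, rel=0.03)
        assert meas.minor_px == pytest.approx(30, rel=0.03)
        assert abs(meas.orientation) < 0.05  # major axis along columns

    def test_rotated_ellipse_orientation_recovered(self):
        angle = math.radians(30)
        meas = measure_mask_single(digital_ellipse(30, 15, angle))
        assert abs(abs(meas.orientation) - angle) < 0.05

    def test_quarter_rotation_swaps_axes_exactly(self):
        m = digital_ellipse(25, 12, math.radians(20))
        a = measure_mask_single(m)
        b = measure_mask_single(np.rot90(m))
        assert b.area_px == a.area_px
        assert b.major_px == pytest.approx(a.major_px, rel=0.005)
        assert b.minor_px == pytest.approx(a.minor_px, rel=0.005)

    def test_agrees_with_regionprops_on_large_blob(self):
        # library cross-check; the +1/12 pixel term is negligible at this size
        skmeasure = pytest.importorskip("skimage.measure")
        m = digital_ellipse(35, 22, 0.7)
        meas = measure_mask_single(m)
        props = skmeasure.regionprops(m.astype(np.uint8))[0]
        assert meas.major_px == pytest.approx(props.axis_major_length, rel=0.005)
        assert meas.minor_px == pytest.approx(props.axis_minor_length, rel=0.005)
        assert meas.centroid == pytest.approx(props.centroid, abs=1e-9)


class TestModelArea:
    @pytest.mark.parametrize(
        "major,minor,expected",
        [(2, 2, math.pi), (60, 30, 450 * math.pi)],
    )
    def test_ellipse_area_formula(self, major, minor, expected):
        assert model_area(major, minor) == pytest.approx(expected, rel=1e-12)

    def test_consistent_with_measured_disk(self):
        meas = measure_mask_single(digital_disk(20))
        assert model_area(meas.major_px, meas.minor_px) == pytest.approx(
            meas.area_px, rel=0.03
        )

    def test_nonpositive_axis_rejected(self):
        with pytest.raises(ValueError):
            model_area(0, 10)
        with pytest.raises(ValueError):
            model_area(10, -1)


class TestEllipseConsistency:
    def test_perfect_digital_ellipse_passes(self):
        assert ellipse_consistency(measure_mask_single(digital_ellipse(30, 15)), tol=0.10)

    def test_touching_pair_union_fails(self):
        # two ellipses (semi-axes 30, 15) with centers 62 px apart along
        # the major axis, treated as one component: a dumbbell whose
        # pixel count falls well short of its fitted-ellipse area
        n = 40
        yy, xx = np.mgrid[-n : n + 1, -n - 31 : n + 32]
        left = ((xx + 31) / 30) ** 2 + (yy / 15) ** 2 <= 1
        right = ((xx - 31) / 30) ** 2 + (yy / 15) ** 2 <= 1
        union = left | right
        coords = np.argwhere(union)
        from seedscan import Component

        meas = measure_component(Component(label=1, coords=coords, touches_border=False))
        assert not ellipse_consistency(meas, tol=0.10)

    def test_infinite_tolerance_is_vacuous(self):
        meas = measure_mask_single(digital_ellipse(30, 6))  # quite elongated
        assert ellipse_consistency(meas, tol=math.inf)


class TestAspectFilter:
    @pytest.mark.parametrize(
        "major,minor,keep",
        [
            (52, 20, False),  # ratio 2.6: more than 2.5x longer -> reject
            (20, 20, True),  # ratio 1
            (50, 20, True),  # exactly 2.5: inclusive bound -> keep
        ],
    )
    def test_ratio_bound_is_inclusive(self, major, minor, keep):
        meas = ComponentMeasure(
            label=1, area_px=100, major_px=major, minor_px=minor,
            centroid=(0, 0), orientation=0.0,
        )
        assert aspect_filter(meas, max_ratio=2.5) is keep


def _scratch_mask():
    m = np.zeros((210, 13), bool)
    m[5:205, 5:8] = True  # 200 x 3 px line
    return m


class TestFilterComponents:
    def test_empty_input_gives_empty_output(self):
        assert filter_components([], FilterConfig(dpi=3200)) == []

    def test_mixed_fixture_keeps_only_the_seed(self):
        # one clean ellipse + one touching-pair union + one scratch
        canvas = np.zeros((300, 300), bool)
        ell = digital_ellipse(30, 15)
        canvas[20 : 20 + ell.shape[0], 20 : 20 + ell.shape[1]] = ell
        # tangent pair: one shared pixel keeps it 8-connected, and the
        # dumbbell still misses its fitted-ellipse area by >10%
        yy, xx = np.mgrid[-20:21, -52:53]
        pair = (((xx + 30) / 30) ** 2 + (yy / 15) ** 2 <= 1) | (
            ((xx - 30) / 30) ** 2 + (yy / 15) ** 2 <= 1
        )
        canvas[120:161, 100:205] |= pair
        sm = _scratch_mask()
        canvas[60:270, 280:293] |= sm
        measures = [measure_component(c) for c in mask_to_components(canvas)]
        records = filter_components(measures, FilterConfig(dpi=3200), image_id="fix")
        assert len(records) == 3
        accepted = [r for r in records if r.accepted]
        assert len(accepted) == 1
        assert accepted[0].passed_ellipse and accepted[0].passed_aspect
        rejected = {r.label: r for r in records if not r.accepted}
        assert any(not r.passed_ellipse for r in rejected.values())  # the pair
        assert any(not r.passed_aspect for r in rejected.values())  # the scratch

    def test_accepted_records_convert_units(self):
        meas = measure_mask_single(digital_ellipse(30, 15))
        (rec,) = filter_components([meas], FilterConfig(dpi=3200, exclude_border=False))
        assert rec.area_mm2 == pytest.approx(rec.area_px * (25.4 / 3200) ** 2)
        assert rec.major_mm == pytest.approx(rec.major_px * 25.4 / 3200)
        assert rec.minor_mm == pytest.approx(rec.minor_px * 25.4 / 3200)
        assert rec.accepted == (
            rec.passed_border and rec.passed_ellipse and rec.passed_aspect and rec.passed_area
        )

    def test_refiltering_accepted_set_is_idempotent(self):
        measures = [measure_mask_single(digital_ellipse(30, 15))]
        cfg = FilterConfig(dpi=3200, exclude_border=False)
        first = filter_components(measures, cfg)
        again = filter_components(measures, cfg)
        assert first == again

    def test_border_exclusion_flag(self):
        m = np.zeros((40, 40), bool)
        m[0:10, 5:20] = True  # touches top edge
        measures = [measure_component(c) for c in mask_to_components(m)]
        (strict,) = filter_components(measures, FilterConfig(dpi=3200, exclude_border=True))
        (lax,) = filter_components(measures, FilterConfig(dpi=3200, exclude_border=False))
        assert not strict.passed_border and lax.passed_border

    def test_loosening_tolerances_never_loses_acceptances(self):
        rng = np.random.default_rng(5)
        measures = []
        for _ in range(30):
            a = rng.uniform(8, 35)
            b = rng.uniform(4, a)
            measures.append(measure_mask_single(digital_ellipse(a, b, rng.uniform(0, 3))))
        cfg = dict(dpi=3200, exclude_border=False)
        tight = filter_components(measures, FilterConfig(ellipse_tol=0.05, max_aspect=2.0, **cfg))
        loose = filter_components(measures, FilterConfig(ellipse_tol=0.15, max_aspect=4.0, **cfg))
        for t, l in zip(tight, loose):
            assert l.accepted or not t.accepted


class TestRecordOutput:
    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        measures = [measure_mask_single(digital_ellipse(30, 15))]
        records = filter_components(measures, FilterConfig(dpi=3200, exclude_border=False), "img1")
        path = tmp_path / "records.csv"
        write_records_csv(records, path)
        back = pd.read_csv(path)
        assert list(back.columns) == list(records_to_frame(records).columns)
        assert back.loc[0, "area_px"] == records[0].area_px
        assert back.loc[0, "area_mm2"] == pytest.approx(records[0].area_mm2)
        assert bool(back.loc[0, "accepted"]) is records[0].accepted
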