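"""Characterization: regional integration, carbon apportionment, C_nm."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omstab.characterize import (
    EEM,
    IncubationSeries,
    SampleRecord,
    ScatterMask,
    Zone,
    ZoneSet,
    apportion_carbon,
    assemble_features,
    cnm_from_series,
    compute_cnm,
    fluorescence_proportions,
    integrate_eem_zones,
    net_co2,
    normalize_zone_volumes,
    FEATURE_NAMES,
    FRACTIONS,
)


def grid_eem(ex, em, intensity, toc=1.0):
    return EEM(np.asarray(ex, float), np.asarray(em, float),
               np.asarray(intensity, float), toc_sample=toc)


class TestRegionalIntegration:
    def test_constant_field_area_identity(self):
        # cell centres 5..45 step 10 tile [0, 50] exactly; unit intensity
        ax = np.arange(5.0, 50.0, 10.0)
        eem = grid_eem(ax, ax, np.ones((5, 5)))
        zones = ZoneSet([Zone("I", 0, 50, 0, 50)])
        assert integrate_eem_zones(eem, zones) == pytest.approx([2500.0])

    def test_zero_intensity_gives_zero_volumes(self):
        ax = np.arange(5.0, 50.0, 10.0)
        eem = grid_eem(ax, ax, np.zeros((5, 5)))
        zones = ZoneSet(
            [Zone(lab, 0, 50, lo, hi) for lab, lo, hi in
             (("I", 0, 10), ("II", 10, 20), ("III", 20, 30), ("IV", 30, 40),
              ("V", 40, 50), ("VI", 0, 25), ("VII", 25, 50))]
        )
        assert np.all(integrate_eem_zones(eem, zones) == 0.0)

    def test_two_zone_split_matches_hand_summation(self):
        # 3x3 grid, intensities 1..9, cell size 10x10; zones split the em
        # axis: left zone covers em centres {5, 15}, right covers {25}
        ex = np.array([5.0, 15.0, 25.0])
        em = np.array([5.0, 15.0, 25.0])
        inten = np.arange(1.0, 10.0).reshape(3, 3)
        zones = ZoneSet([Zone("L", 0, 30, 0, 20), Zone("R", 0, 30, 20, 30)])
        # independent oracle: explicit loop over every cell
        expected = np.zeros(2)
        for i, e in enumerate(ex):
            for j, m in enumerate(em):
                expected[0 if m <= 20 else 1] += inten[i, j] * 100.0
        got = integrate_eem_zones(grid_eem(ex, em, inten), zones)
        assert got == pytest.approx(expected)

    def test_zone_outside_coverage_names_zone(self):
        ax = np.arange(5.0, 50.0, 10.0)
        eem = grid_eem(ax, ax, np.ones((5, 5)))
        with pytest.raises(ValueError, match="FAR"):
            integrate_eem_zones(eem, ZoneSet([Zone("FAR", 100, 150, 0, 50)]))

    def test_empty_zone_rejected(self):
        ax = np.array([5.0, 25.0, 45.0])
        eem = grid_eem(ax, ax, np.ones((3, 3)))
        with pytest.raises(ValueError, match="no grid cells"):
            integrate_eem_zones(eem, ZoneSet([Zone("E", 10, 20, 10, 20)]))

    def test_scatter_mask_zeroes_diagonal(self):
        ax = np.arange(5.0, 50.0, 10.0)
        eem = grid_eem(ax, ax, np.ones((5, 5)))
        zones = ZoneSet([Zone("I", 0, 50, 0, 50)])
        masked = integrate_eem_zones(eem, zones, ScatterMask(first_order_width=1.0))
        # the 5 diagonal (em == ex) cells drop out
        assert masked == pytest.approx([2500.0 - 5 * 100.0])

    def test_eem_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            grid_eem([5, 5, 15], [5, 15, 25], np.ones((3, 3)))
        with pytest.raises(ValueError, match="does not match"):
            grid_eem([5, 15], [5, 15, 25], np.ones((3, 2)))


class TestNormalization:
    def test_single_zone(self):
        zones = ZoneSet([Zone("I", 0, 50, 0, 50)])
        assert normalize_zone_volumes(np.array([10.0]), 2.0, zones) == pytest.approx([5.0])

    def test_equal_area_zones_apply_stated_formula(self):
        zones = ZoneSet([Zone("A", 0, 10, 0, 10), Zone("B", 10, 20, 0, 10)])
        # hand application: raw/TOC divided by relative area 1/2
        got = normalize_zone_volumes(np.array([4.0, 6.0]), 2.0, zones)
        assert got == pytest.approx([4.0, 6.0])

    def test_nonpositive_toc_rejected(self):
        zones = ZoneSet([Zone("I", 0, 50, 0, 50)])
        for bad in (0.0, -1.0, None):
            with pytest.raises(ValueError):
                normalize_zone_volumes(np.array([1.0]), bad, zones)

    @given(
        vf=st.lists(st.floats(0, 1e6), min_size=7, max_size=7).filter(
            lambda v: sum(v) > 1e-6
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_proportions_close_to_100(self, vf):
        assert fluorescence_proportions(np.array(vf)).sum() == pytest.approx(100.0)

    def test_proportions_examples(self):
        pf = fluorescence_proportions(np.array([4.0, 6.0, 0, 0, 0, 0, 0]))
        assert pf == pytest.approx([40, 60, 0, 0, 0, 0, 0])
        assert fluorescence_proportions(np.ones(7)) == pytest.approx(np.full(7, 100 / 7))
        with pytest.raises(ValueError, match="zero"):
            fluorescence_proportions(np.zeros(7))

    def test_intensity_scaling_homogeneity(self, rng):
        """Scaling all intensities by k scales Vf by k, leaves Pf unchanged."""
        ax = np.arange(5.0, 50.0, 10.0)
        inten = rng.uniform(0.1, 5.0, size=(5, 5))
        zones = ZoneSet([Zone("L", 0, 50, 0, 30), Zone("R", 0, 50, 30, 50)])
        k = 7.3
        vf1 = normalize_zone_volumes(
            integrate_eem_zones(grid_eem(ax, ax, inten), zones), 3.0, zones
        )
        vf2 = normalize_zone_volumes(
            integrate_eem_zones(grid_eem(ax, ax, k * inten), zones), 3.0, zones
        )
        assert vf2 == pytest.approx(k * vf1)
        assert fluorescence_proportions(vf2) == pytest.approx(
            fluorescence_proportions(vf1)
        )

    def test_equal_area_zones_area_weight_is_neutral(self, rng):
        """With equal-area zones, Pf with and without the weight coincide."""
        raw = rng.uniform(0, 10, size=3)
        zones = ZoneSet([Zone(l, 10 * i, 10 * (i + 1), 0, 10) for i, l in
                         enumerate("ABC")])
        vf = normalize_zone_volumes(raw, 2.0, zones)
        assert fluorescence_proportions(vf) == pytest.approx(
            fluorescence_proportions(raw)
        )


class TestCarbonApportionment:
    def test_worked_example(self):
        ac, closure = apportion_carbon(
            200.0, dict(zip(FRACTIONS, [20.0, 30.0, 10.0, 40.0])), 80.0
        )
        assert ac == pytest.approx([10, 15, 5, 20, 40])
        assert closure == pytest.approx(90.0)

    def test_all_carbon_in_residue(self):
        ac, closure = apportion_carbon(
            150.0, dict(zip(FRACTIONS, [0.0, 0.0, 0.0, 0.0])), 150.0
        )
        assert ac == pytest.approx([0, 0, 0, 0, 100])
        assert closure == pytest.approx(100.0)

    @given(
        carbon=st.lists(st.floats(0, 100), min_size=5, max_size=5),
        om_tc=st.floats(50, 500),
    )
    @settings(max_examples=100, deadline=None)
    def test_closure_identity(self, carbon, om_tc):
        """Sum of the AC values equals recovered carbon over OM_TC x 100."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ac, closure = apportion_carbon(
                om_tc, dict(zip(FRACTIONS, carbon[:4])), carbon[4]
            )
        assert closure == pytest.approx(sum(carbon) / om_tc * 100.0)
        assert closure == pytest.approx(float(np.sum(ac)))

    def test_residue_by_difference_closes_exactly(self):
        ac, closure = apportion_carbon(
            200.0,
            dict(zip(FRACTIONS, [20.0, 30.0, 10.0, 40.0])),
            0.0,
            residue_by_difference=True,
        )
        assert closure == pytest.approx(100.0)
        assert ac[4] == pytest.approx(50.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            apportion_carbon(0.0, dict(zip(FRACTIONS, [1, 1, 1, 1])), 1.0)
        with pytest.raises(ValueError):
            apportion_carbon(100.0, dict(zip(FRACTIONS, [-1, 1, 1, 1])), 1.0)


class TestIncubation:
    def mk(self, amended, control, tc=300.0):
        days = np.arange(1, len(amended) + 1, dtype=float)
        return IncubationSeries(days, np.array(amended, float),
                                np.array(control, float), tc)

    def test_equal_arms_give_zero(self):
        assert np.all(net_co2(self.mk([1, 2, 3], [1, 2, 3])) == 0.0)

    def test_constant_offset_preserved(self):
        assert net_co2(self.mk([2, 3, 4], [1, 2, 3])) == pytest.approx([1, 1, 1])

    def test_negative_net_kept_with_warning(self):
        with pytest.warns(UserWarning, match="negative"):
            net = net_co2(self.mk([1, 2, 3], [2, 2, 3]))
        assert net[0] == -1.0

    def test_day_grid_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            IncubationSeries(np.array([1.0, 1.0]), np.zeros(2), np.zeros(2), 1.0)
        with pytest.raises(ValueError, match="length"):
            IncubationSeries(np.array([1.0, 2.0]), np.zeros(3), np.zeros(2), 1.0)
        with pytest.raises(ValueError, match="non-decreasing"):
            self.mk([3, 2, 1], [0, 0, 0])

    def test_cnm_examples(self):
        assert compute_cnm(60.0, 300.0) == pytest.approx(80.0)
        assert compute_cnm(0.0, 300.0) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            compute_cnm(10.0, 0.0)

    @given(
        net=st.floats(0, 300),
        tc=st.floats(1, 300),
    )
    @settings(max_examples=100, deadline=None)
    def test_cnm_bounds_and_monotonicity(self, net, tc):
        """C_nm in [0, 100] for net in [0, tc], decreasing in net."""
        if net > tc:
            net = tc
        c = compute_cnm(net, tc)
        assert 0.0 <= c <= 100.0 + 1e-9
        assert compute_cnm(min(net + 1, tc), tc) <= c + 1e-9

    def test_cnm_from_series_uses_last_day(self):
        s = self.mk([10, 30, 60], [0, 0, 0], tc=300.0)
        assert cnm_from_series(s) == pytest.approx(80.0)


class TestSampleRecord:
    def test_feature_count_enforced(self):
        with pytest.raises(ValueError, match="34"):
            SampleRecord("x", np.zeros(10))

    def test_validation_flags_bad_closures(self, default_params):
        from omstab.synthetic import generate_wastes

        rec = generate_wastes(default_params, seed=0)[0]
        assert rec.validate() == []
        bad = rec.features.copy()
        bad[1] += 60.0  # break AC closure
        issues = SampleRecord("bad", bad).validate()
        assert any("AC closure" in m for m in issues)

    def test_assemble_features_order(self, default_params):
        from omstab.characterize import FractionProfile, FluorescenceProfile

        prof = FractionProfile(
            om_tc=200.0,
            toc_by_fraction=dict(zip(FRACTIONS, [20.0, 30.0, 10.0, 40.0])),
            tc_residue=80.0,
        )
        pf = np.array([40, 60, 0, 0, 0, 0, 0], float)
        fluo = {
            f: FluorescenceProfile(f, vf=pf.copy(), pf=pf.copy()) for f in FRACTIONS
        }
        feats = assemble_features(prof, fluo)
        assert feats[0] == 200.0
        assert feats[1:6] == pytest.approx([10, 15, 5, 20, 40])
        assert len(feats) == len(FEATURE_NAMES) == 34
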