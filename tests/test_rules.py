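import numpy as np
import pytest

from ezar import (
    EnFaceMap,
    RuleThresholds,
    ScanGeometry,
    ValidationError,
    attenuation_columns,
    derive_at_risk_columns,
    detect_ga_columns,
    render_training_mask,
)
from ezar.core import MapKind

from conftest import make_surfaces

THR = RuleThresholds()


def tmap(values):
    return EnFaceMap(np.atleast_2d(np.asarray(values, dtype=float)))


def fmap(values):
    return EnFaceMap(np.atleast_2d(values), MapKind.FLAG)


def reference_rules(t_ez, t_rpe, thr):
    """Naive per-column reference for all three column rules."""
    n_b, n_a = t_ez.shape
    ga = np.zeros((n_b, n_a), dtype=bool)
    at_risk = np.zeros_like(ga)
    partial = np.zeros_like(ga)
    total_ez = np.zeros_like(ga)
    total_rpe = np.zeros_like(ga)
    for i in range(n_b):
        for j in range(n_a):
            ga[i, j] = t_ez[i, j] <= thr.total_tol and t_rpe[i, j] <= thr.total_tol
    for i in range(n_b):
        for j in range(n_a):
            at_risk[i, j] = t_ez[i, j] <= thr.at_risk_max and not ga[i, j]
            partial[i, j] = t_ez[i, j] < thr.partial_max
            total_ez[i, j] = t_ez[i, j] <= thr.total_tol
            total_rpe[i, j] = t_rpe[i, j] <= thr.total_tol
    return ga, at_risk, partial, total_ez, total_rpe


def random_thickness_pair(rng, n_b=8, n_a=24):
    """Random maps with a deliberate mass of exact zeros and near-threshold
    values so every branch of the rules is exercised."""
    t_ez = rng.uniform(0, 40, (n_b, n_a))
    t_rpe = rng.uniform(0, 35, (n_b, n_a))
    zero_ez = rng.random((n_b, n_a)) < 0.25
    zero_both = rng.random((n_b, n_a)) < 0.1
    t_ez[zero_ez] = 0.0
    t_ez[zero_both] = 0.0
    t_rpe[zero_both] = 0.0
    edges = rng.random((n_b, n_a)) < 0.05
    t_ez[edges] = rng.choice([10.0, 20.0, 10.0 + 1e-9], size=int(edges.sum()))
    return t_ez, t_rpe


class TestDetectGA:
    def test_requires_both_pairs_collapsed(self):
        ga = detect_ga_columns(tmap([0.0, 0.0]), tmap([0.0, 15.0]), THR)
        np.testing.assert_array_equal(ga.values, [[True, False]])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            detect_ga_columns(tmap([0.0]), tmap([0.0, 0.0]), THR)

    def test_min_extent_clears_short_runs(self):
        thr = RuleThresholds(ga_min_extent=100.0)
        t_ez = np.zeros((1, 8))
        t_rpe = np.array([[0, 0, 0, 9, 0, 9, 0, 0]], dtype=float)
        # lateral_scale 40 um -> min run 3 columns; runs are len 3, 1, 2
        ga = detect_ga_columns(tmap(t_ez), tmap(t_rpe), thr, lateral_scale=40.0)
        np.testing.assert_array_equal(
            ga.values, [[True, True, True, False, False, False, False, False]]
        )

    def test_min_extent_needs_lateral_scale(self):
        thr = RuleThresholds(ga_min_extent=100.0)
        with pytest.raises(ValidationError, match="lateral_scale"):
            detect_ga_columns(tmap([0.0]), tmap([0.0]), thr)


class TestAtRisk:
    def test_threshold_is_inclusive_and_ga_excluded(self):
        t = tmap([0.0, 5.0, 10.0, 10.1, 15.0])
        ga = fmap([True, False, False, False, False])
        flags = derive_at_risk_columns(t, ga, THR)
        np.testing.assert_array_equal(
            flags.values, [[False, True, True, False, False]]
        )

    def test_all_ga_gives_empty_map(self):
        t = tmap([0.0, 3.0])
        ga = fmap([True, True])
        assert not derive_at_risk_columns(t, ga, THR).values.any()


class TestAttenuation:
    def test_partial_threshold_is_strict(self):
        flags = attenuation_columns(tmap([19.9, 20.0]), "partial_ez", THR)
        np.testing.assert_array_equal(flags.values, [[True, False]])

    def test_total_is_subset_of_partial(self):
        t = tmap([0.0])
        assert attenuation_columns(t, "partial_ez", THR).values[0, 0]
        assert attenuation_columns(t, "total_ez_rpe", THR).values[0, 0]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            attenuation_columns(tmap([1.0]), "bogus", THR)


class TestRuleOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_all_rules_match_reference(self, seed):
        rng = np.random.default_rng(seed)
        t_ez, t_rpe = random_thickness_pair(rng)
        ga_ref, ar_ref, part_ref, tez_ref, trpe_ref = reference_rules(
            t_ez, t_rpe, THR
        )
        ga = detect_ga_columns(tmap(t_ez), tmap(t_rpe), THR)
        np.testing.assert_array_equal(ga.values, ga_ref)
        np.testing.assert_array_equal(
            derive_at_risk_columns(tmap(t_ez), ga, THR).values, ar_ref
        )
        np.testing.assert_array_equal(
            attenuation_columns(tmap(t_ez), "partial_ez", THR).values, part_ref
        )
        np.testing.assert_array_equal(
            attenuation_columns(tmap(t_ez), "total_ez_rpe", THR).values, tez_ref
        )
        np.testing.assert_array_equal(
            attenuation_columns(tmap(t_rpe), "total_rpe_bm", THR).values,
            trpe_ref,
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_exclusion_and_nesting_invariants(self, seed):
        rng = np.random.default_rng(1000 + seed)
        t_ez, t_rpe = random_thickness_pair(rng)
        ga = detect_ga_columns(tmap(t_ez), tmap(t_rpe), THR)
        at_risk = derive_at_risk_columns(tmap(t_ez), ga, THR)
        partial = attenuation_columns(tmap(t_ez), "partial_ez", THR)
        total = attenuation_columns(tmap(t_ez), "total_ez_rpe", THR)
        assert not (at_risk.values & ga.values).any()
        assert (total.values <= partial.values).all()
        assert (total.values <= (at_risk.values | ga.values)).all()
        assert (at_risk.values <= partial.values).all()


class TestTrainingMask:
    def _setup(self, n_depth=200, ez_row=100.0):
        geom = ScanGeometry(n_bscans=1, n_ascans=3, n_depth=n_depth,
                            axial_scale=4.0)
        s = make_surfaces(1, 3, 20.0, 20.0, bm_row=ez_row + 10)
        s.ez[:] = ez_row
        flags = fmap([False, True, False])
        return geom, s, flags

    def test_band_is_10px_centered_on_ez(self):
        geom, s, flags = self._setup()
        mask = render_training_mask(flags, s, 0, THR, geometry=geom)
        col = mask.pixels[:, 1]
        assert col.sum() == 10
        assert col[95:105].all()
        assert not mask.pixels[:, 0].any() and not mask.pixels[:, 2].any()

    def test_band_clips_at_top_border(self):
        geom, s, flags = self._setup(ez_row=3.0)
        s.onl[:] = 0.0
        mask = render_training_mask(flags, s, 0, THR, geometry=geom)
        col = mask.pixels[:, 1]
        assert col.sum() == 8
        assert col[0:8].all()

    def test_no_flags_gives_empty_mask(self):
        geom, s, flags = self._setup()
        empty = fmap([False, False, False])
        mask = render_training_mask(empty, s, 0, THR, geometry=geom)
        assert not mask.pixels.any()

    def test_absent_ez_centers_on_rpe(self):
        geom = ScanGeometry(n_bscans=1, n_ascans=2, n_depth=200, axial_scale=4.0)
        absent = np.array([[True, False]])
        s = make_surfaces(1, 2, 0.0, 20.0, bm_row=120.0, ez_absent=absent)
        flags = fmap([True, False])
        mask = render_training_mask(flags, s, 0, THR, geometry=geom)
        c = int(np.floor(s.rpe[0, 0] + 0.5))
        assert mask.pixels[c - 5 : c + 5, 0].all()
        assert mask.pixels[:, 0].sum() == 10

    def test_out_of_range_bscan_rejected(self):
        geom, s, flags = self._setup()
        with pytest.raises(ValidationError, match="out of range"):
            render_training_mask(flags, s, 5, THR, geometry=geom)

    @pytest.mark.parametrize("seed", range(5))
    def test_column_sums_equal_band_or_clip(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_depth = 30, 60
        geom = ScanGeometry(n_bscans=1, n_ascans=n_a, n_depth=n_depth,
                            axial_scale=4.0)
        ez_rows = rng.uniform(0, n_depth - 1, (1, n_a))
        s = make_surfaces(1, n_a, 0.0, 0.0, bm_row=0.0)
        s.ez[:] = ez_rows
        s.rpe[:] = ez_rows
        s.bm[:] = np.maximum(ez_rows, s.rpe)
        s.onl[:] = 0.0
        flags = EnFaceMap(rng.random((1, n_a)) < 0.5, MapKind.FLAG)
        mask = render_training_mask(flags, s, 0, THR, geometry=geom)
        for j in range(n_a):
            col_sum = mask.pixels[:, j].sum()
            if not flags.values[0, j]:
                assert col_sum == 0
                continue
            c = int(np.floor(ez_rows[0, j] + 0.5))
            expected = min(c + 5, n_depth) - max(c - 5, 0)
            assert col_sum == expected
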