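"""DEAB threshold, bright/low split, standardized MFI, fold difference."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aldhgate as ag
from aldhgate.gating import ReferencePopulationError

from conftest import make_events


class TestDeabThreshold:
    def test_constant_distribution_gives_that_constant(self, cfg):
        ev = make_events(treatment="DEAB", ALDH=np.full(100, 7.5))
        thr = ag.deab_threshold(ev, np.arange(100), cfg)
        assert thr.value == 7.5
        assert thr.n_reference_events == 100

    def test_matches_sorted_order_statistic(self, cfg):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(2, 0.4, 1000)
        ev = make_events(treatment="DEAB", ALDH=vals)
        thr = ag.deab_threshold(ev, np.arange(1000), cfg)
        assert thr.value == np.sort(vals)[int(np.ceil(0.99 * 1000)) - 1]

    def test_raising_quantile_never_lowers_threshold(self, cfg):
        rng = np.random.default_rng(3)
        ev = make_events(treatment="DEAB", ALDH=rng.lognormal(2, 0.5, 500))
        thrs = [
            ag.deab_threshold(ev, np.arange(500), cfg.replace(deab_quantile=q)).value
            for q in (0.5, 0.8, 0.9, 0.95, 0.99, 0.999)
        ]
        assert all(a <= b for a, b in zip(thrs, thrs[1:]))

    def test_empty_scope_raises(self, cfg):
        ev = make_events(treatment="DEAB", ALDH=np.ones(5))
        with pytest.raises(ReferencePopulationError):
            ag.deab_threshold(ev, np.array([], dtype=int), cfg)

    def test_native_aliquot_rejected(self, cfg):
        ev = make_events(treatment="native", ALDH=np.ones(5))
        with pytest.raises(ValueError, match="DEAB"):
            ag.deab_threshold(ev, np.arange(5), cfg)


class TestSplit:
    def test_bright_low_partition(self, normal_bm):
        stem = normal_bm.labels.indices("blast_CD34pos_CD38neg")
        bright = ag.split_aldh_compartments(
            normal_bm.pair.native, stem, normal_bm.result.threshold
        )
        assert bright.size == stem.size
        assert bright.dtype == bool  # every event is exactly bright or low

    def test_all_below_threshold_all_low(self):
        ev = make_events(ALDH=np.full(20, 3.0))
        thr = ag.AldhThreshold(value=5.0, quantile_used=0.99, n_reference_events=100)
        assert not ag.split_aldh_compartments(ev, np.arange(20), thr).any()

    def test_tie_at_threshold_is_low(self):
        ev = make_events(ALDH=np.array([5.0, 5.1]))
        thr = ag.AldhThreshold(value=5.0, quantile_used=0.99, n_reference_events=10)
        np.testing.assert_array_equal(
            ag.split_aldh_compartments(ev, np.arange(2), thr), [False, True]
        )

    def test_truth_agreement_on_cd34pos_preset(self, aml_cd34pos):
        """HSC->bright, LSC->low agreement >= 95% in the stem gate."""
        stem = aml_cd34pos.labels.indices("blast_CD34pos_CD38neg")
        bright = ag.split_aldh_compartments(
            aml_cd34pos.pair.native, stem, aml_cd34pos.result.threshold
        )
        tl = aml_cd34pos.truth["truth_label"].to_numpy()[stem]
        mask = np.isin(tl, ("HSC", "LSC_cd34pos"))
        expected = tl[mask] == "HSC"
        assert (bright[mask] == expected).mean() >= 0.95


class TestStandardizedMfi:
    def test_subset_equals_lymphocytes_gives_one(self):
        ev = make_events(ALDH=[10, 20, 30])
        m = ag.standardized_mfi(ev, np.arange(3), np.arange(3))
        assert m.ratio == pytest.approx(1.0)

    def test_hand_arithmetic_example(self):
        ev = make_events(ALDH=[20.0, 40.0, 10.0, 10.0])
        m = ag.standardized_mfi(ev, np.array([0, 1]), np.array([2, 3]))
        assert m.raw_mfi == pytest.approx(30.0)
        assert m.lymph_mfi == pytest.approx(10.0)
        assert m.ratio == pytest.approx(3.0)

    @given(st.floats(0.01, 1000.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance_of_ratio(self, k):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(2, 0.5, 60)
        subset, lymph = np.arange(30), np.arange(30, 60)
        r1 = ag.standardized_mfi(make_events(ALDH=vals), subset, lymph).ratio
        r2 = ag.standardized_mfi(make_events(ALDH=k * vals), subset, lymph).ratio
        assert r2 == pytest.approx(r1)

    def test_geometric_statistic_option(self):
        ev = make_events(ALDH=[1.0, 100.0, 10.0, 10.0])
        m = ag.standardized_mfi(ev, np.array([0, 1]), np.array([2, 3]), "geometric")
        assert m.raw_mfi == pytest.approx(10.0)
        assert m.ratio == pytest.approx(1.0)

    def test_empty_subset_raises(self):
        ev = make_events(ALDH=np.ones(5))
        with pytest.raises(ReferencePopulationError):
            ag.standardized_mfi(ev, np.array([], dtype=int), np.arange(5))


class TestFoldDifference:
    def test_equal_ratios_give_one(self):
        m = ag.StandardizedMfi(raw_mfi=5.0, lymph_mfi=1.0, ratio=5.0)
        assert ag.fold_difference(m, m) == pytest.approx(1.0)

    def test_arithmetic(self):
        hsc = ag.StandardizedMfi(raw_mfi=6.9, lymph_mfi=1.0, ratio=6.9)
        lsc = ag.StandardizedMfi(raw_mfi=1.0, lymph_mfi=1.0, ratio=1.0)
        assert ag.fold_difference(hsc, lsc) == pytest.approx(6.9)

    def test_lymphocyte_standardization_cancels(self):
        """fold equals the raw MFI ratio on random data: the shared
        lymphocyte denominator drops out algebraically."""
        rng = np.random.default_rng(5)
        vals = rng.lognormal(2, 0.6, 90)
        ev = make_events(ALDH=vals)
        a, b, lymph = np.arange(30), np.arange(30, 60), np.arange(60, 90)
        ma = ag.standardized_mfi(ev, a, lymph)
        mb = ag.standardized_mfi(ev, b, lymph)
        assert ag.fold_difference(ma, mb) == pytest.approx(ma.raw_mfi / mb.raw_mfi)

    def test_zero_denominator_rejected(self):
        good = ag.StandardizedMfi(raw_mfi=5.0, lymph_mfi=1.0, ratio=5.0)
        bad = ag.StandardizedMfi(raw_mfi=0.0, lymph_mfi=1.0, ratio=0.0)
        with pytest.raises(ValueError):
            ag.fold_difference(good, bad)


class TestPositiveFraction:
    def test_all_below_threshold_gives_zero(self, cfg):
        ev = make_events(ALDH=np.ones(50))
        thr = ag.AldhThreshold(value=10.0, quantile_used=0.99, n_reference_events=100)
        assert ag.aldh_positive_fraction(ev, np.arange(50), thr, cfg).fraction == 0.0

    def test_850_of_10000_above_gives_8_5(self, cfg):
        vals = np.ones(10_000)
        vals[:850] = 100.0
        ev = make_events(ALDH=vals)
        thr = ag.AldhThreshold(value=10.0, quantile_used=0.99, n_reference_events=100)
        rep = ag.aldh_positive_fraction(ev, np.arange(10_000), thr, cfg)
        assert rep.fraction == pytest.approx(8.5)
        assert rep.numerator == 850

    def test_normal_bm_positive_fraction_matches_binomial_oracle(self, normal_bm, cfg):
        """ALDH+ share of the sample = bright-population mass plus the
        (1 - deab_quantile) background share the threshold leaves above
        itself, within 3 SE (binomial counting noise plus the quantile-
        estimation noise of the threshold itself)."""
        spec = normal_bm.scenario
        thr = normal_bm.result.threshold
        q = cfg.deab_quantile
        f_bright = sum(p.frequency for p in spec.populations if p.aldh_state == "bright")
        p_exp = f_bright + (1 - f_bright) * (1 - q)
        n = spec.n_events
        rep = ag.aldh_positive_fraction(
            normal_bm.pair.native, np.arange(n), thr, cfg
        )
        se_count = np.sqrt(p_exp * (1 - p_exp) / n)
        se_thr = (1 - f_bright) * np.sqrt(q * (1 - q) / thr.n_reference_events)
        assert abs(rep.fraction / 100.0 - p_exp) <= 3 * (se_count + se_thr)
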