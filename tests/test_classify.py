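"""Sample-level and per-event classification rules."""

from __future__ import annotations

import numpy as np
import pytest

import aldhgate as ag
from aldhgate.classify import CD34_NEGATIVE, CD34_POSITIVE, ClassificationError

from conftest import make_events


def labels_with_blast_counts(n_stem=0, n_prog=0, n_cd34neg=0, n_lymph=5) -> ag.GateLabels:
    comp = (
        ["lymphocyte"] * n_lymph
        + ["blast_CD34pos_CD38neg"] * n_stem
        + ["blast_CD34pos_CD38pos"] * n_prog
        + ["blast_CD34neg"] * n_cd34neg
    )
    comp = np.array(comp, dtype=str)
    lymph = np.arange(n_lymph)
    blasts = np.arange(n_lymph, comp.size)
    return ag.GateLabels(compartment=comp, lymphocytes=lymph, blasts=blasts)


class TestCd34Status:
    def test_published_negative_instance(self, cfg):
        # 0.03% CD34+ of blasts, as in the published CD34-negative example
        lab = labels_with_blast_counts(n_stem=3, n_cd34neg=9997)
        assert ag.classify_cd34_status(lab, cfg) == CD34_NEGATIVE

    def test_published_positive_instance(self, cfg):
        # 72% CD34+ of blasts
        lab = labels_with_blast_counts(n_stem=20, n_prog=52, n_cd34neg=28)
        assert ag.classify_cd34_status(lab, cfg) == CD34_POSITIVE

    def test_exactly_1pct_is_positive(self, cfg):
        lab = labels_with_blast_counts(n_stem=1, n_cd34neg=99)
        assert ag.classify_cd34_status(lab, cfg) == CD34_POSITIVE

    def test_just_under_1pct_is_negative(self, cfg):
        lab = labels_with_blast_counts(n_stem=1, n_cd34neg=100)
        assert ag.classify_cd34_status(lab, cfg) == CD34_NEGATIVE

    def test_empty_blast_gate_raises(self, cfg):
        lab = labels_with_blast_counts()
        with pytest.raises(ClassificationError):
            ag.classify_cd34_status(lab, cfg)

    def test_agrees_with_rule_on_fraction_grid(self, cfg):
        """Brute-force check over blast CD34+ percentages around the cutoff."""
        for n_pos in range(0, 40):
            lab = labels_with_blast_counts(n_stem=n_pos, n_cd34neg=1000 - n_pos)
            pct = 100.0 * n_pos / 1000
            oracle = CD34_NEGATIVE if pct < 1.0 else CD34_POSITIVE
            assert ag.classify_cd34_status(lab, cfg) == oracle

    def test_presets_classified_correctly(self, aml_cd34pos, aml_cd34neg):
        assert aml_cd34pos.result.summary.cd34_status == CD34_POSITIVE
        assert aml_cd34neg.result.summary.cd34_status == CD34_NEGATIVE


class TestStemCalls:
    def _call(self, compartment, bright, marker, status):
        comp = np.array(["lymphocyte", compartment], dtype=str)
        lab = ag.GateLabels(
            compartment=comp, lymphocytes=np.array([0]), blasts=np.array([1])
        )
        calls = ag.call_stem_cells(
            lab,
            bright=np.array([False, bright]),
            marker_positive=np.array([False, marker]),
            status=status,
        )
        return calls.call[1]

    @pytest.mark.parametrize(
        "bright,marker,expected",
        [
            (True, False, "HSC"),        # bright, marker-negative
            (False, True, "LSC"),        # ALDH-low, marker-positive
            (False, False, "LSC"),       # ALDH-low even without marker
            (True, True, "ambiguous"),   # conflicting evidence surfaces
        ],
    )
    def test_cd34pos_cd38neg_rules(self, bright, marker, expected):
        got = self._call("blast_CD34pos_CD38neg", bright, marker, CD34_POSITIVE)
        assert got == expected

    def test_cd34neg_blasts_called_only_in_cd34_negative_samples(self):
        assert self._call("blast_CD34neg", False, True, CD34_NEGATIVE) == "LSC"
        assert self._call("blast_CD34neg", True, False, CD34_NEGATIVE) == "ambiguous"
        assert self._call("blast_CD34neg", False, True, CD34_POSITIVE) == "not_stem"

    def test_non_candidates_not_stem(self):
        assert self._call("blast_CD34pos_CD38pos", True, False, CD34_POSITIVE) == "not_stem"

    def test_call_invariants_on_presets(self, all_presets):
        """HSC implies bright & marker-negative; LSC implies not bright;
        HSC/LSC sets disjoint; calls only on stem candidates."""
        for ap in all_presets.values():
            calls = ap.result.calls
            bright = calls.evidence["aldh_bright"]
            marker = calls.evidence["marker_positive"]
            hsc = calls.call == "HSC"
            lsc = calls.call == "LSC"
            assert not (hsc & lsc).any()
            assert bright[hsc].all() and not marker[hsc].any()
            assert not bright[lsc].any()
            candidate = np.isin(
                ap.labels.compartment, ("blast_CD34pos_CD38neg", "blast_CD34neg")
            )
            assert (calls.call[~candidate] == "not_stem").all()

    def test_cd34neg_sample_stem_gate_essentially_no_lsc(self, aml_cd34neg):
        """In the simulated CD34-negative AML the CD34+CD38- compartment is
        all normal HSC; LSC calls there are limited to the below-threshold
        tail that a 0.99-quantile background threshold necessarily leaves
        (~1% of bright events)."""
        stem = aml_cd34neg.labels.compartment == "blast_CD34pos_CD38neg"
        lsc = aml_cd34neg.result.calls.call == "LSC"
        hsc_truth = aml_cd34neg.truth["truth_label"].to_numpy() == "HSC"
        n_hsc_in_stem = (stem & hsc_truth).sum()
        assert (stem & lsc & hsc_truth).sum() <= 0.03 * n_hsc_in_stem

    def test_missing_split_rejected(self):
        lab = labels_with_blast_counts(n_stem=2)
        with pytest.raises(ClassificationError, match="ALDH split"):
            ag.call_stem_cells(
                lab, np.array([True]), np.zeros(lab.compartment.size, bool), CD34_POSITIVE
            )


class TestCheung:
    @pytest.mark.parametrize(
        "pct,expected",
        [(8.2, "positive"), (9.5, "positive"), (12.6, "positive"),
         (4.9, "negative"), (5.0, "negative"), (0.0, "negative")],
    )
    def test_instances(self, pct, expected, cfg):
        assert ag.cheung_classification(pct, cfg) == expected

    def test_raising_cutoff_never_converts_negative_to_positive(self, cfg):
        for pct in np.linspace(0, 20, 41):
            calls = [
                ag.cheung_classification(pct, cfg.replace(aldh_pos_sample_cutoff=c))
                for c in (2.0, 5.0, 8.0, 12.0)
            ]
            # once negative at some cutoff, stays negative at higher cutoffs
            seen_negative = False
            for c in calls:
                if c == "negative":
                    seen_negative = True
                assert not (seen_negative and c == "positive")


class TestPearce:
    def _sample(self, n=10_000, pos_pct=2.0, confined_frac=1.0, lymph_ssc=80.0):
        """Constructed sample: pos_pct% of events above the ALDH threshold,
        of which confined_frac have SSC below 1.7x the lymphocyte median."""
        n_pos = int(round(n * pos_pct / 100))
        n_conf = int(round(n_pos * confined_frac))
        aldh = np.full(n, 1.0)
        aldh[:n_pos] = 100.0
        ssc = np.full(n, lymph_ssc)
        ssc[:n_pos] = 1000.0
        ssc[:n_conf] = lymph_ssc  # confined positives
        ev = make_events(ALDH=aldh, SSC=ssc)
        thr = ag.AldhThreshold(value=10.0, quantile_used=0.99, n_reference_events=100)
        lymph = np.arange(n_pos, n)
        return ev, thr, lymph

    def test_no_positive_events_is_negative(self, cfg):
        ev, thr, lymph = self._sample(pos_pct=0.0)
        assert ag.pearce_pattern(ev, thr, lymph, cfg) == "negative"

    def test_2pct_confined_is_rare(self, cfg):
        ev, thr, lymph = self._sample(pos_pct=2.0, confined_frac=1.0)
        assert ag.pearce_pattern(ev, thr, lymph, cfg) == "rare"

    def test_2pct_unconfined_is_numerous(self, cfg):
        ev, thr, lymph = self._sample(pos_pct=2.0, confined_frac=0.5)
        assert ag.pearce_pattern(ev, thr, lymph, cfg) == "numerous"

    def test_cheung_positive_samples_are_numerous(self, cfg):
        """>5% ALDH+ forces 'numerous' regardless of confinement, so every
        sample-level ALDH-positive case has the numerous pattern."""
        for pct in (5.5, 8.2, 12.6):
            for conf in (0.0, 0.5, 1.0):
                ev, thr, lymph = self._sample(pos_pct=pct, confined_frac=conf)
                assert ag.cheung_classification(pct, cfg) == "positive"
                assert ag.pearce_pattern(ev, thr, lymph, cfg) == "numerous"

    def test_agrees_with_truth_table_grid(self, cfg):
        """Brute-force rule evaluation over (positivity, confinement)."""
        for pct in (0.0, 0.05, 0.2, 1.0, 3.0, 4.9, 6.0, 20.0):
            for conf in (0.0, 0.5, 0.79, 0.8, 1.0):
                ev, thr, lymph = self._sample(pos_pct=pct, confined_frac=conf)
                realized_pct = 100.0 * (ev.column("ALDH") > thr.value).mean()
                if realized_pct < cfg.pearce_negative_max_pct:
                    oracle = "negative"
                elif realized_pct < cfg.pearce_rare_max_pct:
                    pos = ev.column("ALDH") > thr.value
                    bound = cfg.ssc_ratio_max * np.median(ev.column("SSC")[lymph])
                    frac = (ev.column("SSC")[pos] <= bound).mean()
                    oracle = "rare" if frac >= cfg.pearce_ssc_confinement else "numerous"
                else:
                    oracle = "numerous"
                assert ag.pearce_pattern(ev, thr, lymph, cfg) == oracle, (pct, conf)
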