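"""Poisson quantification, QC, thresholding and calling."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ddrain
from ddrain.quantify import ClassCounts, SaturationError


class TestLambdaFromCounts:
    def test_all_negative_is_zero(self):
        assert ddrain.lambda_from_counts(10_000, 10_000) == 0.0

    def test_half_negative_is_ln2(self):
        assert ddrain.lambda_from_counts(5000, 10_000) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_e_minus_one_fraction(self):
        # high-precision oracle: -ln(0.3679) = 0.999944116871408375...
        assert ddrain.lambda_from_counts(3679, 10_000) == pytest.approx(
            0.999944116871408, abs=1e-12
        )

    def test_saturation_is_explicit_error(self):
        with pytest.raises(SaturationError):
            ddrain.lambda_from_counts(0, 10_000)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ddrain.lambda_from_counts(5, 0)
        with pytest.raises(ValueError):
            ddrain.lambda_from_counts(11, 10)

    @given(
        n_acc=st.integers(10, 100_000),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_negatives(self, n_acc, data):
        n1 = data.draw(st.integers(1, n_acc))
        n2 = data.draw(st.integers(n1, n_acc))
        assert ddrain.lambda_from_counts(n2, n_acc) <= ddrain.lambda_from_counts(
            n1, n_acc
        )


class TestVafFromCounts:
    def test_symmetric_counts_give_fifty_percent(self):
        c = ClassCounts(nn=8100, np=900, pn=900, pp=100)
        r = ddrain.vaf_from_counts(c)
        assert r.vaf_percent == pytest.approx(50.0, abs=1e-9)

    def test_no_mutant_positive_is_zero(self):
        r = ddrain.vaf_from_counts(ClassCounts(nn=9000, np=1000, pn=0, pp=0))
        assert r.vaf_percent == 0.0

    def test_worked_mixed_counts(self):
        # Mutant negatives 9000/10000, wild-type negatives 6000/10000.
        c = ClassCounts(nn=5400, np=3600, pn=600, pp=400)
        lam_mut = -math.log(0.9)
        lam_wt = -math.log(0.6)
        r = ddrain.vaf_from_counts(c)
        assert r.lambda_mut == pytest.approx(lam_mut, abs=1e-12)
        assert r.lambda_wt == pytest.approx(lam_wt, abs=1e-12)
        assert r.vaf_percent == pytest.approx(100 * lam_mut / (lam_mut + lam_wt), abs=1e-9)
        assert r.vaf_percent == pytest.approx(17.10, abs=0.005)

    def test_saturated_channel_is_flagged_not_raised(self):
        r = ddrain.vaf_from_counts(ClassCounts(nn=0, np=0, pn=5000, pp=5000))
        assert r.vaf_percent is None
        assert not r.qc_pass
        assert any("saturated" in reason for reason in r.qc_reasons)

    def test_no_template_is_flagged_undefined(self):
        r = ddrain.vaf_from_counts(ClassCounts(nn=10_000, np=0, pn=0, pp=0))
        assert r.vaf_percent is None
        assert any("undefined" in reason for reason in r.qc_reasons)

    @given(
        nn=st.integers(1, 5000),
        np_=st.integers(1, 3000),
        pn=st.integers(1, 3000),
        pp=st.integers(0, 2000),
    )
    @settings(max_examples=100, deadline=None)
    def test_channel_swap_mirrors_vaf(self, nn, np_, pn, pp):
        a = ddrain.vaf_from_counts(ClassCounts(nn=nn, np=np_, pn=pn, pp=pp))
        b = ddrain.vaf_from_counts(ClassCounts(nn=nn, np=pn, pn=np_, pp=pp))
        assert a.vaf_percent == pytest.approx(100.0 - b.vaf_percent, abs=1e-9)


class TestQcReaction:
    NTC = ClassCounts(nn=11_000, np=1, pn=2, pp=3)  # positive mean 2.0

    def test_droplet_floor(self):
        c = ClassCounts(nn=9000, np=500, pn=300, pp=199)  # accepted 9,999
        ok, reasons = ddrain.qc_reaction(c, self.NTC)
        assert not ok
        assert any("10000" in r for r in reasons)

    def test_passing_reaction(self):
        c = ClassCounts(nn=11_000, np=500, pn=300, pp=200)
        ok, reasons = ddrain.qc_reaction(c, self.NTC)
        assert ok and reasons == []

    def test_signal_below_ntc(self):
        c = ClassCounts(nn=12_000, np=1, pn=1, pp=1)  # positive mean 1.0 < 2.0
        ok, reasons = ddrain.qc_reaction(c, self.NTC)
        assert not ok
        assert any("NTC" in r for r in reasons)

    def test_both_rules_reported(self):
        c = ClassCounts(nn=9000, np=0, pn=0, pp=0)
        ok, reasons = ddrain.qc_reaction(c, self.NTC)
        assert not ok and len(reasons) == 2

    def test_multiple_ntc_wells_averaged(self):
        c = ClassCounts(nn=12_000, np=3, pn=3, pp=3)  # positive mean 3.0
        loud = ClassCounts(nn=11_000, np=4, pn=4, pp=4)  # mean 4.0
        quiet = ClassCounts(nn=11_000, np=1, pn=1, pp=1)  # mean 1.0
        ok, _ = ddrain.qc_reaction(c, [loud, quiet])  # NTC mean 2.5 < 3
        assert ok
        ok2, _ = ddrain.qc_reaction(c, [loud, loud])  # NTC mean 4 > 3
        assert not ok2


class TestSelectReplicate:
    def _result(self, vaf, rep, qc=True):
        return ddrain.QuantResult(
            lambda_mut=0.1, lambda_wt=0.2, vaf_percent=vaf,
            accepted_droplets=12_000, qc_pass=qc, replicate_index=rep,
        )

    def test_closest_to_reference_wins(self):
        best = ddrain.select_replicate(
            [self._result(20.0, 0), self._result(30.0, 1)], reference_vaf=28.0
        )
        assert best.vaf_percent == 30.0

    def test_single_replicate_returned(self):
        r = self._result(12.0, 0)
        assert ddrain.select_replicate([r], reference_vaf=99.0) is r

    def test_tie_goes_to_lowest_index(self):
        best = ddrain.select_replicate(
            [self._result(25.0, 0), self._result(31.0, 1)], reference_vaf=28.0
        )
        assert best.vaf_percent == 25.0

    def test_failing_replicates_excluded(self):
        with pytest.raises(ddrain.NoPassingReplicateError):
            ddrain.select_replicate([self._result(20.0, 0, qc=False)], 20.0)


class TestPositivityThreshold:
    def test_zero_spread_threshold_is_mean(self):
        t = ddrain.positivity_threshold([4.2, 4.2, 4.2], confidence=0.9998)
        assert t.threshold_percent == pytest.approx(4.2)

    def test_t_interval_worked_example(self):
        # mean 9, s = 1, n = 3; t_{0.975, 2} = 4.30265
        t = ddrain.positivity_threshold([8.0, 9.0, 10.0], confidence=0.95)
        assert t.threshold_percent == pytest.approx(9 + 4.30265 / math.sqrt(3), abs=1e-4)
        assert t.threshold_percent == pytest.approx(11.4841, abs=1e-3)

    def test_too_few_controls_rejected(self):
        with pytest.raises(ValueError):
            ddrain.positivity_threshold([5.0])

    def test_invalid_confidence_rejected(self):
        with pytest.raises(ValueError):
            ddrain.positivity_threshold([1.0, 2.0], confidence=-0.5)

    def test_threshold_not_below_mean(self):
        t = ddrain.positivity_threshold([1.0, 3.0, 8.0, 2.0], confidence=0.9998)
        assert t.threshold_percent >= 3.5


class TestCallSample:
    THR = ddrain.PositivityThreshold(threshold_percent=9.82, confidence=0.9998, n_controls=4)

    def test_just_above_legacy_cutoff_is_positive(self):
        assert ddrain.call_sample(9.9, self.THR) == "positive"

    def test_exactly_at_threshold_is_negative(self):
        assert ddrain.call_sample(9.82, self.THR) == "negative"

    def test_zero_is_negative(self):
        assert ddrain.call_sample(0.0, self.THR) == "negative"

    def test_undefined_vaf_is_no_call(self):
        assert ddrain.call_sample(None, self.THR) == "no-call"


class TestQuantifyWell:
    def test_rain_excluded_from_denominator(self):
        import numpy as np

        w = ddrain.Well(well_id="w", amplitudes=np.ones((6, 2)))
        cw = ddrain.ClassifiedWell(
            well=w, labels=["NN", "NN", "NP", "PN", "RAIN", "RAIN"]
        )
        r = ddrain.quantify_well(cw)
        assert r.accepted_droplets == 4
        # mutant negatives 3/4, wt negatives 3/4
        assert r.lambda_mut == pytest.approx(-math.log(3 / 4))
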