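"""Gating, k-NN and rain-filter behaviour."""

import math

import numpy as np
import pytest

import ddrain
from conftest import brute_force_knn
from ddrain.classify import _CODE

CODES = np.array([_CODE[lab] for lab in ddrain.CLASS_LABELS])


def _well(amps, **kwargs):
    return ddrain.Well(well_id=kwargs.pop("well_id", "w"), amplitudes=amps, **kwargs)


class TestNtcGate:
    def test_zero_variance_cut_equals_mean(self):
        w = _well(np.full((10, 2), 1000.0))
        gate = ddrain.fit_ntc_gate(w, multiplier=7.0)
        assert gate.ch1_cut == 1000.0
        assert gate.ch2_cut == 1000.0

    def test_mean_plus_multiplier_sd(self):
        # ch1 values with mean 1000 and sample SD 100 -> cut 1500 at x5.
        ch1 = np.array([900.0, 1000.0, 1100.0])
        assert np.std(ch1, ddof=1) == pytest.approx(100.0)
        w = _well(np.column_stack([ch1, ch1]))
        gate = ddrain.fit_ntc_gate(w, multiplier=5.0)
        assert gate.ch1_cut == pytest.approx(1500.0)

    def test_single_droplet_ntc_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            ddrain.fit_ntc_gate(_well([[1000.0, 1000.0]]))


class TestManualGate:
    GATE = ddrain.GateThresholds(ch1_cut=3000.0, ch2_cut=3000.0)

    @pytest.mark.parametrize(
        "amp,expected",
        [
            ((9000, 1000), "PN"),
            ((1000, 9000), "NP"),
            ((9000, 9000), "PP"),
            ((1000, 1000), "NN"),
            ((3000, 3000), "NN"),   # exactly on both cuts -> negative side
            ((3000.0001, 3000), "PN"),
        ],
    )
    def test_quadrant_assignment(self, amp, expected):
        cw = ddrain.manual_gate(_well([amp]), self.GATE)
        assert cw.labels[0] == expected

    def test_never_emits_rain(self, clean_well):
        well, _, _ = clean_well
        cw = ddrain.manual_gate(well, self.GATE)
        assert cw.counts["RAIN"] == 0


class TestKnnClassify:
    SQUARE = ddrain.TrainingSet(
        amplitudes=np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 0.0], [10.0, 10.0]]),
        labels=np.array(["NN", "NP", "PN", "PP"]),
    )

    def test_coincident_query_k1(self):
        cw = ddrain.knn_classify(_well([[0.0, 10.0]]), self.SQUARE, k=1)
        assert cw.labels[0] == "NP"

    def test_majority_vote(self):
        tr = ddrain.TrainingSet(
            amplitudes=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
            labels=np.array(["PN", "PN", "NP"]),
        )
        cw = ddrain.knn_classify(_well([[0.2, 0.2]]), tr, k=3)
        assert cw.labels[0] == "PN"

    def test_three_way_tie_goes_to_nearest(self):
        # Query (8,2): d^2 = 8 to PN, 68 to NN and PP, 128 to NP.  With
        # k=3 each of PN/NN/PP gets one vote; the nearest (PN) wins.
        cw = ddrain.knn_classify(_well([[8.0, 2.0]]), self.SQUARE, k=3)
        assert cw.labels[0] == "PN"

    def test_k1_reproduces_training_labels(self):
        rng = np.random.default_rng(11)
        amps = rng.uniform(0, 100, size=(40, 2))
        labels = np.array(ddrain.CLASS_LABELS)[rng.integers(0, 4, size=40)]
        tr = ddrain.TrainingSet(amplitudes=amps, labels=labels)
        cw = ddrain.knn_classify(_well(amps), tr, k=1)
        np.testing.assert_array_equal(cw.labels, labels)

    def test_empty_training_and_oversized_k_rejected(self):
        with pytest.raises(ValueError, match="k=5 exceeds"):
            ddrain.knn_classify(_well([[0.0, 0.0]]), self.SQUARE, k=5)

    def test_permutation_invariance(self, clean_well, training_set):
        well, _, _ = clean_well
        perm = np.random.default_rng(1).permutation(well.n_droplets)
        shuffled = _well(well.amplitudes[perm])
        a = ddrain.knn_classify(well, training_set, k=3)
        b = ddrain.knn_classify(shuffled, training_set, k=3)
        np.testing.assert_array_equal(a.labels[perm], b.labels)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_exhaustive_search(self, k):
        rng = np.random.default_rng(202)
        for _ in range(10):
            n_tr = int(rng.integers(k, 51))
            n_q = int(rng.integers(1, 201))
            tr_amps = rng.uniform(0, 1000, size=(n_tr, 2))
            tr_codes = rng.integers(0, 4, size=n_tr)
            tr = ddrain.TrainingSet(
                amplitudes=tr_amps,
                labels=np.array(ddrain.CLASS_LABELS)[tr_codes],
            )
            q = rng.uniform(0, 1000, size=(n_q, 2))
            got = ddrain.knn_classify(_well(q), tr, k=k)
            expected = CODES[brute_force_knn(q, tr_amps, tr_codes, k)]
            np.testing.assert_array_equal(
                got.labels, np.array(ddrain.CLASS_LABELS)[expected]
            )

    def test_high_accuracy_on_clean_simulation(self, clean_well, training_set):
        well, truth, _ = clean_well
        cw = ddrain.knn_classify(well, training_set, k=3)
        assert (cw.labels == truth).mean() >= 0.99


class TestRainFilter:
    def test_disabled_filter_is_identity(self, clean_well, training_set):
        well, _, _ = clean_well
        cw = ddrain.knn_classify(well, training_set, k=3)
        policy = ddrain.RainPolicy(rain_distance=np.inf,
                                   low_bound=-np.inf, high_bound=np.inf)
        out = ddrain.apply_rain_filter(cw, training_set, policy)
        np.testing.assert_array_equal(out.labels, cw.labels)

    def test_droplet_at_centroid_never_rain(self):
        tr = ddrain.TrainingSet(
            amplitudes=np.array([[0.0, 0.0], [2.0, 0.0], [1000.0, 1000.0], [1002.0, 1000.0]]),
            labels=np.array(["NN", "NN", "PP", "PP"]),
        )
        w = _well([[1.0, 0.0]])
        cw = ddrain.ClassifiedWell(well=w, labels=["NN"])
        out = ddrain.apply_rain_filter(
            cw, tr, ddrain.RainPolicy(rain_distance=1e-9, low_bound=-1, high_bound=1e9)
        )
        assert out.labels[0] == "NN"

    def test_distance_rule_uses_euclidean_distance(self):
        # Droplet at distance exactly 5 from its class centroid.
        tr = ddrain.TrainingSet(
            amplitudes=np.array([[0.0, 0.0], [0.0, 0.0]]),
            labels=np.array(["NN", "NN"]),
        )
        w = _well([[3.0, 4.0]])
        cw = ddrain.ClassifiedWell(well=w, labels=["NN"])
        rained = ddrain.apply_rain_filter(
            cw, tr, ddrain.RainPolicy(rain_distance=4.0, low_bound=-1, high_bound=1e9)
        )
        kept = ddrain.apply_rain_filter(
            cw, tr, ddrain.RainPolicy(rain_distance=5.5, low_bound=-1, high_bound=1e9)
        )
        assert rained.labels[0] == "RAIN"
        assert kept.labels[0] == "NN"

    def test_amplitude_bounds_mark_broken_and_outliers(self, training_set):
        w = _well([[10.0, 10.0], [20_000.0, 9000.0], [1000.0, 1000.0]])
        cw = ddrain.ClassifiedWell(well=w, labels=["NN", "PP", "NN"])
        out = ddrain.apply_rain_filter(
            cw, training_set,
            ddrain.RainPolicy(rain_distance=np.inf, low_bound=300, high_bound=12_000),
        )
        assert list(out.labels) == ["RAIN", "RAIN", "NN"]

    def test_idempotent(self, clean_well, training_set):
        well, _, _ = clean_well
        cw = ddrain.knn_classify(well, training_set, k=3)
        policy = ddrain.RainPolicy()
        once = ddrain.apply_rain_filter(cw, training_set, policy)
        twice = ddrain.apply_rain_filter(once, training_set, policy)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_rain_count_monotone_in_distance(self, clean_well, training_set):
        well, _, _ = clean_well
        cw = ddrain.knn_classify(well, training_set, k=3)
        counts = [
            ddrain.apply_rain_filter(
                cw, training_set, ddrain.RainPolicy(rain_distance=d)
            ).counts["RAIN"]
            for d in [2000.0, 1200.0, 800.0, 400.0]
        ]
        assert counts == sorted(counts)

    def test_unrepresented_class_is_an_error(self):
        tr = ddrain.TrainingSet(
            amplitudes=np.array([[0.0, 0.0], [1.0, 1.0]]),
            labels=np.array(["NN", "NN"]),
        )
        w = _well([[500.0, 500.0]])
        cw = ddrain.ClassifiedWell(well=w, labels=["PP"])
        with pytest.raises(ValueError, match="PP"):
            ddrain.apply_rain_filter(
                cw, tr, ddrain.RainPolicy(rain_distance=10.0, low_bound=-1, high_bound=1e9)
            )


class TestBuildTrainingSet:
    def _plates(self, n_plates, wells_each, seed=0):
        plates = []
        rng = np.random.default_rng(seed)
        for p in range(n_plates):
            wells = []
            for i in range(wells_each):
                cfg = ddrain.config_for_vaf(
                    30.0, n_droplets=200, seed=int(rng.integers(1 << 30))
                )
                w, labels = ddrain.simulate_well(
                    cfg, well_id=f"P{p}W{i}", sample_id=f"P{p}S{i}"
                )
                wells.append(ddrain.ClassifiedWell(well=w, labels=labels))
            plates.append(wells)
        return plates

    def test_six_plates_times_three_wells(self):
        tr = ddrain.build_training_set(self._plates(6, 5), wells_per_plate=3, seed=1)
        assert len(tr.source_wells) == 18
        assert len(tr) > 0
        assert set(np.unique(tr.labels)) <= set(ddrain.CLASS_LABELS)

    def test_single_plate_single_well(self):
        tr = ddrain.build_training_set(self._plates(1, 2), wells_per_plate=1, seed=3)
        assert len(tr.source_wells) == 1

    def test_seed_determinism(self):
        plates = self._plates(4, 6)
        a = ddrain.build_training_set(plates, wells_per_plate=2, seed=9)
        b = ddrain.build_training_set(plates, wells_per_plate=2, seed=9)
        assert a.source_wells == b.source_wells

    def test_insufficient_wells_rejected(self):
        with pytest.raises(ValueError, match="eligible"):
            ddrain.build_training_set(self._plates(2, 2), wells_per_plate=3, seed=0)

    def test_rain_droplets_dropped_from_pool(self):
        w = _well(np.ones((4, 2)) * 1000, well_id="t")
        cw = ddrain.ClassifiedWell(well=w, labels=["NN", "RAIN", "NN", "RAIN"])
        tr = ddrain.build_training_set([[cw]], wells_per_plate=1, seed=0)
        assert len(tr) == 2
        assert "RAIN" not in tr.labels
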