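import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ededock import scoring as sc
from ededock.exceptions import (
    AllScoresMissingError,
    EmptyResultsError,
    ReferenceEnergyError,
    UnlabeledCompoundError,
)

KT300 = 0.0019872041 * 300.0


def oracle_score(dg_bind, dg_conf, kT=KT300):
    """Direct partition-sum evaluation: kT·ln(P_unbound / P_bound).

    Enumerates both partitions term by term with plain math.exp — an
    implementation independent of the log-sum-exp production path.
    """
    p_unbound = sum(math.exp(-g) for g in dg_conf)
    p_bound = sum(
        math.exp(-gc - gb / kT)
        for gc, gb in zip(dg_conf, dg_bind)
        if math.isfinite(gb)
    )
    return kT * math.log(p_unbound / p_bound)


def random_instance(rng, n=None, allow_missing=False):
    n = n if n is not None else int(rng.integers(1, 9))
    dg_conf = np.concatenate([[0.0], rng.uniform(0.0, 6.0, n - 1)])
    rng.shuffle(dg_conf)
    dg_conf -= dg_conf.min()
    dg_bind = rng.uniform(-14.0, -2.0, n)
    if allow_missing and n > 1:
        drop = rng.random(n) < 0.2
        if drop.all():
            drop[rng.integers(n)] = False
        dg_bind[drop] = np.nan
    return dg_bind, dg_conf


class TestEnsembleScore:
    def test_single_conformation_identity(self):
        s, contrib = sc.ensemble_score(np.array([-11.2]), np.array([0.0]))
        assert s == pytest.approx(-11.2, abs=1e-12)
        np.testing.assert_allclose(contrib, [1.0])

    def test_equal_conformations_equal_scores(self):
        s, _ = sc.ensemble_score(np.full(4, -8.3), np.zeros(4))
        assert s == pytest.approx(-8.3, abs=1e-12)

    def test_reference_four_state_instance_vs_oracle(self):
        dg_conf = np.array([0.0, 0.5108, 1.2040, 2.3026])
        dg_bind = np.array([-9.4, -11.2, -8.0, -10.0])
        s, contrib = sc.ensemble_score(dg_bind, dg_conf)
        assert abs(s - oracle_score(dg_bind, dg_conf)) < 1e-10 * abs(s)
        assert contrib.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(contrib >= 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_vs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(400):
            dg_bind, dg_conf = random_instance(rng, allow_missing=True)
            s, _ = sc.ensemble_score(dg_bind, dg_conf)
            assert abs(s - oracle_score(dg_bind, dg_conf)) <= 1e-10 * max(abs(s), 1.0)

    def test_bounds_within_per_conformation_scores(self, rng):
        for _ in range(500):
            dg_bind, dg_conf = random_instance(rng)
            s, _ = sc.ensemble_score(dg_bind, dg_conf)
            assert dg_bind.min() - 1e-12 <= s <= dg_bind.max() + 1e-12

    def test_monotone_in_any_single_score(self, rng):
        dg_bind, dg_conf = random_instance(rng, n=5)
        base, _ = sc.ensemble_score(dg_bind, dg_conf)
        for i in range(5):
            better = dg_bind.copy()
            better[i] -= 1.0
            s, _ = sc.ensemble_score(better, dg_conf)
            assert s < base

    def test_rare_state_does_not_contribute(self, rng):
        """A 20 kT conformation is negligible even when it docks as well as
        the best-scoring state of the ensemble."""
        for _ in range(200):
            dg_bind, dg_conf = random_instance(rng)
            base, _ = sc.ensemble_score(dg_bind, dg_conf)
            dg_bind2 = np.append(dg_bind, dg_bind.min())
            dg_conf2 = np.append(dg_conf, 20.0)
            s, _ = sc.ensemble_score(dg_bind2, dg_conf2)
            assert abs(s - base) < 1e-6

    def test_missing_pose_drops_bound_term_only(self):
        dg_conf = np.array([0.0, 1.0])
        full, _ = sc.ensemble_score(np.array([-10.0, -9.0]), dg_conf)
        part, contrib = sc.ensemble_score(np.array([-10.0, np.nan]), dg_conf)
        # unbound partition unchanged, bound partition loses a term -> worse
        assert part > full
        assert contrib[1] == 0.0 and contrib[0] == 1.0

    def test_all_missing_raises(self):
        with pytest.raises(AllScoresMissingError):
            sc.ensemble_score(np.array([np.nan, np.nan]), np.array([0.0, 1.0]))

    def test_nonzero_reference_raises(self):
        with pytest.raises(ReferenceEnergyError):
            sc.ensemble_score(np.array([-9.0, -9.0]), np.array([0.5, 1.0]))

    def test_numerical_stability_extremes(self):
        dg_bind = np.array([-50.0, 50.0, -50.0])
        dg_conf = np.array([0.0, 250.0, 500.0])
        s, contrib = sc.ensemble_score(dg_bind, dg_conf)
        assert np.isfinite(s) and np.all(np.isfinite(contrib))
        s2 = sc.equal_weight_score(np.array([50.0, -50.0]))
        assert np.isfinite(s2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=8),
           st.lists(st.floats(0, 500), min_size=1, max_size=8))
    def test_property_bounds_and_finiteness(self, scores, confs):
        n = min(len(scores), len(confs))
        dg_bind = np.asarray(scores[:n])
        dg_conf = np.asarray(confs[:n])
        dg_conf -= dg_conf.min()
        s, contrib = sc.ensemble_score(dg_bind, dg_conf)
        assert np.isfinite(s)
        assert dg_bind.min() - 1e-9 <= s <= dg_bind.max() + 1e-9
        assert contrib.sum() == pytest.approx(1.0, abs=1e-9)


class TestEqualWeight:
    def test_equal_scores_identity(self):
        assert sc.equal_weight_score(np.full(4, -7.0)) == pytest.approx(-7.0)

    def test_matches_ensemble_score_with_zero_dgconf(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 9))
            dg_bind = rng.uniform(-14, -2, n)
            a = sc.equal_weight_score(dg_bind)
            b, _ = sc.ensemble_score(dg_bind, np.zeros(n))
            assert abs(a - b) <= 1e-12 * max(abs(a), 1.0)

    def test_soft_minimum_behavior(self):
        s = sc.equal_weight_score(np.array([-10.0, 0.0]))
        assert -10.0 < s < 0.0
        assert abs(s - (-10.0)) < abs(s - (-5.0))

    def test_limit_consistency(self, rng):
        dg_bind = rng.uniform(-12, -4, 5)
        for eps in (1e-3, 1e-6, 1e-9):
            dg_conf = np.array([0.0, eps, eps, eps, eps])
            s, _ = sc.ensemble_score(dg_bind, dg_conf)
            if eps <= 1e-9:
                assert abs(s - sc.equal_weight_score(dg_bind)) < 1e-9


class TestThermalContext:
    def test_kT_at_300K(self):
        assert sc.ThermalContext(300.0).kT == pytest.approx(0.59616, abs=1e-4)

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            sc.ThermalContext(-1.0)


def _results(scores, ids=None):
    ids = ids or [f"c{i}" for i in range(len(scores))]
    return [sc.EnsembleResult(compound_id=i, ensemble_dg_bind=s,
                              contributions=np.ones(1), n_conformations_used=1)
            for i, s in zip(ids, scores)]


class TestTriage:
    def test_class_mean_partition(self):
        # class-average scores: strong -10.4, medium -9.8, weak -8.5
        actives, inactives = sc.triage(_results([-10.4, -9.8, -8.5]), cutoff=-9.0)
        assert [r.ensemble_dg_bind for r in actives] == [-10.4, -9.8]
        assert [r.ensemble_dg_bind for r in inactives] == [-8.5]

    def test_boundary_is_active(self):
        actives, inactives = sc.triage(_results([-9.0]), cutoff=-9.0)
        assert len(actives) == 1 and not inactives

    def test_empty(self):
        assert sc.triage([], cutoff=-9.0) == ([], [])

    def test_sorted_ascending_within_partitions(self, rng):
        res = _results(list(rng.uniform(-12, -6, 20)))
        actives, inactives = sc.triage(res, cutoff=-9.0)
        for part in (actives, inactives):
            vals = [r.ensemble_dg_bind for r in part]
            assert vals == sorted(vals)


class TestEvaluateScreen:
    def test_perfect_separation(self):
        res = _results([-10.0, -9.5, -8.0, -7.5], ids=list("abcd"))
        labels = {"a": "strong", "b": "medium", "c": "weak", "d": "weak"}
        ev = sc.evaluate_screen(res, labels, cutoff=-9.0)
        assert ev["accuracy"] == 1.0 and ev["fnr"] == 0.0 and ev["fpr"] == 0.0

    def test_all_predicted_active_half_true(self):
        res = _results([-10.0, -10.0, -10.0, -10.0], ids=list("abcd"))
        labels = {"a": "strong", "b": "strong", "c": "weak", "d": "weak"}
        ev = sc.evaluate_screen(res, labels, cutoff=-9.0)
        assert ev["accuracy"] == 0.5
        assert ev["fpr"] == 1.0 and ev["fnr"] == 0.0

    def test_undefined_rates_reported_as_none(self):
        res = _results([-10.0], ids=["a"])
        ev = sc.evaluate_screen(res, {"a": "strong"}, cutoff=-9.0)
        assert ev["fpr"] is None  # no true negatives or false positives

    def test_random_23_compounds_vs_hand_enumeration(self, rng):
        scores = rng.uniform(-12, -6, 23)
        classes = rng.choice(["strong", "medium", "weak"], 23)
        ids = [f"c{i}" for i in range(23)]
        res = _results(list(scores), ids=ids)
        labels = dict(zip(ids, classes))
        ev = sc.evaluate_screen(res, labels, cutoff=-9.0)
        tp = fp = tn = fn = 0
        for s, c in zip(scores, classes):
            pred, truth = s <= -9.0, c in ("strong", "medium")
            tp += pred and truth
            fp += pred and not truth
            fn += (not pred) and truth
            tn += (not pred) and (not truth)
        assert (ev["tp"], ev["fp"], ev["tn"], ev["fn"]) == (tp, fp, tn, fn)
        assert ev["accuracy"] == pytest.approx((tp + tn) / 23)

    def test_unlabeled_compound_raises(self):
        with pytest.raises(UnlabeledCompoundError):
            sc.evaluate_screen(_results([-10.0], ids=["a"]), {}, cutoff=-9.0)


class TestScreenSummary:
    def test_full_fraction_is_plain_mean(self, rng):
        scores = list(rng.uniform(-12, -6, 4))
        out = sc.screen_summary(_results(scores), top_fraction=1.0)
        assert out["mean"] == pytest.approx(np.mean(scores))

    def test_top_fraction_matches_brute_force(self, rng):
        scores = rng.uniform(-14, -2, 1000)
        out = sc.screen_summary(_results(list(scores)), top_fraction=0.025)
        assert out["n_top"] == 25
        assert out["mean"] == pytest.approx(np.sort(scores)[:25].mean())

    def test_degenerate_scores(self):
        out = sc.screen_summary(_results([-9.0] * 5), top_fraction=0.5)
        assert out["mean"] == -9.0 and out["std"] == 0.0

    def test_empty_raises(self):
        with pytest.raises(EmptyResultsError):
            sc.screen_summary([], top_fraction=0.5)


class TestScoreTable:
    def test_csv_roundtrip_with_missing(self, tmp_path, rng):
        dg = rng.uniform(-12, -4, (5, 3))
        dg[1, 2] = np.nan
        t = sc.ScoreTable([f"c{i}" for i in range(5)], ["S0", "S1", "S2"], dg)
        p = t.to_csv(tmp_path / "scores.csv")
        back = sc.ScoreTable.from_csv(p)
        np.testing.assert_allclose(back.dg_bind, dg)
        assert back.compound_ids == t.compound_ids

    def test_all_missing_compound_rejected(self):
        with pytest.raises(AllScoresMissingError):
            sc.ScoreTable(["a"], ["S0", "S1"], np.array([[np.nan, np.nan]]))


class TestScorerEstimator:
    def test_fit_predict_roundtrip(self, rng):
        dg_conf = np.array([0.0, 0.5, 1.2, 2.3])
        table = sc.ScoreTable(
            [f"c{i}" for i in range(10)], ["S0", "S1", "S2", "S3"],
            rng.uniform(-12, -6, (10, 4)))
        scorer = sc.BoltzmannEnsembleScorer().fit(dg_conf)
        scores = scorer.decision_function(table)
        expected = [sc.ensemble_score(row, dg_conf)[0] for row in table.dg_bind]
        np.testing.assert_allclose(scores, expected, atol=1e-12)
        np.testing.assert_array_equal(scorer.predict(table), scores <= -9.0)

    def test_sklearn_get_set_params(self):
        scorer = sc.BoltzmannEnsembleScorer()
        scorer.set_params(temperature=310.0, triage_cutoff=-8.5)
        assert scorer.get_params() == {"temperature": 310.0, "triage_cutoff": -8.5}
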