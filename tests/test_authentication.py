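import numpy as np
import pytest
from scipy import stats

from breathauth.authentication import (combine_votes, confirm_ht, confirm_ml,
                                       evaluate, hotelling_t2, identify,
                                       precision_accuracy,
                                       true_confirmation_rate, ztest_boundary)
from breathauth.enrollment import enroll, split_user

from conftest import make_gaussian_cohort


def _enrolled(cohort, seed=0):
    train, test = {}, {}
    for u, m in cohort.items():
        train[u], test[u] = split_user(m, seed=seed)
    names = cohort[sorted(cohort)[0]].feature_names
    return enroll(train, names, test_features=test), test


class TestHotelling:
    def test_identical_samples_statistic_zero(self):
        x = np.random.default_rng(0).normal(size=(30, 5))
        res = hotelling_t2(x, x.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-20)
        assert res.p_value == pytest.approx(1.0)

    def test_1d_equals_squared_pooled_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(25, 1))
        b = rng.normal(0.7, 1, size=(35, 1))
        res = hotelling_t2(a, b)
        t, _ = stats.ttest_ind(a.ravel(), b.ravel(), equal_var=True)
        assert res.statistic == pytest.approx(t ** 2, abs=1e-10)

    def test_power_at_large_separation(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(50, 10))
        b = rng.normal(5, 1, size=(50, 10))
        assert hotelling_t2(a, b).p_value < 1e-3

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, size=(40, 4))
        b = rng.normal(0.3, 1.2, size=(55, 4))
        res = hotelling_t2(a, b)
        oracle = pingouin.multivariate_ttest(a, b)
        assert res.statistic == pytest.approx(float(oracle["T2"].iloc[0]),
                                              rel=1e-9)
        assert res.p_value == pytest.approx(float(oracle["pval"].iloc[0]),
                                            rel=1e-6)

    def test_insufficient_samples_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            hotelling_t2(rng.normal(size=(5, 10)), rng.normal(size=(5, 10)))

    def test_singular_covariance_ridged(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(30, 3))
        a[:, 2] = a[:, 1]  # perfectly collinear
        b = rng.normal(1, 1, size=(30, 3))
        b[:, 2] = b[:, 1]
        res = hotelling_t2(a, b)
        assert res.ridged
        assert np.isfinite(res.statistic) and 0 <= res.p_value <= 1


class TestConfirmation:
    def test_genuine_claim_confirmed_ht(self, gaussian_cohort3):
        lib, test = _enrolled(gaussian_cohort3)
        res = confirm_ht(test["user001"], "user001", lib)
        assert res.v == 2 and res.eta == 100.0 and res.confirmed

    def test_impostor_rejected_ht(self, gaussian_cohort3):
        lib, test = _enrolled(gaussian_cohort3)
        res = confirm_ht(test["user002"], "user000", lib)
        assert not res.confirmed

    def test_no_prediction_when_both_rejected(self, gaussian_cohort3):
        lib, test = _enrolled(gaussian_cohort3)
        alien = test["user000"].data + 1000.0  # far from every user
        alien_fm = type(test["user000"])(alien)
        res = confirm_ht(alien_fm, "user000", lib)
        assert res.v == 0 and not res.confirmed
        assert all(d[1] is None for d in res.per_pair_detail)

    def test_genuine_claim_confirmed_ml(self, gaussian_cohort3):
        lib, test = _enrolled(gaussian_cohort3)
        res = confirm_ml(test["user001"], "user001", lib)
        assert res.eta >= 50 and res.confirmed

    def test_genuine_claim_dominates_impostor_claims_ml(self,
                                                        gaussian_cohort3):
        # the one-vs-one committee has no reject option, so a neighbouring
        # identity can collect stray votes; the guarantee the identification
        # stage relies on is that the genuine claim always scores strictly
        # highest for a given subject's data
        lib, test = _enrolled(gaussian_cohort3)
        for claimant in lib.user_ids:
            etas = {claimed: confirm_ml(test[claimant], claimed, lib).eta
                    for claimed in lib.user_ids}
            genuine = etas.pop(claimant)
            assert genuine > max(etas.values())

    def test_two_user_cohort_eta_binary(self):
        lib, test = _enrolled(make_gaussian_cohort(2, seed=21))
        res = confirm_ml(test["user000"], "user000", lib)
        assert res.eta in (0.0, 100.0)

    def test_unenrolled_claim_rejected(self, gaussian_cohort3):
        lib, test = _enrolled(gaussian_cohort3)
        with pytest.raises(KeyError):
            confirm_ml(test["user000"], "ghost", lib)


class TestVoteFusion:
    def test_identity_weight(self):
        v = np.array([40.0, 60.0, 0.0])
        np.testing.assert_array_equal(combine_votes([v, v * 0], [1.0, 0.0]), v)

    def test_weighted_sum(self):
        out = combine_votes([np.array([100.0, 0.0]), np.array([0.0, 100.0])],
                            [0.3, 0.7])
        np.testing.assert_allclose(out, [30.0, 70.0])

    @pytest.mark.parametrize("weights", [[0.5, 0.6], [1.2, -0.2], [0.5]])
    def test_invalid_weights_rejected(self, weights):
        vecs = [np.zeros(3), np.zeros(3)]
        with pytest.raises(ValueError):
            combine_votes(vecs[:len(weights)] if len(weights) < 2 else vecs,
                          weights)

    def test_pure_weights_reproduce_single_method(self, gaussian_cohort3):
        lib, test = _enrolled(gaussian_cohort3)
        both = identify(test["user001"], lib, weights=(0.3, 0.7), eta_t=0)
        ht_only = identify(test["user001"], lib, weights=(1.0, 0.0), eta_t=0)
        ml_only = identify(test["user001"], lib, weights=(0.0, 1.0), eta_t=0)
        np.testing.assert_array_equal(ht_only.fused, both.vote_vectors["HT"])
        np.testing.assert_array_equal(ml_only.fused, both.vote_vectors["ML"])


class TestIdentification:
    def test_separated_cohort_mostly_identified(self, gaussian_cohort5):
        lib, test = _enrolled(gaussian_cohort5)
        correct = sum(
            identify(test[u], lib, true_user=u).outcome == "true_positive"
            for u in lib.user_ids)
        assert correct >= 4

    def test_tie_yields_no_identification(self):
        # two users with identical training data: HT favors every claimant,
        # so with pure-HT weights the fused vector is a perfect tie
        cohort = make_gaussian_cohort(2, seed=30)
        train, test = {}, {}
        train["user000"], test["user000"] = split_user(cohort["user000"],
                                                       seed=0)
        twin = cohort["user000"].data.copy()
        twin.index = twin.index.set_levels(
            twin.index.levels[0].str.replace("user000", "user001"), level=0)
        cohort["user001"] = type(cohort["user000"])(twin)
        train["user001"], test["user001"] = split_user(cohort["user001"],
                                                       seed=0)
        names = cohort["user000"].feature_names
        lib = enroll(train, names)
        res = identify(test["user000"], lib, weights=(1.0, 0.0), eta_t=50)
        assert res.identified is None
        assert res.outcome == "not_identified"

    def test_unreachable_threshold_identifies_nobody(self, gaussian_cohort3):
        lib, test = _enrolled(gaussian_cohort3)
        outcomes = [identify(test[u], lib, eta_t=101.0, true_user=u).outcome
                    for u in lib.user_ids]
        assert outcomes == ["not_identified"] * 3

    def test_degenerates_to_confirmation_for_two_users(self):
        cohort = make_gaussian_cohort(2, seed=31)
        lib, test = _enrolled(cohort)
        for u in lib.user_ids:
            ml = confirm_ml(test[u], u, lib)
            res = identify(test[u], lib, weights=(0.0, 1.0), eta_t=50,
                           true_user=u)
            if ml.confirmed and res.identified is not None:
                assert res.identified == u

    def test_raising_threshold_monotone_in_security(self, gaussian_cohort5):
        lib, test = _enrolled(gaussian_cohort5)
        results = {u: identify(test[u], lib, eta_t=0.0, true_user=u)
                   for u in lib.user_ids}
        t_prev, f_prev = None, None
        for eta_t in (0.0, 25.0, 50.0, 75.0, 100.0, 101.0):
            t = f = 0
            for u, res in results.items():
                vmax = res.fused.max()
                unique = (res.fused == vmax).sum() == 1
                if unique and vmax >= eta_t:
                    who = res.user_order[int(np.argmax(res.fused))]
                    if who == u:
                        t += 1
                    else:
                        f += 1
            if t_prev is not None:
                assert t <= t_prev and f <= f_prev
            t_prev, f_prev = t, f


class TestMetrics:
    def test_printed_worked_examples(self):
        assert precision_accuracy(31, 58, 5, 94) == (34.8, 33.0)
        assert precision_accuracy(18, 6, 70, 94) == (75.0, 19.1)

    def test_tcr(self):
        assert true_confirmation_rate(94, 94) == 100.0
        assert true_confirmation_rate(47, 94) == 50.0
        with pytest.raises(ValueError):
            true_confirmation_rate(5, 4)

    def test_precision_undefined_when_no_identifications(self):
        P, E = precision_accuracy(0, 0, 10, 10)
        assert P is None and E == 0.0

    def test_inconsistent_outcomes_rejected(self):
        with pytest.raises(ValueError):
            precision_accuracy(3, 3, 3, 10)


class TestZTestBoundary:
    def test_point_at_training_mean_accepted(self):
        rng = np.random.default_rng(40)
        a = rng.normal([0, 0], 1, size=(200, 2))
        b = rng.normal([10, 10], 1, size=(200, 2))
        labels = ztest_boundary(a, b, np.array([[0.0, 0.0], [10.0, 10.0],
                                                [100.0, 100.0]]))
        assert list(labels) == ["a", "b", "neither"]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(41)
        a = rng.normal([0, 1], [1, 2], size=(150, 2))
        b = rng.normal([3, -1], [2, 1], size=(150, 2))
        grid = rng.uniform(-5, 8, size=(100, 2))
        labels = ztest_boundary(a, b, grid, confidence=0.999)

        def brute(point):
            out = []
            for name, T in (("a", a), ("b", b)):
                ok = True
                for dim in range(2):
                    z = (point[dim] - T[:, dim].mean()) / T[:, dim].std(ddof=1)
                    if 2 * stats.norm.sf(abs(z)) <= 0.001:
                        ok = False
                if ok:
                    out.append(name)
            if len(out) == 2:
                return "both"
            return out[0] if out else "neither"

        assert [brute(p) for p in grid] == list(labels)

    def test_zero_variance_dimension_rejected(self):
        a = np.c_[np.ones(50), np.random.default_rng(42).normal(size=50)]
        b = np.random.default_rng(43).normal(size=(50, 2))
        with pytest.raises(ValueError):
            ztest_boundary(a, b, np.zeros((1, 2)))


class TestEvaluate:
    def test_separable_cohort_perfect_ml(self, gaussian_cohort3):
        rep = evaluate(gaussian_cohort3, n_shuffles=3, seed=1)
        assert rep.summaries["TCR_ML"]["mean"] == 100.0
        assert rep.summaries["TCR_ML"]["two_sigma"] == 0.0

    def test_outcome_conservation(self, gaussian_cohort3):
        rep = evaluate(gaussian_cohort3, n_shuffles=3, seed=2)
        n = rep.n
        for _, row in rep.per_shuffle.iterrows():
            assert row["c_ht"] + row["u_ht"] == n
            assert row["c_ml"] + row["u_ml"] == n
            assert row["t"] + row["f"] + row["h"] == n

    def test_single_shuffle_zero_spread(self, gaussian_cohort3):
        rep = evaluate(gaussian_cohort3, n_shuffles=1, seed=3)
        assert rep.n_shuffles == 1
        assert rep.summaries["TCR_ML"]["two_sigma"] == 0.0

    def test_report_roundtrips_to_json(self, tmp_path, gaussian_cohort3):
        rep = evaluate(gaussian_cohort3, n_shuffles=2, seed=4)
        rep.to_json(tmp_path / "rep.json")
        rep.per_shuffle_csv(tmp_path / "rep.csv")
        assert (tmp_path / "rep.json").stat().st_size > 0
        import json
        data = json.loads((tmp_path / "rep.json").read_text())
        assert data["n"] == 3 and len(data["per_shuffle"]) == 2
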