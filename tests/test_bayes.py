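import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import lymphcoo as lc
from lymphcoo.bayes import BayesError, model_from_json


def _cohort_from_flags(gcb_rows, non_rows, markers=("CD10", "MUM1")):
    """Build a cohort whose binarized patterns (30% cut-off) equal the
    given 0/1 rows; unused markers are filled with 0."""
    rows = []
    for i, (flags, label) in enumerate(
        [(r, "GCB") for r in gcb_rows] + [(r, "ABC") for r in non_rows]
    ):
        profile = {m: 0.0 for m in lc.MARKERS}
        profile.update({m: 90.0 if f else 0.0 for m, f in zip(markers, flags)})
        rows.append({"case_id": f"c{i}", **profile, "gep_label": label})
    return lc.Cohort(pd.DataFrame(rows))


class TestNaiveBayesFit:
    def test_laplace_smoothing_formula(self):
        cohort = _cohort_from_flags(
            gcb_rows=[(1,)] * 3 + [(0,)] * 7, non_rows=[(1,)] * 5, markers=("CD10",)
        )
        model = lc.fit_naive_bayes(cohort, (1,), alpha=1.0)
        assert model.theta[lc.GCB]["CD10"] == pytest.approx(4 / 12)
        assert model.priors[lc.GCB] == pytest.approx(10 / 15)

    def test_unsmoothed_all_positive_gives_theta_one(self):
        cohort = _cohort_from_flags(
            gcb_rows=[(1,)] * 4, non_rows=[(0,)] * 4, markers=("CD10",)
        )
        model = lc.fit_naive_bayes(cohort, (1,), alpha=0.0)
        assert model.theta[lc.GCB]["CD10"] == 1.0

    def test_empty_class_rejected(self, tiny_df):
        df = tiny_df[tiny_df.gep_label == "GCB"]
        with pytest.raises(BayesError, match="non-GCB"):
            lc.fit_naive_bayes(lc.Cohort(df), (1, 5))

    def test_parameter_recovery_at_two_sample_sizes(self):
        """theta and pi estimates converge on the configured generator
        values: coarse at n=2,000, within +/-0.02 at n=40,000."""
        config = lc.default_config(n=40_000, seed=21)
        errors = {}
        for n in (2_000, 40_000):
            cohort = lc.simulate_cohort(lc.default_config(n=n, seed=21))
            model = lc.fit_naive_bayes(cohort, (1, 2, 3, 4, 5), alpha=0.0)
            errs = [
                abs(model.theta[c][m] - config.positivity[c][m])
                for c in (lc.GCB, lc.NON_GCB)
                for m in lc.MARKERS
            ]
            errs.append(abs(model.priors[lc.GCB] - config.prevalence))
            errors[n] = max(errs)
        assert errors[40_000] <= 0.02
        assert errors[40_000] <= errors[2_000] + 0.01  # shrinking with n


class TestJointBayesFit:
    def test_empirical_pattern_table(self):
        cohort = _cohort_from_flags(
            gcb_rows=[(0, 0)] * 4 + [(1, 1)] * 4, non_rows=[(0, 1)] * 4
        )
        model = lc.fit_joint_bayes(cohort, (1, 5), alpha=0.0)
        table = model.tables[lc.GCB]
        assert table[(0, 0)] == pytest.approx(0.5)
        assert table[(0, 1)] == 0.0
        assert table[(1, 0)] == 0.0
        assert table[(1, 1)] == pytest.approx(0.5)

    def test_smoothing_gives_unseen_patterns_mass(self):
        cohort = _cohort_from_flags(gcb_rows=[(0, 0)] * 4, non_rows=[(1, 1)] * 4)
        model = lc.fit_joint_bayes(cohort, (1, 5), alpha=1.0)
        assert model.tables[lc.GCB][(1, 0)] == pytest.approx(1 / 8)

    def test_unsmoothed_model_reproduces_empirical_bayes_decisions(self):
        """With alpha=0 the joint classifier is exactly the empirical
        argmax_c pi_c * p(pattern | c) rule on its own training set."""
        rng = np.random.default_rng(4)
        gcb = [tuple(rng.integers(0, 2, 2)) for _ in range(60)]
        non = [tuple(rng.integers(0, 2, 2)) for _ in range(40)]
        cohort = _cohort_from_flags(gcb_rows=gcb, non_rows=non)
        model = lc.fit_joint_bayes(cohort, (1, 5), alpha=0.0)
        for pattern in itertools.product((0, 1), repeat=2):
            n_g = gcb.count(pattern)
            n_n = non.count(pattern)
            if n_g + n_n == 0:
                continue
            # empirical joint: weight by class counts directly
            expected = lc.GCB if n_g > n_n else lc.NON_GCB
            profile = {"CD10": 90.0 * pattern[0], "MUM1": 90.0 * pattern[1]}
            assert lc.classify_bayes(model, profile) == expected


class TestPosterior:
    def test_symmetric_model_gives_half(self):
        model = lc.BernoulliNBModel(
            combination=(1, 5),
            priors={lc.GCB: 0.5, lc.NON_GCB: 0.5},
            theta={c: {"CD10": 0.7, "MUM1": 0.3} for c in (lc.GCB, lc.NON_GCB)},
            alpha=0.0,
            cutoffs={"CD10": 30.0, "MUM1": 30.0},
        )
        assert lc.posterior(model, {"CD10": 90.0, "MUM1": 0.0}) == pytest.approx(0.5)

    def test_uninformative_markers_return_the_prior(self):
        model = lc.BernoulliNBModel(
            combination=(1,),
            priors={lc.GCB: 0.9, lc.NON_GCB: 0.1},
            theta={c: {"CD10": 0.5} for c in (lc.GCB, lc.NON_GCB)},
            alpha=0.0,
            cutoffs={"CD10": 30.0},
        )
        assert lc.posterior(model, {"CD10": 90.0}) == pytest.approx(0.9)

    def test_two_marker_posterior_matches_hand_computation(self):
        theta = {
            lc.GCB: {"CD10": 0.8, "MUM1": 0.2},
            lc.NON_GCB: {"CD10": 0.1, "MUM1": 0.9},
        }
        model = lc.BernoulliNBModel(
            combination=(1, 5),
            priors={lc.GCB: 0.4, lc.NON_GCB: 0.6},
            theta=theta,
            alpha=0.0,
            cutoffs={"CD10": 30.0, "MUM1": 30.0},
        )
        # pattern CD10+, MUM1-: P(x|G) = .8*.8, P(x|N) = .1*.1
        num = 0.4 * 0.8 * 0.8
        den = num + 0.6 * 0.1 * 0.1
        assert lc.posterior(model, {"CD10": 50.0, "MUM1": 10.0}) == pytest.approx(
            num / den
        )

    def test_missing_marker_is_named(self):
        model = lc.BernoulliNBModel(
            combination=(1, 5),
            priors={lc.GCB: 0.5, lc.NON_GCB: 0.5},
            theta={c: {"CD10": 0.5, "MUM1": 0.5} for c in (lc.GCB, lc.NON_GCB)},
            alpha=0.0,
            cutoffs={"CD10": 30.0, "MUM1": 30.0},
        )
        with pytest.raises(BayesError, match="MUM1"):
            lc.posterior(model, {"CD10": 50.0})

    @given(
        p_cd10=st.floats(0.05, 0.95),
        p_mum1=st.floats(0.05, 0.95),
        prior=st.floats(0.05, 0.95),
        pattern=st.tuples(st.booleans(), st.booleans()),
    )
    def test_posterior_and_complement_sum_to_one(self, p_cd10, p_mum1, prior, pattern):
        model = lc.BernoulliNBModel(
            combination=(1, 5),
            priors={lc.GCB: prior, lc.NON_GCB: 1 - prior},
            theta={
                lc.GCB: {"CD10": p_cd10, "MUM1": p_mum1},
                lc.NON_GCB: {"CD10": p_mum1, "MUM1": p_cd10},
            },
            alpha=0.0,
            cutoffs={"CD10": 30.0, "MUM1": 30.0},
        )
        mirror = lc.BernoulliNBModel(
            combination=(1, 5),
            priors={lc.GCB: 1 - prior, lc.NON_GCB: prior},
            theta={
                lc.GCB: model.theta[lc.NON_GCB],
                lc.NON_GCB: model.theta[lc.GCB],
            },
            alpha=0.0,
            cutoffs={"CD10": 30.0, "MUM1": 30.0},
        )
        profile = {"CD10": 90.0 if pattern[0] else 0.0, "MUM1": 90.0 if pattern[1] else 0.0}
        p = lc.posterior(model, profile)
        q = lc.posterior(mirror, profile)  # complementary posterior
        assert p + q == pytest.approx(1.0)

    def test_decision_invariant_to_marker_order(self, sim_cohort_475):
        a = lc.fit_naive_bayes(sim_cohort_475, (1, 3, 4, 5), alpha=1.0)
        b = lc.fit_naive_bayes(sim_cohort_475, (5, 4, 3, 1), alpha=1.0)
        for i in range(0, len(sim_cohort_475), 7):
            profile = sim_cohort_475.profile(i)
            assert lc.posterior(a, profile) == pytest.approx(lc.posterior(b, profile))


class TestClassification:
    def test_tie_goes_to_non_gcb(self):
        model = lc.BernoulliNBModel(
            combination=(1,),
            priors={lc.GCB: 0.5, lc.NON_GCB: 0.5},
            theta={c: {"CD10": 0.5} for c in (lc.GCB, lc.NON_GCB)},
            alpha=0.0,
            cutoffs={"CD10": 30.0},
        )
        assert lc.posterior(model, {"CD10": 90.0}) == pytest.approx(0.5)
        assert lc.classify_bayes(model, {"CD10": 90.0}) == lc.NON_GCB

    def test_joint_classifier_approaches_bayes_optimal_accuracy(self):
        """Train on data from a known 2-marker joint; compare test accuracy
        with the brute-force Bayes-optimal rule computed from the true
        joint (within 2 points at n=10,000)."""
        rng = np.random.default_rng(5)
        prior_g = 0.45
        joint = {
            lc.GCB: {(0, 0): 0.10, (0, 1): 0.15, (1, 0): 0.60, (1, 1): 0.15},
            lc.NON_GCB: {(0, 0): 0.40, (0, 1): 0.35, (1, 0): 0.05, (1, 1): 0.20},
        }

        def sample(n):
            rows_g, rows_n = [], []
            for _ in range(n):
                if rng.random() < prior_g:
                    patterns, probs = zip(*joint[lc.GCB].items())
                    rows_g.append(patterns[rng.choice(4, p=probs)])
                else:
                    patterns, probs = zip(*joint[lc.NON_GCB].items())
                    rows_n.append(patterns[rng.choice(4, p=probs)])
            return rows_g, rows_n

        train_g, train_n = sample(10_000)
        cohort = _cohort_from_flags(gcb_rows=train_g, non_rows=train_n)
        model = lc.fit_joint_bayes(cohort, (1, 5), alpha=0.0)

        # brute-force oracle: argmax over the TRUE joint, and its accuracy
        bayes_rule, bayes_acc = {}, 0.0
        for pattern in itertools.product((0, 1), repeat=2):
            pg = prior_g * joint[lc.GCB][pattern]
            pn = (1 - prior_g) * joint[lc.NON_GCB][pattern]
            bayes_rule[pattern] = lc.GCB if pg > pn else lc.NON_GCB
            bayes_acc += max(pg, pn)

        test_g, test_n = sample(10_000)
        correct = 0
        for pattern, label in [(p, lc.GCB) for p in test_g] + [
            (p, lc.NON_GCB) for p in test_n
        ]:
            profile = {"CD10": 90.0 * pattern[0], "MUM1": 90.0 * pattern[1]}
            if lc.classify_bayes(model, profile) == label:
                correct += 1
        acc = correct / (len(test_g) + len(test_n))
        assert abs(acc - bayes_acc) <= 0.02
        # and the fitted rule equals the oracle rule on every pattern
        for pattern, expected in bayes_rule.items():
            profile = {"CD10": 90.0 * pattern[0], "MUM1": 90.0 * pattern[1]}
            assert lc.classify_bayes(model, profile) == expected

    def test_sklearn_bernoulli_nb_cross_check(self, sim_cohort_475):
        from sklearn.naive_bayes import BernoulliNB

        cohort = sim_cohort_475
        combo = (1, 3, 4, 5)
        model = lc.fit_naive_bayes(cohort, combo, alpha=1.0)
        markers = model.markers
        X = (cohort.df[list(markers)].to_numpy(float) >= 30.0).astype(int)
        y = (cohort.truth == lc.GCB).to_numpy(int)
        sk = BernoulliNB(alpha=1.0).fit(X, y)
        sk_post = sk.predict_proba(X)[:, 1]
        mine = np.array(
            [lc.posterior(model, cohort.profile(i)) for i in range(len(cohort))]
        )
        assert np.allclose(mine, sk_post, atol=1e-9)


class TestVariantsAndPreset:
    def test_pv_preset_definition(self):
        spec = lc.pv_preset()
        assert spec.combination == (1, 3, 4, 5)
        assert 2 not in spec.combination  # BCL6 deliberately excluded
        assert spec.variant == "BS"

    def test_bs_failover_on_zero_counts_warns(self):
        cohort = _cohort_from_flags(
            gcb_rows=[(1, 0)] * 5, non_rows=[(0, 1)] * 5
        )
        with pytest.warns(UserWarning, match="alpha=0.5"):
            model = lc.fit_bayes_variant(cohort, (1, 5), "BS")
        assert model.alpha == 0.5

    def test_variant_dispatch(self, sim_cohort_475):
        b = lc.fit_bayes_variant(sim_cohort_475, (1, 5), "B")
        bn = lc.fit_bayes_variant(sim_cohort_475, (1, 5), "BN")
        assert isinstance(b, lc.JointBayesModel)
        assert isinstance(bn, lc.BernoulliNBModel) and bn.alpha == 1.0
        with pytest.raises(BayesError, match="variant"):
            lc.fit_bayes_variant(sim_cohort_475, (1, 5), "QDA")

    def test_model_json_round_trip(self, sim_cohort_475):
        for variant in ("B", "BN"):
            model = lc.fit_bayes_variant(sim_cohort_475, (1, 4, 5), variant)
            clone = model_from_json(model.to_json())
            profile = sim_cohort_475.profile(0)
            assert lc.posterior(clone, profile) == pytest.approx(
                lc.posterior(model, profile)
            )
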