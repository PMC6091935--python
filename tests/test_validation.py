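"""TPR / FPR / CCR identification under observed and latent truth."""

import itertools

import numpy as np
import pytest
from scipy.optimize import approx_fprime

from rrtvalid.designs import MisclassPair, RRTDesign, Technique
from rrtvalid.validation import (
    DiceGameValidationModel,
    GameOutcomeSample,
    ValidationAssumption,
    _components,
    _latent_stats,
    _observed_stats,
    bootstrap_se,
    delta_method_se,
    joint_mean_covariance,
    validate_latent_truth,
    validate_observed_truth,
)

DQ = RRTDesign(Technique.DQ)
CM = RRTDesign(Technique.CM, p_z=1 / 6)
WIN = 1.0 / 6.0


def make_groups(n_cheat, y_cheat, n_honest, y_honest):
    """Observed-truth sample: cheaters are claimers who did not win."""
    y = np.concatenate([np.ones(y_cheat), np.zeros(n_cheat - y_cheat),
                        np.ones(y_honest), np.zeros(n_honest - y_honest)])
    claim = np.concatenate([np.ones(n_cheat), np.zeros(n_honest)])
    truth = np.zeros(n_cheat + n_honest)
    return GameOutcomeSample(y, claim, DQ, truth=truth)


class TestObservedTruth:
    def test_all_honest_perfect_classification(self):
        sample = make_groups(10, 10, 90, 0)
        res = validate_observed_truth(sample)
        assert (res.tpr, res.fpr, res.ccr) == (1.0, 0.0, 1.0)

    def test_direct_counting_example(self):
        res = validate_observed_truth(make_groups(10, 7, 90, 0))
        assert res.tpr == pytest.approx(0.7)
        assert res.fpr == 0.0
        assert res.ccr == pytest.approx(0.7 * 0.1 + 1.0 * 0.9)
        assert res.cheat_rate == pytest.approx(0.1)

    def test_exhaustive_small_instances_match_brute_force(self):
        """Every valid DQ dataset of 4 respondents equals direct counting."""
        # per-respondent states: (x_star, x) in {(0,0),(0,1),(1,1)} x y
        states = [(xs, x, y) for (xs, x) in [(0, 0), (0, 1), (1, 1)] for y in (0, 1)]
        checked = 0
        for combo in itertools.product(states, repeat=4):
            arr = np.array(combo, dtype=float)
            xs, x, y = arr[:, 0], arr[:, 1], arr[:, 2]
            cheater = x != xs
            if not cheater.any() or cheater.all():
                continue
            res = validate_observed_truth(GameOutcomeSample(y, x, DQ, truth=xs))
            tpr = y[cheater].mean()
            fpr = y[~cheater].mean()
            w = cheater.mean()
            assert res.tpr == pytest.approx(tpr)
            assert res.fpr == pytest.approx(fpr)
            assert res.ccr == pytest.approx(tpr * w + (1 - fpr) * (1 - w))
            checked += 1
        assert checked > 500

    def test_empty_groups_rejected(self):
        y = np.array([1.0, 0.0]); claim = np.array([1.0, 1.0])
        with pytest.raises(ValueError, match="non-cheater"):
            validate_observed_truth(GameOutcomeSample(y, claim, DQ, truth=np.zeros(2)))
        with pytest.raises(ValueError, match="cheater"):
            validate_observed_truth(
                GameOutcomeSample(y, np.zeros(2), DQ, truth=np.zeros(2))
            )

    def test_missing_truth_rejected(self):
        sample = GameOutcomeSample(np.array([1.0, 0.0]), np.array([1.0, 0.0]), DQ)
        with pytest.raises(ValueError, match="truth"):
            validate_observed_truth(sample)

    def test_false_losers_rejected_at_construction(self):
        with pytest.raises(ValueError, match="false loser"):
            GameOutcomeSample(
                np.array([0.0, 0.0]),
                np.array([0.0, 1.0]),
                DQ,
                truth=np.array([1.0, 0.0]),
            )


def latent_sample(n_claim_yes, y_given_claim, n_claim_no, y_given_noclaim, design=DQ):
    y = np.concatenate(
        [
            np.ones(y_given_claim),
            np.zeros(n_claim_yes - y_given_claim),
            np.ones(y_given_noclaim),
            np.zeros(n_claim_no - y_given_noclaim),
        ]
    )
    claim = np.concatenate([np.ones(n_claim_yes), np.zeros(n_claim_no)])
    return GameOutcomeSample(y, claim, design)


class TestLatentTruth:
    def test_identification_formula_hand_example(self):
        # Pr(X=1) = 5/12, Pr(Y=1|X=1) = 0.22, Pr(Y=1|X=0) = 0.10
        sample = latent_sample(500, 110, 700, 70)
        res = validate_latent_truth(sample)
        assert res.cheat_rate == pytest.approx(5 / 12 - 1 / 6)
        assert res.fpr == pytest.approx(0.10)
        assert res.tpr == pytest.approx(
            (5 / 12 * 0.22 - 1 / 6 * 0.10) / 0.25, abs=1e-12
        )
        assert res.tpr == pytest.approx(0.30, abs=1e-12)
        assert res.ccr == pytest.approx(
            res.tpr * 0.25 + (1 - res.fpr) * (7 / 12 + 1 / 6)
        )

    def test_response_independent_of_claim_gives_tpr_equal_fpr(self):
        # common conditional response rate 0.2 in both claim groups
        sample = latent_sample(500, 100, 700, 140)
        res = validate_latent_truth(sample)
        assert res.tpr == pytest.approx(0.2)
        assert res.fpr == pytest.approx(0.2)

    def test_a2prime_reweights_losers_and_lowers_fpr(self):
        sample = latent_sample(500, 110, 700, 70)
        a2 = validate_latent_truth(sample, ValidationAssumption.A1_A2)
        a2p = validate_latent_truth(sample, ValidationAssumption.A1_A2PRIME)
        xbar = 5 / 12
        # winner mass removed: losers reweighted by (1-x)/(1-x+1/6)
        assert a2p.fpr == pytest.approx(a2.fpr * (1 - xbar) / (1 - xbar + WIN))
        assert a2p.fpr <= a2.fpr
        # dropping the (nonnegative) winner joint term raises the TPR
        assert a2p.tpr >= a2.tpr
        assert a2p.tpr == pytest.approx((xbar * 0.22) / 0.25)

    def test_a2prime_never_exceeds_a2_fpr_on_simulated_data(self, rng):
        for _ in range(25):
            n = 400
            claim = rng.random(n) < rng.uniform(0.3, 0.7)
            y = rng.random(n) < rng.uniform(0.05, 0.5)
            sample = GameOutcomeSample(
                y.astype(float), claim.astype(float), DQ
            )
            a2 = validate_latent_truth(sample, "A1_A2")
            a2p = validate_latent_truth(sample, "A1_A2prime")
            if a2.fpr >= 0:
                assert a2p.fpr <= a2.fpr + 1e-12

    def test_no_identifiable_cheating_mass(self):
        sample = latent_sample(100, 10, 900, 90)  # Pr(X=1)=0.1 < 1/6
        with pytest.raises(ValueError, match="no identifiable cheating mass"):
            validate_latent_truth(sample)

    def test_assumption_required_without_truth(self):
        sample = latent_sample(500, 110, 700, 70)
        model = DiceGameValidationModel.from_sample(sample)
        with pytest.raises(ValueError, match="assumption"):
            model.fit(assumption=None)


class TestTruncation:
    def test_negative_fpr_kept_raw_but_truncated_in_ccr(self):
        # FR-style data in which non-claimers' "yes" share sits below the
        # forced-yes floor -> negative inverted FPR
        fr = RRTDesign(Technique.FR, p_yes=1 / 6, p_no=1 / 6)
        sample = latent_sample(500, 200, 700, 70, design=fr)
        res = validate_latent_truth(sample)
        assert res.fpr < 0.0
        assert res.fpr_truncated
        xbar = 5 / 12
        expected_ccr = res.tpr * res.cheat_rate + 1.0 * (1 - xbar + WIN)
        assert res.ccr == pytest.approx(expected_ccr)

    def test_positive_fpr_not_flagged(self):
        res = validate_latent_truth(latent_sample(500, 110, 700, 70))
        assert not res.fpr_truncated


class TestDeltaMethod:
    def test_linear_statistic_matches_closed_form(self):
        """For DQ prevalence the delta SE equals the closed-form SE exactly."""
        y = np.concatenate([np.ones(13), np.zeros(27)])
        means, cov = joint_mean_covariance(y)
        se = delta_method_se(cov, np.array([[1.0]]))[0]
        ybar = y.mean()
        assert se == pytest.approx(np.sqrt(ybar * (1 - ybar) / (len(y) - 1)))

    @pytest.mark.parametrize("mode", ["observed", "A1_A2", "A1_A2prime"])
    @pytest.mark.parametrize("pair", [MisclassPair(1.0, 0.0), MisclassPair(1 / 6, 5 / 6)])
    def test_analytic_gradients_match_numerical(self, mode, pair):
        m0 = np.array([0.42, 0.11, 0.06])  # (group mean, joint means)

        def values(m):
            if mode == "observed":
                return _observed_stats(m, pair)[0]
            return _latent_stats(m, pair, WIN, mode == "A1_A2prime")[0]

        if mode == "observed":
            _, grads, _ = _observed_stats(m0, pair)
        else:
            _, grads, _ = _latent_stats(m0, pair, WIN, mode == "A1_A2prime")
        for i in range(4):
            num = approx_fprime(m0, lambda m: values(m)[i], 1e-7)
            assert grads[i] == pytest.approx(num, rel=1e-4, abs=1e-6)

    def test_delta_se_close_to_empirical_sd(self, rng):
        """Delta SEs track the Monte-Carlo SD of the latent-truth estimator."""
        n, reps = 2000, 400
        ests, ses = [], []
        for _ in range(reps):
            win = rng.random(n) < WIN
            cheat = (~win) & (rng.random(n) < 0.3)
            claim = (win | cheat).astype(float)
            p_yes = np.where(cheat, 0.3, 0.1)
            y = (rng.random(n) < p_yes).astype(float)
            res = validate_latent_truth(GameOutcomeSample(y, claim, DQ))
            ests.append([res.tpr, res.fpr, res.ccr, res.cheat_rate])
            ses.append([res.se_tpr, res.se_fpr, res.se_ccr, res.se_cheat_rate])
        emp = np.std(ests, axis=0, ddof=1)
        avg = np.mean(ses, axis=0)
        assert np.all(np.abs(avg / emp - 1.0) < 0.15)


class TestBootstrap:
    def test_deterministic_given_seed(self):
        sample = latent_sample(500, 110, 700, 70)
        a = bootstrap_se(sample, "A1_A2", B=300, seed=9)
        b = bootstrap_se(sample, "A1_A2", B=300, seed=9)
        assert a == b
        c = bootstrap_se(sample, "A1_A2", B=300, seed=10)
        assert c != a

    def test_zero_variance_data(self):
        sample = make_groups(10, 0, 30, 0)  # every response identical (0)
        boot = bootstrap_se(sample, assumption=None, B=200, seed=1)
        assert boot.se_tpr == 0.0 and boot.se_fpr == 0.0

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError, match="at least 200"):
            bootstrap_se(latent_sample(500, 110, 700, 70), "A1_A2", B=50)

    def test_model_fit_bootstrap_variance(self):
        sample = latent_sample(500, 110, 700, 70)
        res = DiceGameValidationModel.from_sample(sample).fit(
            assumption="A1_A2", variance="bootstrap", n_boot=300, seed=5
        )
        assert res.variance_method == "bootstrap" and res.n_boot == 300
        assert res.se_tpr > 0

    def test_degenerate_resamples_redrawn_with_warning(self, rng):
        # Pr(X=1) barely above 1/6: many resamples cross the boundary
        claim = (rng.random(300) < 0.19).astype(float)
        y = (rng.random(300) < 0.1).astype(float)
        sample = GameOutcomeSample(y, claim, DQ)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            boot = bootstrap_se(sample, "A1_A2", B=200, seed=3)
        assert boot.n_redraws > 0


def test_latent_agrees_with_observed_truth_on_a1_a2_population(rng):
    """Headline oracle-equivalence check on one simulated prediction game."""
    n = 40_000
    win = rng.random(n) < WIN
    cheat = (~win) & (rng.random(n) < 0.3)
    claim = (win | cheat).astype(float)
    p_yes = np.where(cheat, 0.3, 0.1)
    y = (rng.random(n) < p_yes).astype(float)
    latent = validate_latent_truth(GameOutcomeSample(y, claim, DQ))
    observed = validate_observed_truth(
        GameOutcomeSample(y, claim, DQ, truth=win.astype(float))
    )
    assert latent.tpr == pytest.approx(observed.tpr, abs=3 * latent.se_tpr)
    assert latent.fpr == pytest.approx(observed.fpr, abs=3 * max(latent.se_fpr, 1e-3))
    assert latent.ccr == pytest.approx(observed.ccr, abs=3 * latent.se_ccr)
    assert latent.tpr == pytest.approx(0.3, abs=3 * latent.se_tpr)
    assert latent.fpr == pytest.approx(0.1, abs=3 * latent.se_fpr)


def test_summary_reports_truncation_and_assumption():
    fr = RRTDesign(Technique.FR, p_yes=1 / 6, p_no=1 / 6)
    res = validate_latent_truth(latent_sample(500, 200, 700, 70, design=fr))
    text = res.summary()
    assert "A1_A2" in text and "truncated" in text
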