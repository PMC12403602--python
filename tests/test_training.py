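"""Risk estimators and the weak-supervision training loop."""

import math

import numpy as np
import pytest

from minsupre import (
    FeatureGenConfig,
    LossConfig,
    PriorConfig,
    TeacherConfig,
    TrainConfig,
    binary_biased_risk,
    fit,
    gen_feature_corpus,
    generate_pairwise,
    logistic_loss,
    noisy_unbiased_risk,
    pcomp_corrected_risk,
    pcomp_teacher_fit,
    pcomp_unbiased_risk,
    rank_pruning_fit,
    split_pointwise,
    supervised_risk,
    train,
)
from minsupre.weak import derive_noise_rates

LN2 = math.log(2)


class TestLogisticLoss:
    def test_symmetry_point(self):
        assert logistic_loss(0.0, +1) == pytest.approx(LN2)
        assert logistic_loss(0.0, -1) == pytest.approx(LN2)

    def test_overflow_safe_both_tails(self):
        assert logistic_loss(100.0, +1) == pytest.approx(0.0, abs=1e-40)
        assert logistic_loss(-100.0, +1) == pytest.approx(100.0, rel=1e-12)
        assert logistic_loss(1000.0, -1) == pytest.approx(1000.0, rel=1e-12)

    def test_vectorized_matches_scalar(self, rng):
        z = rng.standard_normal(50) * 5
        vec = logistic_loss(z, +1)
        assert np.allclose(vec, [logistic_loss(float(x), +1) for x in z])


class TestRisks:
    def test_supervised_at_zero_scores(self, rng):
        labels = rng.choice([1, -1], size=20)
        assert supervised_risk(np.zeros(20), labels) == pytest.approx(LN2)

    def test_supervised_vanishes_at_large_margin(self):
        labels = np.array([1, -1, 1])
        scores = labels * 50.0
        assert supervised_risk(scores, labels) < 1e-20

    def test_supervised_decomposes_by_class(self, rng):
        scores = rng.standard_normal(200)
        labels = rng.choice([1, -1], size=200)
        pos, neg = scores[labels == 1], scores[labels == -1]
        decomposed = (len(pos) * logistic_loss(pos, +1).mean()
                      + len(neg) * logistic_loss(neg, -1).mean()) / 200
        assert supervised_risk(scores, labels) == pytest.approx(decomposed)

    def test_binary_biased_equals_supervised_on_clean_sets(self, rng):
        pos = rng.standard_normal(80)
        neg = rng.standard_normal(120)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(80, dtype=int), -np.ones(120, dtype=int)])
        assert binary_biased_risk(pos, neg) == pytest.approx(supervised_risk(scores, labels))

    def test_pcomp_unbiased_hand_case(self):
        assert pcomp_unbiased_risk(np.zeros(1), np.zeros(1), PriorConfig(0.5)) == pytest.approx(LN2)

    def test_pcomp_corrected_abs_hand_case(self):
        got = pcomp_corrected_risk(np.zeros(1), np.zeros(1), PriorConfig(0.5), "abs")
        assert got == pytest.approx(LN2)

    def test_identity_correction_equals_unbiased(self, rng):
        """The corrected estimator with g = identity is an exact rearrangement."""
        for _ in range(200):
            n = int(rng.integers(1, 50))
            zp = rng.standard_normal(n) * 3
            zn = rng.standard_normal(n) * 3
            prior = PriorConfig(float(rng.uniform(0.05, 0.95)))
            a = pcomp_unbiased_risk(zp, zn, prior)
            b = pcomp_corrected_risk(zp, zn, prior, "identity")
            assert abs(a - b) < 1e-12

    def test_relu_clamps_negative_bracket(self):
        # large correctly-signed margins make both brackets negative
        zp = np.full(10, 50.0)
        zn = np.full(10, -50.0)
        prior = PriorConfig(0.5)
        assert pcomp_unbiased_risk(zp, zn, prior) < 0
        assert pcomp_corrected_risk(zp, zn, prior, "relu") == 0.0
        assert pcomp_corrected_risk(zp, zn, prior, "abs") >= 0.0

    def test_corrected_nonnegative_on_random_inputs(self, rng):
        for _ in range(100):
            zp = rng.standard_normal(20) * 5
            zn = rng.standard_normal(20) * 5
            prior = PriorConfig(float(rng.uniform(0.1, 0.9)))
            assert pcomp_corrected_risk(zp, zn, prior, "relu") >= 0
            assert pcomp_corrected_risk(zp, zn, prior, "abs") >= 0

    def test_noisy_unbiased_at_zero_scores_balanced(self):
        # symmetric rates: the correction cancels and the value is ln 2
        got = noisy_unbiased_risk(np.zeros(10), np.zeros(10), PriorConfig(0.5))
        assert got == pytest.approx(LN2)

    def test_noisy_collapses_to_binary_when_noise_free(self, rng):
        zp, zn = rng.standard_normal(30), rng.standard_normal(30)
        got = noisy_unbiased_risk(zp, zn, PriorConfig(0.5), noise_rates=(0.0, 0.0))
        assert got == pytest.approx(binary_biased_risk(zp, zn), rel=1e-12)

    def test_noise_rates_near_one_are_unidentifiable(self, rng):
        # as pi+ -> 1, rho- -> 1 and the correction blows up before that
        with pytest.raises(ValueError, match="unidentifiable"):
            noisy_unbiased_risk(rng.standard_normal(5), rng.standard_normal(5),
                                PriorConfig(0.5), noise_rates=(0.6, 0.5))

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pcomp_unbiased_risk(np.zeros(3), np.zeros(4), PriorConfig(0.5))


def _mixture_scores(prior, n, rng, scorer_w=(1.0,), scorer_b=0.0, mu=2.0):
    """Scores of a fixed linear scorer on data drawn exactly from the
    pairwise pointwise mixtures of two 1-D Gaussians N(±mu, 1)."""
    from minsupre.weak import mixture_weights

    wpp, _, wmp, _ = mixture_weights(prior)
    w = float(np.asarray(scorer_w)[0])

    def sample(frac_pos):
        is_pos = rng.random(n) < frac_pos
        x = rng.standard_normal(n) + np.where(is_pos, mu, -mu)
        return w * x + scorer_b

    return sample(wpp), sample(wmp)


def _true_risk(prior, scorer_w=(1.0,), scorer_b=0.0, mu=2.0):
    """Clean classification risk of the fixed scorer by Gaussian quadrature."""
    from scipy.integrate import quad

    w = float(np.asarray(scorer_w)[0])

    def phi(x, m):
        return math.exp(-((x - m) ** 2) / 2) / math.sqrt(2 * math.pi)

    lp = quad(lambda x: math.log1p(math.exp(-(w * x + scorer_b))) * phi(x, mu), -30, 30)[0]
    lm = quad(lambda x: math.log1p(math.exp(w * x + scorer_b)) * phi(x, -mu), -30, 30)[0]
    return prior.pi_plus * lp + prior.pi_minus * lm


class TestEstimatorConsistency:
    def test_pcomp_unbiased_converges_to_clean_risk(self):
        rng = np.random.default_rng(42)
        prior = PriorConfig(0.5)
        target = _true_risk(prior)
        zp, zn = _mixture_scores(prior, 100_000, rng)
        assert abs(pcomp_unbiased_risk(zp, zn, prior) - target) < 0.01

    def test_noisy_unbiased_converges_to_clean_risk(self):
        rng = np.random.default_rng(43)
        prior = PriorConfig(0.5)
        target = _true_risk(prior)
        zp, zn = _mixture_scores(prior, 100_000, rng)
        assert abs(noisy_unbiased_risk(zp, zn, prior) - target) < 0.01

    def test_root_n_decay(self):
        """|estimate - truth| shrinks like n^{-1/2} (log-log slope -0.5±0.1)."""
        rng = np.random.default_rng(7)
        prior = PriorConfig(0.5)
        target = _true_risk(prior)
        sizes = [1_000, 10_000, 100_000]
        reps = {1_000: 60, 10_000: 30, 100_000: 12}
        means = []
        for n in sizes:
            diffs = []
            for _ in range(reps[n]):
                zp, zn = _mixture_scores(prior, n, rng)
                diffs.append(abs(pcomp_unbiased_risk(zp, zn, prior) - target))
            means.append(np.mean(diffs))
        slope = np.polyfit(np.log(sizes), np.log(means), 1)[0]
        assert -0.6 <= slope <= -0.4


def godag_features(n_pairs, pi, seed, n_inst=8000, sep=4.0):
    cfg = FeatureGenConfig(
        n=n_inst, pi_plus=pi,
        mu_plus=(sep / 2, 0.0), mu_minus=(-sep / 2, 0.0), sigma=1.0, seed=seed,
    )
    fc = gen_feature_corpus(cfg)
    ids = [str(i) for i in range(n_inst)]
    pt = split_pointwise(generate_pairwise(ids, fc.y, n_pairs, seed + 1))
    Xp = fc.X[[int(i) for i in pt.d_plus]]
    Xn = fc.X[[int(i) for i in pt.d_minus]]
    return fc, Xp, Xn


class TestTraining:
    def test_supervised_separable_reaches_high_dev_f1(self):
        fc = gen_feature_corpus(FeatureGenConfig(n=2000, seed=0))
        Xp, Xn = fc.X[fc.y == 1], fc.X[fc.y == -1]
        model = train(Xp, Xn, LossConfig("binary_biased"), TrainConfig(seed=0))
        assert max(h["dev_metric"] for h in model.history) >= 0.95

    def test_pcomp_unbiased_recovers_boundary(self):
        accs = []
        for seed in range(3):
            fc, Xp, Xn = godag_features(2000, 0.5, seed * 10)
            model = train(Xp, Xn, LossConfig("pcomp_unbiased", PriorConfig(0.5)),
                          TrainConfig(seed=seed))
            accs.append(float((model.predict(fc.X) == fc.y).mean()))
        assert np.median(accs) >= 0.9

    def test_zero_epochs_returns_initialization(self):
        fc = gen_feature_corpus(FeatureGenConfig(n=100, seed=1))
        model = train(fc.X[fc.y == 1], fc.X[fc.y == -1],
                      LossConfig("binary_biased"), TrainConfig(epochs=0, seed=0))
        assert model.history == []
        assert model.best_epoch == -1
        assert np.allclose(model.best_params["w"], 0)

    def test_seed_determinism(self):
        fc, Xp, Xn = godag_features(500, 0.5, 3)
        cfg = TrainConfig(epochs=5, seed=4)
        a = train(Xp, Xn, LossConfig("pcomp_relu", PriorConfig(0.5)), cfg)
        b = train(Xp, Xn, LossConfig("pcomp_relu", PriorConfig(0.5)), cfg)
        assert a.history == b.history
        assert np.array_equal(a.best_params["w"], b.best_params["w"])

    def test_best_epoch_is_argmax_of_history(self):
        fc, Xp, Xn = godag_features(500, 0.5, 5)
        model = train(Xp, Xn, LossConfig("binary_biased"), TrainConfig(epochs=10, seed=0))
        best = max(model.history, key=lambda h: h["dev_metric"])
        assert model.history[model.best_epoch]["dev_metric"] == best["dev_metric"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            LossConfig("made_up")


class TestRankPruning:
    def test_no_noise_means_no_pruning(self):
        fc = gen_feature_corpus(FeatureGenConfig(n=600, seed=2))
        Xp, Xn = fc.X[fc.y == 1], fc.X[fc.y == -1]
        model = rank_pruning_fit(Xp, Xn, PriorConfig(0.5), TrainConfig(epochs=5, seed=0),
                                 noise_rates=(0.0, 0.0))
        assert model.extras["pruned_pos"].size == 0
        assert model.extras["pruned_neg"].size == 0

    def test_prunes_exactly_the_planted_contaminants(self):
        """With widely separated classes the pruned instances are the true
        contaminants implied by the mixture (1/3 of each set at pi=0.5)."""
        rng = np.random.default_rng(0)
        n = 900
        # build noisy sets explicitly: 2/3 clean, 1/3 flipped, far apart
        pos_true = rng.standard_normal((600, 2)) + [6, 0]
        pos_noise = rng.standard_normal((300, 2)) + [-6, 0]
        neg_true = rng.standard_normal((600, 2)) + [-6, 0]
        neg_noise = rng.standard_normal((300, 2)) + [6, 0]
        Xp = np.vstack([pos_true, pos_noise])
        Xn = np.vstack([neg_true, neg_noise])
        model = rank_pruning_fit(Xp, Xn, PriorConfig(0.5), TrainConfig(epochs=15, seed=1))
        assert set(model.extras["pruned_pos"].tolist()) == set(range(600, 900))
        assert set(model.extras["pruned_neg"].tolist()) == set(range(600, 900))

    def test_pruning_fraction_matches_mixture_noise(self):
        fc, Xp, Xn = godag_features(900, 0.5, 21)
        model = rank_pruning_fit(Xp, Xn, PriorConfig(0.5), TrainConfig(epochs=5, seed=0))
        rho_p, rho_m = derive_noise_rates(PriorConfig(0.5))
        assert model.extras["pruned_pos"].size == round(rho_p * 900)
        assert model.extras["pruned_neg"].size == round(rho_m * 900)


class TestTeacher:
    def test_ema_trace_matches_hand_rolled(self):
        fc, Xp, Xn = godag_features(300, 0.5, 8)
        cfg = TrainConfig(epochs=3, batch_size=64, seed=2)
        tc = TeacherConfig(ema_decay=0.9, consistency_weight=0.5, perturbation_scale=0.1)
        model = pcomp_teacher_fit(Xp, Xn, PriorConfig(0.5), cfg, tc)
        # the teacher must lag the student: it is a convex combination of
        # past student iterates, so its norm is below the final student's
        w_s = np.linalg.norm(model.params["w"])
        w_t = np.linalg.norm(model.extras["teacher"]["w"])
        assert 0 < w_t < w_s

    def test_ema_recursion_explicitly(self):
        # one-parameter check of the update theta_t <- a theta_t + (1-a) theta_s
        a = 0.9
        teacher, trace = 0.0, []
        students = [1.0, 2.0, 3.0, 4.0]
        for s in students:
            teacher = a * teacher + (1 - a) * s
            trace.append(teacher)
        assert trace[-1] == pytest.approx(
            sum((1 - a) * a ** (len(students) - 1 - k) * s for k, s in enumerate(students))
        )

    def test_invalid_ema_decay(self):
        with pytest.raises(ValueError):
            TeacherConfig(ema_decay=1.0)

    def test_learns_the_boundary(self):
        fc, Xp, Xn = godag_features(1000, 0.5, 9)
        model = pcomp_teacher_fit(Xp, Xn, PriorConfig(0.5), TrainConfig(epochs=20, seed=3))
        acc = float((model.predict(fc.X) == fc.y).mean())
        assert acc >= 0.9


class TestDispatch:
    @pytest.mark.parametrize("method", [
        "binary_biased", "noisy_unbiased", "pcomp_unbiased",
        "pcomp_relu", "pcomp_abs", "rank_pruning", "pcomp_teacher",
    ])
    def test_every_method_trains_and_predicts(self, method):
        fc, Xp, Xn = godag_features(400, 0.5, 31)
        model = fit(Xp, Xn, LossConfig(method, PriorConfig(0.5)), TrainConfig(epochs=5, seed=0))
        pred = model.predict(fc.X[:50])
        assert set(np.unique(pred)).issubset({1, -1})
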