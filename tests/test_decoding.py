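import numpy as np
import pytest
from scipy import optimize

from neurosig.decoding import (
    CVResult,
    binomial_p,
    exclude_voxels,
    forced_choice,
    loso_cv,
    roc,
    threshold_report,
    train_signature,
)
from neurosig.volume_core import ValidationError


def svm_dual_oracle(X, y, C):
    """Independent brute-force solve of the linear C-SVM dual by SLSQP.

    max sum(a) - 0.5 a^T (yy^T * XX^T) a  s.t. 0 <= a <= C, sum(a y) = 0;
    weights = sum a_i y_i x_i; intercept from margin support vectors.
    """
    n = len(y)
    K = (X @ X.T) * np.outer(y, y)
    fun = lambda a: -(a.sum() - 0.5 * a @ K @ a)
    jac = lambda a: -(np.ones(n) - K @ a)
    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y.astype(float)}]
    res = optimize.minimize(
        fun,
        np.full(n, C / 2),
        jac=jac,
        bounds=[(0, C)] * n,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    a = res.x
    w = (a * y) @ X
    on_margin = (a > 1e-6 * C) & (a < C * (1 - 1e-6))
    sv = on_margin if on_margin.any() else a > 1e-6 * C
    b = np.mean(y[sv] - X[sv] @ w)
    return w, b


class TestTrainSignature:
    def test_separable_toy_all_training_decisions_correct(self):
        paired = {
            "s1": (np.array([2.0, 0.1]), np.array([-2.0, 0.0])),
            "s2": (np.array([1.8, -0.2]), np.array([-1.7, 0.3])),
            "s3": (np.array([2.2, 0.0]), np.array([-2.1, -0.1])),
        }
        m = train_signature(paired, "pair")
        for tgt, ctl in paired.values():
            assert m.decision(tgt) > 0
            assert m.decision(ctl) < 0

    def test_duplicating_observations_keeps_boundary(self):
        rng = np.random.default_rng(2)
        paired = {
            f"s{i}": (rng.normal(1, 1, 3), rng.normal(-1, 1, 3)) for i in range(5)
        }
        doubled = dict(paired)
        doubled.update({f"d{i}": v for i, v in enumerate(paired.values())})
        m1 = train_signature(paired, "p")
        m2 = train_signature(doubled, "p")
        assert np.allclose(m1.weights, m2.weights, atol=1e-5)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-5)

    @pytest.mark.parametrize("C", [0.5, 1.0, 4.0])
    def test_matches_brute_force_qp_on_small_instance(self, C):
        rng = np.random.default_rng(7)
        paired = {
            "s1": (np.array([1.4, 0.3]), np.array([-1.0, 0.2])),
            "s2": (np.array([0.8, -0.5]), np.array([-0.6, 0.9])),
        }
        m = train_signature(paired, "p", regularization=C)
        X = np.array([v for pair in paired.values() for v in pair])
        y = np.array([1, -1, 1, -1])
        w, b = svm_dual_oracle(X, y, C)
        assert np.allclose(m.weights, w, atol=1e-4)
        assert m.intercept == pytest.approx(b, abs=1e-4)

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError):
            train_signature({"s1": (np.ones(2), -np.ones(2))}, "p")


class TestLOSO:
    def test_noiseless_separable_cohort_perfect(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(20)
        paired = {f"s{i}": (u * (1 + 0.1 * i), -u * (1 + 0.1 * i)) for i in range(6)}
        cv = loso_cv(paired, "p")
        rep = threshold_report(cv)
        assert rep.accuracy == 1.0

    def test_three_subjects_bookkeeping(self):
        rng = np.random.default_rng(1)
        paired = {f"s{i}": (rng.normal(1, 1, 4), rng.normal(-1, 1, 4)) for i in range(3)}
        cv = loso_cv(paired, "p")
        assert len(cv.decisions) == 3
        assert sum(len(v) for v in cv.decisions.values()) == 6

    def test_permuted_labels_near_chance(self):
        """Swapping target/control at random within training folds destroys
        the signal: held-out accuracy falls to chance within binomial noise."""
        rng = np.random.default_rng(3)
        u = rng.standard_normal(50)
        paired = {}
        for i in range(40):
            tgt = 2 * u + rng.standard_normal(50)
            ctl = -2 * u + rng.standard_normal(50)
            if rng.random() < 0.5:
                tgt, ctl = ctl, tgt  # label permutation
            paired[f"s{i}"] = (tgt, ctl)
        cv = loso_cv(paired, "p")
        rep = threshold_report(cv)
        assert abs(rep.accuracy - 0.5) < 0.2

    def test_no_leakage_fold_model_ignores_test_subject(self):
        """Each fold's decisions must equal those of a model trained with the
        held-out subject entirely absent."""
        rng = np.random.default_rng(4)
        u = rng.standard_normal(10)
        paired = {
            f"s{i}": (u + rng.normal(0, 0.3, 10), -u + rng.normal(0, 0.3, 10))
            for i in range(5)
        }
        cv = loso_cv(paired, "p")
        for sid in paired:
            others = {s: v for s, v in paired.items() if s != sid}
            m = train_signature(others, "p")
            tgt, ctl = paired[sid]
            assert cv.decisions[sid][0] == pytest.approx(m.decision(tgt))
            assert cv.decisions[sid][1] == pytest.approx(m.decision(ctl))
            # corrupting the held-out subject cannot move its fold's model
            corrupted = dict(others)
            assert train_signature(corrupted, "p").intercept == m.intercept


class TestReports:
    def test_all_correct_closed_form_p(self):
        decisions = {f"s{i}": (1.0, -1.0) for i in range(5)}
        cv = CVResult(list(decisions), decisions, "p")
        rep = threshold_report(cv)
        assert rep.accuracy == 1.0
        assert rep.p_value == pytest.approx(0.5**10, rel=1e-12)

    def test_tie_at_threshold_counted_incorrect(self):
        decisions = {"s1": (0.0, 0.0)}  # target at threshold -> wrong;
        cv = CVResult(["s1"], decisions, "p")
        rep = threshold_report(cv)
        # control at threshold -> correct (classified -1)
        assert rep.accuracy == 0.5
        assert rep.sensitivity == 0.0
        assert rep.specificity == 1.0

    def test_sensitivity_specificity_definitions(self):
        decisions = {"s1": (1.0, 1.0), "s2": (-1.0, -1.0)}
        cv = CVResult(["s1", "s2"], decisions, "p")
        rep = threshold_report(cv)
        assert rep.sensitivity == 0.5  # one of two targets above threshold
        assert rep.specificity == 0.5  # one of two controls at/below

    def test_binomial_conventions(self):
        p_one, p_two = binomial_p(33, 33)
        assert p_one == pytest.approx(0.5**33, rel=1e-12)
        assert p_two == pytest.approx(2 * 0.5**33, rel=1e-12)


class TestForcedChoice:
    def _model(self, w, b=3.7):
        from neurosig.decoding import SignatureModel

        return SignatureModel(np.asarray(w, float), b, "p")

    def test_perfect_accuracy_closed_form_p(self):
        m = self._model([1.0, 0.0])
        paired = {f"s{i}": (np.array([1.0, 0.0]), np.array([0.0, 0.0])) for i in range(33)}
        rep = forced_choice(m, paired)
        assert rep.accuracy == 1.0
        assert rep.n_comparisons == 33
        assert rep.p_value == pytest.approx(0.5**33, rel=1e-12)
        assert rep.p_value_doubled == pytest.approx(2.33e-10, rel=0.01)

    def test_constant_shift_invariance(self):
        m = self._model([2.0, -1.0])
        rng = np.random.default_rng(0)
        paired = {f"s{i}": (rng.standard_normal(2), rng.standard_normal(2)) for i in range(10)}
        shifted = {s: (t + 42.0, c + 42.0) for s, (t, c) in paired.items()}
        assert forced_choice(m, paired).accuracy == forced_choice(m, shifted).accuracy

    def test_equal_expressions_incorrect(self):
        m = self._model([1.0])
        rep = forced_choice(m, {"s1": (np.array([2.0]), np.array([2.0]))})
        assert rep.accuracy == 0.0

    def test_single_subject_smallest_case(self):
        m = self._model([1.0])
        rep = forced_choice(m, {"s1": (np.array([1.0]), np.array([0.0]))})
        assert rep.n_comparisons == 1
        assert rep.p_value == pytest.approx(0.5)

    def test_mask_fingerprint_mismatch(self):
        from neurosig.decoding import SignatureModel

        m = SignatureModel(np.ones(2), 0.0, "p", mask_fingerprint="abc")
        with pytest.raises(ValidationError):
            forced_choice(m, {"s": (np.ones(2), np.zeros(2))}, mask_fingerprint="xyz")


class TestExcludeVoxels:
    def test_empty_drop_identity(self):
        from neurosig.decoding import SignatureModel

        m = SignatureModel(np.array([1.0, -2.0]), 0.5, "p")
        m2 = exclude_voxels(m, np.zeros(2, dtype=bool))
        assert np.array_equal(m2.weights, m.weights)
        assert m2.intercept == m.intercept

    def test_expressions_independent_of_dropped_voxels(self):
        from neurosig.decoding import SignatureModel

        rng = np.random.default_rng(5)
        m = SignatureModel(rng.standard_normal(10), 0.0, "p")
        drop = np.zeros(10, dtype=bool)
        drop[:4] = True
        m2 = exclude_voxels(m, drop)
        x = rng.standard_normal(10)
        x_pert = x.copy()
        x_pert[:4] += 1e3
        assert m2.expression(x) == pytest.approx(m2.expression(x_pert))

    def test_dropping_signal_region_kills_accuracy(self, tiny_cohort):
        pair = "NV_vs_NeutV"
        paired = tiny_cohort.paired(pair)
        model = train_signature(paired, pair)
        gt = tiny_cohort.ground_truth[pair]
        drop = np.abs(gt) > 0.01 * np.abs(gt).max()
        if drop.all():
            drop[::7] = False
        m2 = exclude_voxels(model, drop)
        rep = forced_choice(m2, paired)
        assert rep.accuracy < 0.85  # signal carried by the dropped blob

    def test_all_dropped_degenerate(self):
        from neurosig.decoding import SignatureModel

        m = SignatureModel(np.ones(3), 0.0, "p")
        with pytest.raises(ValidationError):
            exclude_voxels(m, np.ones(3, dtype=bool))


class TestROC:
    def test_perfect_separation_auc_one(self):
        decisions = {f"s{i}": (1.0 + i, -1.0 - i) for i in range(4)}
        cv = CVResult(list(decisions), decisions, "p")
        _, _, auc = roc(cv)
        assert auc == 1.0

    def test_auc_equals_pair_count_probability(self):
        decisions = {"s1": (0.9, 0.1), "s2": (0.4, 0.6)}
        cv = CVResult(list(decisions), decisions, "p")
        _, _, auc = roc(cv)
        # targets {0.9, 0.4}, controls {0.1, 0.6}: 3 of 4 pairs ordered
        assert auc == pytest.approx(0.75)

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(8)
        decisions = {f"s{i}": tuple(rng.standard_normal(2)) for i in range(200)}
        cv = CVResult(list(decisions), decisions, "p")
        _, _, auc = roc(cv)
        assert abs(auc - 0.5) < 0.08
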