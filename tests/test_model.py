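"""Bag scoring, the weak-supervision loss, staging and patient inference."""

import numpy as np
import pytest

from wisdom import (
    BagScores,
    ConfigurationError,
    FeatureContractError,
    Stage,
    TargetError,
    WeakSupervisionTargets,
    WisdomConfig,
    WisdomModel,
    count_to_stage,
    predict_patient,
    score_bag,
    weak_supervision_loss,
)
from wisdom.model import _bag_loss_grad, _logit, _youden_threshold


class TestCountToStage:
    @pytest.mark.parametrize(
        "k,stage",
        [(0, Stage.N0), (1, Stage.N1), (2, Stage.N1), (3, Stage.N1),
         (4, Stage.N2), (10, Stage.N2), (35, Stage.N2)],
    )
    def test_staging_map(self, k, stage):
        assert count_to_stage(k) == stage

    def test_monotone_partition(self):
        stages = [count_to_stage(k).index for k in range(40)]
        assert stages == sorted(stages)
        assert set(stages) == {0, 1, 2}

    @pytest.mark.parametrize("bad", [-1, 2.5, True])
    def test_domain_errors(self, bad):
        with pytest.raises(ConfigurationError):
            count_to_stage(bad)


class TestBagScores:
    def test_pooling_identities(self, rng):
        probs = rng.random(9)
        s = BagScores.from_probs(probs)
        assert s.p_max == probs.max()
        assert s.p_avg == pytest.approx(probs.mean())
        assert s.p_avg <= s.p_max

    def test_single_node(self):
        s = BagScores.from_probs([0.42])
        assert s.p_max == s.p_avg == 0.42

    def test_out_of_range_rejected(self):
        with pytest.raises(TargetError):
            BagScores.from_probs([0.5, 1.2])


class TestWeakSupervisionTargets:
    def test_negative_patient_zero_rho(self):
        with pytest.raises(TargetError):
            WeakSupervisionTargets(y=0, rho=0.2)

    def test_rho_bounds(self):
        with pytest.raises(TargetError):
            WeakSupervisionTargets(y=1, rho=1.3)


class TestWeakSupervisionLoss:
    def test_mil_only_closed_form(self):
        s = BagScores.from_probs([0.5])
        t = WeakSupervisionTargets(y=1, rho=1.0)
        loss = weak_supervision_loss(s, t, lambda_mil=1.0, lambda_llp=0.0)
        assert loss == pytest.approx(np.log(2.0), abs=1e-9)

    def test_minimum_at_targets(self):
        """When p_max = y and p_avg = rho, the loss equals lambda_llp times
        the entropy of rho (the analytic minimum of soft-target BCE)."""
        rho = 0.3
        probs = np.array([1.0 - 1e-7, rho * 2 - 1 + 1e-7])  # p_max ~ 1, p_avg ~ rho
        probs = np.clip(probs, 0, 1)
        s = BagScores.from_probs(probs)
        t = WeakSupervisionTargets(y=1, rho=s.p_avg)
        entropy = -(t.rho * np.log(t.rho) + (1 - t.rho) * np.log(1 - t.rho))
        loss = weak_supervision_loss(s, t, 1.0, 1.0)
        assert loss == pytest.approx(entropy, abs=1e-5)

    def test_hand_computed_example(self):
        """lambda_mil = lambda_llp = 1, p_max=0.8, y=1, p_avg=0.2, rho=0.1."""
        s = BagScores(probs=np.array([0.8, 0.2]), p_max=0.8, p_avg=0.2)
        t = WeakSupervisionTargets(y=1, rho=0.1)
        expected = -np.log(0.8) - (0.1 * np.log(0.2) + 0.9 * np.log(0.8))
        assert weak_supervision_loss(s, t, 1.0, 1.0) == pytest.approx(expected)

    def test_weights_not_both_zero(self):
        s = BagScores.from_probs([0.5])
        t = WeakSupervisionTargets(y=1, rho=0.5)
        with pytest.raises(ConfigurationError):
            weak_supervision_loss(s, t, 0.0, 0.0)

    def test_mse_proportion_head(self):
        s = BagScores(probs=np.array([0.6, 0.2]), p_max=0.6, p_avg=0.4)
        t = WeakSupervisionTargets(y=1, rho=0.1)
        loss = weak_supervision_loss(s, t, 0.0, 2.0, proportion_loss="mse")
        assert loss == pytest.approx(2.0 * 0.09)

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(0)
        probs = rng.uniform(0.05, 0.95, 6)
        z = _logit(probs)
        for prop in ("bce", "mse"):
            _, dz = _bag_loss_grad(probs, 1.0, 0.3, 1.0, 1.0, prop)
            for i in range(6):
                eps = 1e-6
                zp, zm = z.copy(), z.copy()
                zp[i] += eps
                zm[i] -= eps
                pp = 1 / (1 + np.exp(-zp))
                pm = 1 / (1 + np.exp(-zm))
                lp, _ = _bag_loss_grad(pp, 1.0, 0.3, 1.0, 1.0, prop)
                lm, _ = _bag_loss_grad(pm, 1.0, 0.3, 1.0, 1.0, prop)
                assert dz[i] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)

    def test_permutation_invariance(self, rng):
        probs = rng.uniform(0.1, 0.9, 8)
        t = WeakSupervisionTargets(y=1, rho=0.25)
        l1 = weak_supervision_loss(BagScores.from_probs(probs), t)
        l2 = weak_supervision_loss(BagScores.from_probs(probs[::-1].copy()), t)
        assert l1 == pytest.approx(l2)


class TestScoring:
    def test_score_bag_contracts(self, quick_model, small_cohort):
        bag = small_cohort[0]
        s1 = score_bag(quick_model, bag)
        s2 = quick_model.score_bag(bag)
        assert len(s1.probs) == len(bag.nodes)
        np.testing.assert_array_equal(s1.probs, s2.probs)  # deterministic
        assert s1.p_avg <= s1.p_max

    def test_duplicated_node_moves_average_not_max(self, quick_model, small_cohort):
        import copy

        bag = copy.deepcopy(small_cohort[1])
        s0 = quick_model.score_bag(bag)
        i_max = int(np.argmax(s0.probs))
        i_dup = int(np.argmin(s0.probs))
        bag.nodes.append(copy.deepcopy(bag.nodes[i_dup]))
        s1 = quick_model.score_bag(bag)
        assert s1.p_max == pytest.approx(s0.p_max, abs=1e-6)
        n = len(s0.probs)
        expected_avg = (s0.p_avg * n + s0.probs[i_dup]) / (n + 1)
        assert s1.p_avg == pytest.approx(expected_avg, abs=1e-6)

    def test_predict_patient_hand_rule(self, quick_model, small_cohort):
        probs, k_hat, score, stage = predict_patient(quick_model, small_cohort[2])
        tau = quick_model.tau
        assert k_hat == int((probs >= tau).sum())
        assert score == probs.max()
        assert stage == count_to_stage(k_hat)

    def test_threshold_monotonicity(self, quick_model, small_cohort):
        probs = quick_model.score_bag(small_cohort[3]).probs
        ks = [int((probs >= tau).sum()) for tau in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert ks == sorted(ks, reverse=True)

    def test_identity_fusion_reproduces_intensity_scores(self, quick_model,
                                                         small_cohort):
        """A fusion perceptron forced to pass the intensity logit through
        yields bag scores identical to the intensity model's."""
        import copy

        from wisdom._nn import FusionMLP
        from wisdom.model import WisdomResults

        fused = FusionMLP(4, hidden=8, seed=0)
        mean = np.array([0.2, 8.0, 5.0, 0.6], dtype=np.float32)
        scale = np.array([1.5, 3.0, 2.0, 0.2], dtype=np.float32)
        fused.set_identity(0, mean=float(mean[0]), scale=float(scale[0]))
        results = WisdomResults(
            variant="M_IS",
            intensity_net=quick_model.intensity_net,
            fusion=fused,
            feature_mean=mean,
            feature_scale=scale,
            tau=quick_model.tau,
            config=quick_model.config.replace(variant="M_IS"),
            loss_history={},
            n_train_bags=0,
        )
        for bag in small_cohort[:4]:
            p_int = quick_model.score_bag(bag).probs
            p_fused = results.score_bag(bag).probs
            np.testing.assert_allclose(p_fused, p_int, atol=1e-6)

    def test_integrated_training_runs_and_uses_features(self, small_cohort):
        """A short fused fit on the small cohort produces a working scorer
        whose feature standardization comes from the training bags."""
        from wisdom import train_integrated_model

        cfg = WisdomConfig(epochs=2, fusion_epochs=10, batch_bags=8,
                           val_fraction=0.0, seed=2)
        m_i = WisdomModel(small_cohort[:16], cfg).fit()
        m_isa = train_integrated_model(
            small_cohort[:16], m_i, cfg.replace(variant="M_ISA")
        )
        assert m_isa.fusion is not None
        assert m_isa.feature_mean.shape == (5,)
        s = m_isa.score_bag(small_cohort[17])
        assert len(s.probs) == len(small_cohort[17].nodes)
        assert s.p_avg <= s.p_max

    def test_missing_adc_contract_error(self, small_cohort):
        import copy

        bags = copy.deepcopy(small_cohort[:5])
        for node in bags[0].nodes:
            node.mean_adc = None
        with pytest.raises(FeatureContractError):
            WisdomModel(bags, WisdomConfig(variant="M_ISA"))


class TestYoudenThreshold:
    def test_separable_threshold_between_classes(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        tau = _youden_threshold(scores, labels)
        assert 0.3 < tau < 0.7

    def test_prefers_sensitive_threshold_on_ties(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        tau = _youden_threshold(scores, labels)
        pred = scores >= tau
        assert pred.sum() >= 2  # lower threshold wins the tie


class TestConfig:
    def test_variant_validation(self):
        with pytest.raises(ConfigurationError):
            WisdomConfig(variant="M_X")

    def test_weights_validation(self):
        with pytest.raises(ConfigurationError):
            WisdomConfig(lambda_mil=0.0, lambda_llp=0.0)

    def test_degenerate_label_warning(self, small_cohort):
        import copy

        bags = copy.deepcopy(small_cohort[:4])
        for b in bags:
            b.n_metastatic = 0
        with pytest.warns(UserWarning):
            WisdomModel(bags, WisdomConfig())
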