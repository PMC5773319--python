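import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from minarea import (
    ModelError,
    ModelSpec,
    OrdinalDataset,
    OrdinalFit,
    aic,
    category_probs,
    fit_mle,
    neg_loglik,
)
from oracles import naive_nll, sigma

finite = st.floats(-30, 30, allow_nan=False)


class TestModelSpec:
    @pytest.mark.parametrize(
        "name, K",
        [("random", 2), ("area", 3), ("isolation", 3), ("additive", 4), ("interaction", 5)],
    )
    def test_five_candidates_and_parameter_counts(self, name, K):
        assert ModelSpec.from_name(name).K == K

    def test_interaction_without_main_effects_inexpressible(self):
        with pytest.raises(ModelError):
            ModelSpec(terms=("area:isolation",))
        with pytest.raises(ModelError):
            ModelSpec(terms=("area", "area:isolation"))


class TestCategoryProbs:
    @settings(deadline=None, derandomize=True)
    @given(theta1=finite, gap=st.floats(1e-6, 20), beta=finite, x=st.floats(-5, 5))
    def test_normalization_and_monotone_cumulative(self, theta1, gap, beta, x):
        p = category_probs((theta1, theta1 + gap), [beta], np.array([x]))
        assert p.shape == (3,)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12
        # cumulative monotonicity P(Y<=0) <= P(Y<=1) <= 1
        assert p[0] <= p[0] + p[1] <= 1.0 + 1e-12

    def test_symmetric_cutpoints_balance_extremes(self):
        p = category_probs((-0.5, 0.5), [], np.array([]))
        assert p[0] == pytest.approx(p[2], abs=1e-15)

    def test_hand_evaluated_example(self):
        # independent evaluation: eta = 2 * 0.5 = 1, so the curves are
        # sigma(-2) and sigma(0)
        p = category_probs((-1.0, 1.0), [2.0], np.array([0.5]))
        assert p[0] == pytest.approx(sigma(-2.0), abs=1e-12)
        assert p[1] == pytest.approx(sigma(0.0) - sigma(-2.0), abs=1e-12)
        assert p[2] == pytest.approx(1.0 - sigma(0.0), abs=1e-12)

    def test_positive_slope_shifts_mass_to_richer_states(self):
        x = np.linspace(-3, 3, 50)
        p = category_probs((0.0, 2.0), [1.5], x)
        assert np.all(np.diff(p[:, 0]) < 0)
        assert np.all(np.diff(p[:, 2]) > 0)

    def test_ill_ordered_cutpoints_rejected(self):
        with pytest.raises(ModelError, match="ill-ordered"):
            category_probs((1.0, -1.0), [0.0], np.array([0.0]))


class TestNegLoglik:
    def test_uniform_categories(self):
        data = OrdinalDataset(
            x_area=np.zeros(3), x_isolation=np.zeros(3),
            y=np.array([0, 1, 2]), group="rattlesnakes",
        )
        value = neg_loglik(
            (logit(1 / 3), logit(2 / 3)), [], data, ModelSpec.from_name("random")
        )
        assert value == pytest.approx(-3 * np.log(1 / 3), abs=1e-9)

    @pytest.mark.parametrize("model", ["area", "additive", "interaction"])
    def test_agrees_with_naive_loop(self, toy12, model):
        spec = ModelSpec.from_name(model)
        rng = np.random.default_rng(7)
        for _ in range(5):
            theta = np.sort(rng.normal(size=2) * 2)
            theta[1] = theta[0] + abs(theta[1] - theta[0]) + 1e-3
            beta = rng.normal(size=len(spec.terms))
            expected = naive_nll(
                theta[0], theta[1], beta, spec.design_matrix(toy12), toy12.y
            )
            got = neg_loglik(theta, beta, toy12, spec)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_duplicated_island_doubles_contribution(self, toy12):
        spec = ModelSpec.from_name("area")
        theta, beta = (-0.5, 1.0), [0.8]
        base = neg_loglik(theta, beta, toy12, spec)
        first = OrdinalDataset(
            x_area=toy12.x_area[:1], x_isolation=toy12.x_isolation[:1],
            y=toy12.y[:1], group=toy12.group,
        )
        doubled = OrdinalDataset(
            x_area=np.append(toy12.x_area, toy12.x_area[0]),
            x_isolation=np.append(toy12.x_isolation, toy12.x_isolation[0]),
            y=np.append(toy12.y, toy12.y[0]),
            group=toy12.group,
        )
        contribution = neg_loglik(theta, beta, first, spec)
        assert neg_loglik(theta, beta, doubled, spec) == pytest.approx(
            base + contribution, rel=1e-12
        )


class TestFitMLE:
    def test_null_mle_is_empirical_cumulative_logit(self):
        y = np.repeat([0, 1, 2], 10)
        data = OrdinalDataset(
            x_area=np.zeros(30), x_isolation=np.zeros(30), y=y, group="colubrids"
        )
        fit = fit_mle(data, ModelSpec.from_name("random"))
        assert fit.converged
        assert fit.theta[0] == pytest.approx(logit(1 / 3), abs=1e-6)
        assert fit.theta[1] == pytest.approx(logit(2 / 3), abs=1e-6)

    def test_matches_statsmodels_ordered_model(self, rattle_data):
        pytest.importorskip("statsmodels")
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        X = np.column_stack([rattle_data.x_area, rattle_data.x_isolation])
        sm_fit = OrderedModel(rattle_data.y, X, distr="logit").fit(
            method="bfgs", gtol=1e-10, disp=False
        )
        ours = fit_mle(rattle_data, ModelSpec.from_name("additive"))
        assert ours.loglik == pytest.approx(sm_fit.llf, abs=1e-5)
        assert ours.beta == pytest.approx(sm_fit.params[:2], abs=1e-4)

    def test_model_nesting_monotone_loglik(self, rattle_data):
        lls = {
            name: fit_mle(rattle_data, ModelSpec.from_name(name)).loglik
            for name in ("random", "area", "additive", "interaction")
        }
        assert lls["area"] >= lls["random"] - 1e-6
        assert lls["additive"] >= lls["area"] - 1e-6
        assert lls["interaction"] >= lls["additive"] - 1e-6

    def test_permutation_invariance(self, rattle_data):
        perm = np.random.default_rng(11).permutation(rattle_data.n)
        shuffled = rattle_data.subset(perm)
        a = fit_mle(rattle_data, ModelSpec.from_name("area"))
        b = fit_mle(shuffled, ModelSpec.from_name("area"))
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)
        assert a.theta == pytest.approx(b.theta, abs=1e-6)
        assert a.beta == pytest.approx(b.beta, abs=1e-6)

    def test_loglik_nonpositive_and_beats_neighbourhood(self, toy12):
        spec = ModelSpec.from_name("area")
        fit = fit_mle(toy12, spec)
        assert fit.loglik <= 0
        rng = np.random.default_rng(3)
        for _ in range(200):
            t1 = fit.theta[0] + rng.normal() * 0.3
            t2 = max(fit.theta[1] + rng.normal() * 0.3, t1 + 1e-6)
            beta = fit.beta + rng.normal(size=1) * 0.3
            assert -neg_loglik((t1, t2), beta, toy12, spec) <= fit.loglik + 1e-9

    def test_complete_separation_flagged(self):
        data = OrdinalDataset(
            x_area=np.array([-2.0, -1.5, -1.0, 0.5, 1.0, 1.5, 2.5, 3.0, 3.5]),
            x_isolation=np.zeros(9),
            y=np.repeat([0, 1, 2], 3),
            group="rattlesnakes",
        )
        fit = fit_mle(data, ModelSpec.from_name("area"))
        assert not fit.converged
        assert "separation" in fit.message

    def test_single_state_unidentifiable(self):
        data = OrdinalDataset(
            x_area=np.arange(5.0), x_isolation=np.zeros(5),
            y=np.zeros(5, dtype=int), group="rattlesnakes",
        )
        with pytest.raises(ModelError, match="2 observed states"):
            fit_mle(data, ModelSpec.from_name("area"))

    def test_too_few_islands_rejected(self):
        data = OrdinalDataset(
            x_area=np.arange(4.0), x_isolation=np.zeros(4),
            y=np.array([0, 1, 2, 1]), group="rattlesnakes",
        )
        with pytest.raises(ModelError, match="K\\+1"):
            fit_mle(data, ModelSpec.from_name("interaction"))


class TestAIC:
    def test_formula(self):
        fit = OrdinalFit(
            theta=(-1.0, 1.0), beta=np.zeros(1), loglik=0.0,
            spec=ModelSpec.from_name("area"), n=10, converged=True,
        )
        assert aic(fit) == 6.0

    def test_unconverged_requires_force(self):
        fit = OrdinalFit(
            theta=(-1.0, 1.0), beta=np.zeros(1), loglik=-5.0,
            spec=ModelSpec.from_name("area"), n=10, converged=False,
        )
        with pytest.raises(ModelError, match="unconverged"):
            aic(fit)
        assert aic(fit, force=True) == pytest.approx(16.0)
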