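"""Synthetic trial generator, keyword realization, and simulations."""

import numpy as np
import pytest

from splitwrite import (
    DOMAINS,
    DesignParams,
    SimulationConfig,
    analytic_power,
    fit_variance_components,
    generate_trial,
    keyword_table,
    realize_keywords,
    simulate_power,
    variance_components_from_icc,
    weight_sensitivity,
)
from splitwrite.synthetic import SimulationError, realized_score
from conftest import make_rubric, random_rubric


class TestVarianceMapping:
    def test_study_parametrization(self):
        vc = variance_components_from_icc(4.0, 0.8, 0.4)
        assert (vc.sigma2_b, vc.sigma2_c, vc.sigma2_e) == (
            pytest.approx(6.4), pytest.approx(6.4), pytest.approx(3.2)
        )

    def test_equal_correlations_kill_condition_component(self):
        assert variance_components_from_icc(4.0, 0.6, 0.6).sigma2_c == pytest.approx(0.0)

    def test_perfect_icc_kills_residual(self):
        assert variance_components_from_icc(4.0, 1.0, 0.5).sigma2_e == pytest.approx(0.0)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(SimulationError):
            variance_components_from_icc(4.0, 0.3, 0.5)


class TestGenerateTrial:
    def test_moments_match_generating_parameters(self):
        config = SimulationConfig(n_participants=2000, mu_control=5.0, beta=2.1,
                                  sigma_total=4.0, rho=0.8, rho_prime=0.4, seed=77)
        trial = generate_trial(config)
        piv = trial.scores.pivot_means()
        diff = float((piv["tool"] - piv["control"]).mean())
        assert diff == pytest.approx(2.1, abs=0.15)
        vc = fit_variance_components(trial.scores)
        assert vc.rho == pytest.approx(0.8, abs=0.03)
        assert vc.rho_prime == pytest.approx(0.4, abs=0.04)
        assert vc.total == pytest.approx(16.0, rel=0.10)

    def test_deterministic_given_seed(self):
        a = generate_trial(SimulationConfig(n_participants=15, seed=5))
        b = generate_trial(SimulationConfig(n_participants=15, seed=5))
        assert a.scores.frame.equals(b.scores.frame)
        assert a.sequence.patterns == b.sequence.patterns

    def test_zero_variance_is_deterministic_effect(self):
        config = SimulationConfig(n_participants=8, mu_control=4.0, beta=2.0,
                                  sigma_total=0.0, rho=0.0, rho_prime=0.0, seed=1)
        frame = generate_trial(config).scores.frame
        tool = frame.loc[frame["condition"] == "tool", "score"]
        control = frame.loc[frame["condition"] == "control", "score"]
        assert (tool == 6.0).all() and (control == 4.0).all()

    def test_domain_effects_shift_domains_exactly(self):
        effects = (1.5, -1.5, 0.5, -0.5, 1.0, -1.0)
        config = SimulationConfig(n_participants=4, mu_control=5.0, beta=0.0,
                                  sigma_total=0.0, rho=0.0, rho_prime=0.0,
                                  domain_effects=effects, seed=1)
        frame = generate_trial(config).scores.frame
        for dom, eff in zip(DOMAINS, effects):
            assert (frame.loc[frame["domain"] == dom, "score"] == 5.0 + eff).all()

    def test_truncate_clips_to_score_scale(self):
        config = SimulationConfig(n_participants=50, mu_control=1.0, beta=8.0,
                                  sigma_total=6.0, rho=0.8, rho_prime=0.4,
                                  clip_mode="truncate", seed=2)
        scores = generate_trial(config).scores.frame["score"]
        assert scores.between(0.0, 10.0).all()

    def test_domain_effects_must_balance(self):
        with pytest.raises(SimulationError):
            SimulationConfig(domain_effects=(1.0, 0, 0, 0, 0, 0))


class TestRealizeKeywords:
    def test_greedy_trace(self):
        # weights 4,3,2,1, target 5: take 4, skip 3 and 2, take 1
        rubric = make_rubric(weights=(4, 3, 2, 1))
        presence = realize_keywords(rubric, 5.0)
        assert presence == {"k1": True, "k2": False, "k3": False, "k4": True}
        assert realized_score(rubric, presence) == pytest.approx(5.0)

    def test_extreme_targets(self):
        rubric = make_rubric(weights=(4, 3, 2, 1))
        assert all(realize_keywords(rubric, 10.0).values())
        assert not any(realize_keywords(rubric, 0.0).values())

    def test_target_out_of_range_rejected(self):
        with pytest.raises(SimulationError):
            realize_keywords(make_rubric(), 11.0)

    def test_error_bound_on_random_rubrics(self, rng):
        # |realized - target| <= 10 * w_max / sum(w), 1000 random rubrics
        for _ in range(1000):
            rubric = random_rubric(rng)
            target = float(rng.uniform(0, 10))
            realized = realized_score(rubric, realize_keywords(rubric, target))
            w = [k.weight for k in rubric.keywords]
            assert abs(realized - target) <= 10.0 * max(w) / sum(w) + 1e-9


class TestSimulatePower:
    def test_alpha_one_rejects_everything(self):
        config = SimulationConfig(n_participants=5, seed=3, n_replicates=100)
        assert simulate_power(config, alpha=1.0).power == 1.0

    def test_too_few_replicates_rejected(self):
        with pytest.raises(SimulationError):
            simulate_power(SimulationConfig(seed=1), n_replicates=50)

    def test_null_rejection_near_alpha(self):
        config = SimulationConfig(n_participants=40, beta=0.0, seed=8,
                                  n_replicates=400)
        result = simulate_power(config)
        assert result.power == pytest.approx(0.05, abs=3 * 0.011 + 1e-9)
        assert result.mc_se == pytest.approx(
            np.sqrt(result.power * (1 - result.power) / 400)
        )


class TestAnalyticPower:
    def test_power_at_allocated_sample_size(self):
        # Phi(2 / (4 sqrt(2*1.4/120)) - z_.975) = Phi(1.3133)
        assert analytic_power(DesignParams(), 120) == pytest.approx(0.9055, abs=5e-4)

    def test_power_at_unrounded_requirement_is_nominal(self):
        assert analytic_power(DesignParams(), 117.683) == pytest.approx(0.900, abs=1e-3)

    def test_null_limit_is_half_alpha(self):
        assert analytic_power(DesignParams(delta=1e-12), 120) == pytest.approx(
            0.025, abs=1e-6
        )


@pytest.fixture(scope="module")
def keyword_trial():
    config = SimulationConfig(n_participants=8, clip_mode="truncate", seed=42)
    trial = generate_trial(config, with_keywords=True)
    return trial, keyword_table(trial)


class TestWeightSensitivity:
    def test_identity_scheme_reproduces_original(self, keyword_trial):
        trial, table = keyword_trial
        result = weight_sensitivity(table, trial.rubrics, scheme="original",
                                    n_replicates=10, seed=0)
        assert np.allclose(result.betas, result.beta_original)

    def test_single_keyword_rubrics_invariant(self, rng):
        from splitwrite import ProtocolRubric
        from conftest import make_rubric as mk

        config = SimulationConfig(n_participants=6, clip_mode="truncate", seed=11)
        trial = generate_trial(config, with_keywords=True)
        rubrics = {
            pid: ProtocolRubric(
                pid, tuple(mk(pid, dom, weights=(2.0,)) for dom in DOMAINS)
            )
            for pid in trial.rubrics
        }
        # presence of the single keyword per domain drawn at random
        alloc = trial.sequence.to_frame(list(rubrics))
        from splitwrite import ConsensusRating
        consensus = [
            ConsensusRating(row.protocol_id, row.domain, "k1",
                            present=bool(rng.integers(2)))
            for row in alloc.itertuples()
        ]
        from splitwrite import build_keyword_table
        table = build_keyword_table(rubrics, consensus, alloc)
        result = weight_sensitivity(table, rubrics, scheme="uniform_integer",
                                    n_replicates=20, seed=3)
        assert np.allclose(result.betas, result.beta_original)

    def test_reproducible_given_seed(self, keyword_trial):
        trial, table = keyword_trial
        kwargs = dict(scheme="uniform_integer", n_replicates=25, seed=7)
        a = weight_sensitivity(table, trial.rubrics, **kwargs)
        b = weight_sensitivity(table, trial.rubrics, **kwargs)
        assert np.array_equal(a.betas, b.betas)
        assert a.quantiles == b.quantiles

    def test_unknown_scheme_rejected(self, keyword_trial):
        trial, table = keyword_trial
        with pytest.raises(SimulationError, match="scheme"):
            weight_sensitivity(table, trial.rubrics, scheme="bogus")

    def test_dirichlet_scheme_runs(self, keyword_trial):
        trial, table = keyword_trial
        result = weight_sensitivity(table, trial.rubrics, scheme="dirichlet",
                                    n_replicates=10, seed=5)
        assert result.minimum <= result.quantiles[50.0] <= result.maximum

    def test_rescoring_tracks_generated_scores(self, keyword_trial):
        # rescoring realized keywords with original weights stays within the
        # greedy realization bound of the clipped continuous scores
        trial, table = keyword_trial
        clipped = trial.scores.frame["score"].clip(0, 10).to_numpy()
        regrouped = (
            table.assign(row=np.arange(len(table)))
            .groupby(["participant_id", "domain"], sort=False)
        )
        frame = trial.scores.frame
        for (pid_dom, g) in regrouped:
            part, dom = pid_dom
            pid = g["protocol_id"].iloc[0]
            rubric = trial.rubrics[pid].domain(dom)
            presence = dict(zip(g["keyword_id"], g["present"]))
            realized = realized_score(rubric, presence)
            target = float(
                frame.loc[
                    (frame["participant_id"] == part) & (frame["domain"] == dom),
                    "score",
                ].clip(0, 10).iloc[0]
            )
            w = [k.weight for k in rubric.keywords]
            assert abs(realized - target) <= 10.0 * max(w) / sum(w) + 1e-9
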