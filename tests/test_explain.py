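"""Explainability: attribution, surrogate rules, counterfactuals, trajectories."""

import itertools

import numpy as np
import pytest

from orthoplan.explain import (Attribution, attribute, counterfactual,
                               explain_trajectory, fit_surrogate, render_report)
from orthoplan.planner import Episode, EpisodeStep
from orthoplan.env import TreatmentAction
from orthoplan.rewards import RewardVector, TaskWeights


class TestAttribution:
    def test_state_equals_baseline_all_zero(self):
        f = lambda X: np.atleast_2d(X).sum(axis=1)
        att = attribute(f, np.ones(5), np.ones(5), n_samples=8, seed=0)
        np.testing.assert_array_equal(att.contributions, np.zeros(5))

    def test_additive_model_closed_form(self):
        """For f(x) = sum c_j x_j the Shapley value is c_j (x_j - b_j) exactly."""
        rng = np.random.default_rng(1)
        c = rng.normal(size=6)
        f = lambda X: np.atleast_2d(X) @ c
        x, b = rng.normal(size=6), rng.normal(size=6)
        att = attribute(f, x, b, n_samples=4, seed=0)
        np.testing.assert_allclose(att.contributions, c * (x - b), atol=1e-10)

    def test_completeness_residual(self):
        rng = np.random.default_rng(2)
        # non-additive model with interactions
        f = lambda X: (np.atleast_2d(X) ** 2).sum(axis=1) + \
            np.atleast_2d(X)[:, 0] * np.atleast_2d(X)[:, 1]
        x, b = rng.normal(size=5), rng.normal(size=5)
        att = attribute(f, x, b, n_samples=32, seed=3)
        assert abs(att.completeness_residual) < 1e-6

    def test_symmetry_for_duplicated_features(self):
        f = lambda X: np.atleast_2d(X)[:, 0] * np.atleast_2d(X)[:, 1] + \
            np.atleast_2d(X)[:, 2]
        x = np.array([1.0, 1.0, 0.5])
        b = np.zeros(3)
        att = attribute(f, x, b, n_samples=2000, seed=4)
        # features 0 and 1 play identical roles
        assert abs(att.contributions[0] - att.contributions[1]) < 0.05

    def test_determinism(self):
        f = lambda X: np.sin(np.atleast_2d(X)).sum(axis=1)
        x, b = np.ones(4), np.zeros(4)
        a1 = attribute(f, x, b, n_samples=16, seed=9)
        a2 = attribute(f, x, b, n_samples=16, seed=9)
        np.testing.assert_array_equal(a1.contributions, a2.contributions)

    def test_block_aggregation(self):
        f = lambda X: np.atleast_2d(X).sum(axis=1)
        att = attribute(f, np.ones(148), np.zeros(148), n_samples=2, seed=0)
        blocks = att.by_block()
        assert set(blocks) == {"skeletal", "dental", "soft_tissue", "status"}
        assert blocks["skeletal"] == pytest.approx(45.0)
        assert blocks["dental"] == pytest.approx(52.0)


class TestSurrogate:
    def test_constant_policy_trivial_tree(self):
        rng = np.random.default_rng(0)
        states = rng.normal(size=(200, 5))
        rules = fit_surrogate(lambda X: np.zeros(len(X), int), states, max_depth=3)
        assert rules.trivial
        assert rules.fidelity == 1.0
        assert "constant" in rules.rules_text()

    def test_planted_threshold_rule_recovery(self):
        """A depth-1 tree recovers the 'proceed iff relapse_risk < 0.3' split."""
        rng = np.random.default_rng(1)
        states = rng.uniform(0, 1, size=(5000, 6))
        relapse_col = 2
        policy = lambda X: (np.atleast_2d(X)[:, relapse_col] < 0.3).astype(int)
        rules = fit_surrogate(policy, states, max_depth=1, seed=0,
                              feature_names=[f"f{i}" for i in range(6)])
        assert rules.fidelity >= 0.98
        tree = rules.tree.tree_
        assert tree.feature[0] == relapse_col
        assert abs(tree.threshold[0] - 0.3) < 0.02

    def test_fidelity_reported_on_heldout(self):
        rng = np.random.default_rng(2)
        states = rng.normal(size=(300, 4))
        rules = fit_surrogate(lambda X: (np.atleast_2d(X)[:, 0] > 0).astype(int),
                              states, max_depth=2)
        assert rules.n_train == 150 and rules.n_heldout == 150

    def test_minimum_sample_enforced(self):
        with pytest.raises(ValueError, match="50"):
            fit_surrogate(lambda X: np.zeros(len(X), int), np.zeros((10, 3)))


class TestCounterfactual:
    def test_already_satisfying_zero_delta(self):
        cf = counterfactual(lambda x: x.sum() - 1.0, np.ones(3),
                            (np.zeros(3), 2 * np.ones(3)))
        assert cf.feasible and cf.sparsity == 0 and cf.distance == 0.0

    def test_1d_monotone_threshold(self):
        """Delta equals the distance to the threshold within grid resolution."""
        thr = 0.62
        margin = lambda x: float(x[0]) - thr
        grid = [np.linspace(0.0, 1.0, 101)]
        cf = counterfactual(margin, np.array([0.2]), (np.zeros(1), np.ones(1)),
                            grids=grid)
        assert cf.feasible
        assert abs(cf.modified[0] - thr) <= 0.011  # one grid step

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_small_grid_near_bruteforce_optimum(self, seed):
        """On 21^3 discretized problems the search lands within 5% of the
        exhaustive-search optimum."""
        rng = np.random.default_rng(seed)
        c = rng.uniform(0.5, 2.0, size=3)
        thr = rng.uniform(1.0, 2.0)
        margin = lambda x: float(np.asarray(x) @ c) - thr
        lo, hi = np.zeros(3), np.ones(3)
        grids = [np.linspace(0, 1, 21)] * 3
        x0 = np.zeros(3)
        w = 1.0 / (hi - lo)

        # independent brute-force oracle over the full grid
        best = np.inf
        for pt in itertools.product(*grids):
            p = np.array(pt)
            if margin(p) >= 0:
                best = min(best, float(np.abs(p - x0) @ w))
        cf = counterfactual(margin, x0, (lo, hi), grids=grids, seed=seed)
        assert cf.feasible
        assert cf.distance <= 1.05 * best + 1e-12

    def test_infeasible_reported_not_raised(self):
        cf = counterfactual(lambda x: -1.0, np.zeros(2),
                            (np.zeros(2), np.ones(2)), n_starts=2, max_rounds=3)
        assert not cf.feasible

    def test_immutable_mask_respected(self):
        margin = lambda x: float(x[0] + x[1]) - 1.5
        cf = counterfactual(margin, np.zeros(2), (np.zeros(2), np.ones(2)),
                            mutable_mask=np.array([True, False]))
        assert not cf.feasible or cf.deltas[1] == 0.0

    def test_bounds_must_contain_state(self):
        with pytest.raises(ValueError, match="bounds"):
            counterfactual(lambda x: 1.0, np.array([5.0]),
                           (np.zeros(1), np.ones(1)))


def _episode(phases, rewards):
    steps = []
    rec_action = TreatmentAction(sagittal_mm=5.0, force_g=100.0,
                                 phase_decision="proceed")
    from orthoplan.cohort import CohortConfig, sample_cohort, sample_patient_state
    rec = sample_cohort(CohortConfig(n=1, seed=5))[0]
    base = sample_patient_state(rec, seed=1)
    for phase, r in zip(phases, rewards):
        s = base.copy()
        s.treatment_status.phase = phase
        steps.append(EpisodeStep(state=s, action=rec_action,
                                 reward=RewardVector(*r), next_state=s, info={}))
    return Episode(record_id="t", steps=steps)


class TestTrajectoryExplanation:
    def test_single_phase_single_segment(self):
        ep = _episode([1, 1, 1], [[0.1] * 4] * 3)
        tx = explain_trajectory(ep, TaskWeights())
        assert len(tx.segments) == 1
        assert (tx.segments[0].start, tx.segments[0].end) == (0, 2)

    def test_dominant_component_per_phase(self):
        ep = _episode([1, 1, 2, 2],
                      [[0.9, 0.0, 0.1, 0.1], [0.9, 0.0, 0.1, 0.1],
                       [0.0, 0.9, 0.1, 0.1], [0.0, 0.9, 0.1, 0.1]])
        tx = explain_trajectory(ep, TaskWeights.uniform())
        assert tx.segments[0].dominant_component == "functional"
        assert tx.segments[1].dominant_component == "aesthetic"

    def test_segments_partition_steps(self):
        ep = _episode([1, 1, 2, 3, 3], [[0.2] * 4] * 5)
        tx = explain_trajectory(ep, TaskWeights())
        spans = [(s.start, s.end) for s in tx.segments]
        covered = sorted(i for a, b in spans for i in range(a, b + 1))
        assert covered == list(range(5))
        # disjoint
        assert len(covered) == len(set(covered))
        assert len(tx.justifications) == 5


@pytest.fixture(scope="module")
def attribution():
    f = lambda X: np.atleast_2d(X) @ np.array([3.0, -2.0, 1.0, 0.5, 0.1])
    return attribute(f, np.ones(5), np.zeros(5), n_samples=4, seed=0,
                     feature_names=["ANB", "overjet", "harmony", "tmj", "age"])


class TestRendering:
    def test_same_ranking_across_audiences(self, attribution):
        text_s, doc_s = render_report(attribution, "specialist", top_k=5)
        text_i, doc_i = render_report(attribution, "interdisciplinary", top_k=5)
        names_s = [d["feature"] for d in doc_s["top_features"]]
        names_i = [d["feature"] for d in doc_i["top_features"]]
        assert names_s == names_i
        assert "ANB" in text_s and "ANB" in text_i

    def test_top_k_respected(self, attribution):
        _, doc = render_report(attribution, "specialist", top_k=3)
        assert len(doc["top_features"]) == 3

    def test_zero_delta_counterfactual_message(self):
        cf = counterfactual(lambda x: 1.0, np.zeros(2), (np.zeros(2), np.ones(2)))
        text, doc = render_report(cf, "specialist")
        assert "No modification needed" in text

    def test_unknown_audience_rejected(self, attribution):
        with pytest.raises(ValueError, match="audience"):
            render_report(attribution, "patient")

    def test_trajectory_rendering(self):
        ep = _episode([1, 2], [[0.5, 0.1, 0.1, 0.1], [0.1, 0.5, 0.1, 0.1]])
        tx = explain_trajectory(ep, TaskWeights())
        text, doc = render_report(tx, "interdisciplinary")
        assert "Phase 1" in text and "Phase 2" in text
        assert doc["segments"][0]["dominant"] == "functional"
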