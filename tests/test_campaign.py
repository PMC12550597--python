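"""Closed-loop campaign harness: initial design, determinism, reporting."""

import numpy as np
import pytest

from reactbo import (
    CampaignConfig,
    best_so_far,
    compare_encodings,
    initial_design,
    load_history,
    make_benchmark,
    pareto_front,
    run_campaign,
    save_history,
)
from reactbo.campaign import ComparisonReport, replay_campaign
from reactbo.fixtures import fixture_catalyst_set
from reactbo.moo import dominates
from reactbo.space import ContinuousDim, ParameterSpace


@pytest.fixture(scope="module")
def small_cfg():
    # tiny but complete campaign: all code paths, short runtime
    return CampaignConfig(benchmark="amidation_sim", encoding="chemistry",
                          algorithm="tsemo", budget=2, seed=7,
                          n_features=150, pop_size=24, generations=15,
                          gp_restarts=2)


class TestInitialDesign:
    def test_six_vars_six_catalysts_gives_twelve_two_each(self, amidation):
        # 5 continuous + 1 categorical, 6 catalysts -> 12 runs, 2 per base
        design = initial_design(amidation.space, amidation.catalyst_set, seed=0)
        assert len(design) == 12
        counts = {}
        for c in design:
            counts[c.catalyst.name] = counts.get(c.catalyst.name, 0) + 1
        assert all(v == 2 for v in counts.values()) and len(counts) == 6

    def test_two_catalyst_one_continuous_rule_arithmetic(self):
        cats = fixture_catalyst_set(2, seed=3)
        space = ParameterSpace((ContinuousDim("temperature_C", 0.0, 100.0),), cats)
        design = initial_design(space, cats, seed=1)
        assert len(design) == 4  # 2 * (1 continuous + 1 categorical)
        names = [c.catalyst.name for c in design]
        assert names.count(cats[0].name) == 2 and names.count(cats[1].name) == 2

    def test_latin_hypercube_stratification(self, amidation):
        """Each continuous dimension's 12 values fall in 12 distinct bins."""
        design = initial_design(amidation.space, amidation.catalyst_set, seed=5)
        space = amidation.space
        X = np.array([c.continuous_values(space) for c in design])
        U = (X - space.lows) / (space.highs - space.lows)
        for j in range(space.n_continuous):
            bins = np.floor(U[:, j] * 12).astype(int)
            assert len(set(bins.tolist())) == 12

    def test_deterministic_given_seed(self, amidation):
        a = initial_design(amidation.space, amidation.catalyst_set, seed=9)
        b = initial_design(amidation.space, amidation.catalyst_set, seed=9)
        assert a == b

    def test_design_smaller_than_catalyst_set_rejected(self, amidation):
        with pytest.raises(ValueError, match="at least once"):
            initial_design(amidation.space, amidation.catalyst_set, seed=0, n=4)

    def test_uneven_split_round_robin(self, amidation):
        design = initial_design(amidation.space, amidation.catalyst_set, seed=0, n=15)
        counts = {}
        for c in design:
            counts[c.catalyst.name] = counts.get(c.catalyst.name, 0) + 1
        assert sorted(counts.values()) == [2, 2, 2, 3, 3, 3]


class TestRunCampaign:
    def test_zero_budget_returns_initial_design_only(self):
        cfg = CampaignConfig(budget=0, seed=1)
        h = run_campaign(cfg)
        assert len(h) == 12
        assert all(r.provenance == "init" for r in h.records)

    def test_record_structure_and_counts(self, small_cfg):
        h = run_campaign(small_cfg)
        assert len(h) == 12 + small_cfg.budget
        assert [r.iteration for r in h.records] == list(range(len(h)))
        provs = [r.provenance for r in h.records]
        assert provs[:12] == ["init"] * 12
        assert provs[12:] == ["algorithm"] * small_cfg.budget

    def test_proposed_catalysts_are_set_members(self, small_cfg, amidation):
        h = run_campaign(small_cfg)
        names = set(amidation.catalyst_set.names)
        assert all(r.conditions.catalyst.name in names for r in h.records)
        assert all(amidation.space.contains(r.conditions) for r in h.records)

    def test_byte_identical_histories_same_config(self, small_cfg, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        save_history(run_campaign(small_cfg), p1)
        save_history(run_campaign(small_cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self, small_cfg):
        h1 = run_campaign(small_cfg)
        h2 = run_campaign(CampaignConfig.from_dict({**small_cfg.to_dict(), "seed": 8}))
        assert not h1.to_frame().equals(h2.to_frame())

    def test_replay_regenerates_exactly(self, small_cfg, tmp_path):
        path = tmp_path / "h.csv"
        save_history(run_campaign(small_cfg), path)
        _, ok = replay_campaign(path)
        assert ok

    def test_history_round_trip(self, small_cfg, tmp_path):
        h = run_campaign(small_cfg)
        path = tmp_path / "h.csv"
        save_history(h, path)
        cfg, df = load_history(path)
        assert cfg == small_cfg
        assert len(df) == len(h)
        assert list(df.columns) == list(h.to_frame().columns)

    def test_config_file_round_trip(self, small_cfg, tmp_path):
        path = tmp_path / "cfg.yaml"
        small_cfg.to_file(path)
        assert CampaignConfig.from_file(path) == small_cfg

    def test_multiobjective_campaign_runs_and_reports_front(self):
        cfg = CampaignConfig(benchmark="api_reaction", algorithm="tsemo",
                             objectives=("yield", "base_cost", "pmi"),
                             budget=2, seed=3, n_features=150, pop_size=24,
                             generations=15, gp_restarts=2)
        h = run_campaign(cfg)
        front = pareto_front(h)
        assert 1 <= len(front) <= len(h)
        F = h.objective_matrix(minimize=True)
        front_idx = [h.records.index(r) for r in front]
        for i in front_idx:
            assert not any(dominates(F[j], F[i]) for j in range(len(F)))


class TestBestSoFar:
    def test_single_record(self):
        h = run_campaign(CampaignConfig(budget=0, seed=2))
        traj = best_so_far(h)
        assert len(traj) == len(h)
        assert traj[0] == h.records[0].objectives.yield_pct

    def test_monotone_and_final_is_max(self):
        h = run_campaign(CampaignConfig(budget=0, seed=4))
        traj = best_so_far(h)
        assert np.all(np.diff(traj) >= 0)
        assert traj[-1] == max(r.objectives.yield_pct for r in h.records)

    def test_minimized_objective_runs_downward(self):
        h = run_campaign(CampaignConfig(budget=0, seed=4,
                                        objectives=("yield", "pmi")))
        traj = best_so_far(h, "pmi")
        assert np.all(np.diff(traj) <= 0)


class TestParetoFront:
    def test_identical_points_collapse_to_one(self):
        h = run_campaign(CampaignConfig(budget=0, seed=5,
                                        objectives=("yield", "pmi")))
        # duplicate every record
        h.records = h.records + h.records
        front = pareto_front(h)
        F = np.array([[r.objectives.yield_pct, r.objectives.pmi] for r in front])
        assert len(np.unique(np.round(F, 9), axis=0)) == len(front)

    def test_matches_bruteforce_oracle_and_order_invariance(self, rng):
        h = run_campaign(CampaignConfig(budget=0, seed=6,
                                        objectives=("yield", "base_cost", "pmi")))
        F = h.objective_matrix(minimize=True)
        front = pareto_front(h)
        oracle = {i for i in range(len(F))
                  if not any(dominates(F[j], F[i]) for j in range(len(F)))}
        got_keys = {tuple(np.round(F[h.records.index(r)], 9)) for r in front}
        oracle_keys = {tuple(np.round(F[i], 9)) for i in oracle}
        assert got_keys == oracle_keys
        # permuting the records leaves the front set unchanged
        perm = rng.permutation(len(h.records))
        h.records = [h.records[i] for i in perm]
        front2 = pareto_front(h)

        def keys(front_records):
            return {(round(r.objectives.yield_pct, 9),
                     round(r.objectives.base_cost_per_g, 9),
                     round(r.objectives.pmi, 9)) for r in front_records}

        assert keys(front2) == keys(front)


class TestComparison:
    def test_self_comparison_identical_and_report_round_trip(self, tmp_path):
        rep = compare_encodings(strategies=("chemistry", "chemistry"),
                                n_replicates=3, budget=1, base_seed=1,
                                threshold_pct=90.0, n_features=150,
                                pop_size=24, generations=15, gp_restarts=2)
        assert np.array_equal(rep.trajectories["chemistry"],
                              rep.trajectories["chemistry"])
        med = rep.median_trajectory("chemistry")
        assert np.all(np.diff(med) >= 0)
        path = tmp_path / "rep.json"
        rep.save(path)
        back = ComparisonReport.load(path)
        assert back.strategies == rep.strategies
        assert back.threshold_pct == rep.threshold_pct
        for s in rep.strategies:
            assert np.allclose(back.trajectories[s], rep.trajectories[s])

    def test_requires_enough_replicates_and_strategies(self):
        with pytest.raises(ValueError):
            compare_encodings(strategies=("chemistry",), n_replicates=3)
        with pytest.raises(ValueError):
            compare_encodings(n_replicates=2)
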