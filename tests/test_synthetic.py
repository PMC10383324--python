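"""Statistical fidelity of the synthetic study generator."""

import numpy as np
import pytest

from egopath import (
    BehaviorScenario,
    PlantedModule,
    PlantedPathway,
    SimulationScenario,
    compute_contrast,
    generate_abundances,
    generate_behavior,
    generate_network,
    generate_pathways,
    recognition_index,
    spontaneous_alternation,
)
from egopath.errors import ConfigurationError
from egopath.synthetic import expected_alternation_percent


class TestGenerateNetwork:
    def test_complete_graph_limit(self):
        sc = SimulationScenario(n_proteins=4, mean_degree=3.0, seed=0)
        assert generate_network(sc).n_edges == 6  # K4

    def test_same_seed_identical_edge_sets(self):
        sc = SimulationScenario(n_proteins=100, mean_degree=5, seed=42)
        assert generate_network(sc).edge_set() == generate_network(sc).edge_set()

    def test_realized_mean_degree_near_target(self):
        sc = SimulationScenario(n_proteins=200, mean_degree=6, seed=1)
        net = generate_network(sc)
        realized = 2 * net.n_edges / 200
        assert abs(realized - 6) <= 0.2 * 6

    def test_simple_undirected_no_self_loops(self):
        sc = SimulationScenario(n_proteins=50, mean_degree=4, seed=3)
        net = generate_network(sc)
        assert all(a != b for a, b in net.graph.edges)
        assert sorted(net.nodes)[0] == "P000001"

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationScenario(mean_degree=0.0)
        with pytest.raises(ConfigurationError):
            SimulationScenario(n_proteins=10, mean_degree=10)


class TestGenerateAbundances:
    def test_null_construction_centered_at_zero(self, null_scenario, null_contrasts):
        """With no planted effects, per-protein group-mean log differences are
        centered at 0: the mean over 200 proteins is within 4 SE."""
        _, _, contrasts = null_contrasts
        for c in contrasts:
            vals = c.logfc.dropna().to_numpy()
            se = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean()) <= 4 * se

    def test_planted_module_delta_recovered(self):
        delta = 1.0
        sc = SimulationScenario(n_proteins=150, seed=21,
                                planted_modules=(PlantedModule("P000010", "UCCAO", delta),))
        net = generate_network(sc)
        mat = generate_abundances(net, sc)
        c = compute_contrast(mat, "UCCAO")
        members = sorted({"P000010"} | net.neighbors("P000010"))
        # delta is on the natural-log scale; logfc is log2
        recovered = c.logfc[members].mean() / np.log2(np.e)
        tol = 3 * sc.noise_sd / np.sqrt(sc.n_replicates_per_group)
        assert recovered == pytest.approx(delta, abs=tol)
        # control-only contrast unaffected elsewhere
        others = c.logfc.drop(members)
        assert abs(others.mean()) < 0.2

    def test_planted_pathway_shifts_signed_members(self):
        sc = SimulationScenario(n_proteins=100, seed=33, n_pathways=5,
                                repressor_fraction=0.3,
                                planted_pathways=(PlantedPathway("PW0002", "UCCAO_MF", 1.0),))
        net = generate_network(sc)
        pws = generate_pathways(net, sc)
        mat = generate_abundances(net, sc, pws)
        c = compute_contrast(mat, "UCCAO_MF")
        pw = next(p for p in pws if p.pathway_id == "PW0002")
        acts = [m for m, s in pw.members.items() if s == 1]
        reps = sorted(pw.repressors)
        assert c.logfc[acts].mean() > 0.5
        assert c.logfc[reps].mean() < -0.5

    def test_deterministic_and_positive(self, null_scenario):
        net = generate_network(null_scenario)
        a = generate_abundances(net, null_scenario)
        b = generate_abundances(net, null_scenario)
        assert a.values.equals(b.values)
        assert (a.values.to_numpy() > 0).all()

    def test_planting_in_control_or_unknown_group_rejected(self):
        sc = SimulationScenario(n_proteins=20, seed=0,
                                planted_modules=(PlantedModule("P000001", "SHAM", 1.0),))
        with pytest.raises(ConfigurationError):
            generate_abundances(generate_network(sc), sc)
        sc2 = SimulationScenario(n_proteins=20, seed=0,
                                 planted_modules=(PlantedModule("P000001", "NOPE", 1.0),))
        with pytest.raises(ConfigurationError):
            generate_abundances(generate_network(sc2), sc2)


class TestGeneratePathways:
    def test_repressor_rounding_half_up(self):
        sc = SimulationScenario(n_proteins=50, seed=0, n_pathways=3,
                                pathway_size=10, repressor_fraction=0.3)
        net = generate_network(sc)
        for pw in generate_pathways(net, sc):
            assert len(pw.repressors) == 3

    @pytest.mark.parametrize("fraction,size,expected", [
        (0.0, 10, 0), (0.25, 10, 3), (0.15, 10, 2), (1.0, 6, 6)])
    def test_repressor_counts(self, fraction, size, expected):
        sc = SimulationScenario(n_proteins=40, seed=2, n_pathways=2,
                                pathway_size=size, repressor_fraction=fraction)
        net = generate_network(sc)
        for pw in generate_pathways(net, sc):
            assert len(pw.repressors) == expected
            assert pw.size == size

    def test_same_seed_identical_memberships(self):
        sc = SimulationScenario(n_proteins=60, seed=9, n_pathways=4)
        net = generate_network(sc)
        a = generate_pathways(net, sc)
        b = generate_pathways(net, sc)
        assert [(p.pathway_id, p.members) for p in a] == \
               [(p.pathway_id, p.members) for p in b]

    def test_size_exceeding_proteins_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationScenario(n_proteins=5, pathway_size=10)


class TestGenerateBehavior:
    def test_full_alternation_scores_hundred(self):
        sc = BehaviorScenario(alternation_prob=1.0, n_animals_per_group=3, seed=0)
        data = generate_behavior(sc)
        for s in data.arm_sequences:
            assert spontaneous_alternation(s) == pytest.approx(100.0)

    def test_alternation_rate_converges_to_oracle(self):
        sc = BehaviorScenario(alternation_prob=0.6, n_animals_per_group=150,
                              n_entries=30, seed=4)
        data = generate_behavior(sc)
        vals = [spontaneous_alternation(s) for s in data.arm_sequences
                if s.group == "UCCAO"]
        expect = expected_alternation_percent(sc, "UCCAO")
        # per-window Bernoulli(0.6): SE of the cohort mean
        se = 100 * np.sqrt(0.6 * 0.4 / 28) / np.sqrt(len(vals))
        # windows overlap (positively correlated), inflate conservatively
        assert abs(np.mean(vals) - expect) <= 3 * se * 2

    def test_neutral_preference_centers_at_half(self):
        sc = BehaviorScenario(novelty_preference=0.5, n_animals_per_group=200, seed=8)
        data = generate_behavior(sc)
        idx = [recognition_index((e.time_novel, e.time_familiar)).index
               for e in data.explorations]
        idx = [i for i in idx if i is not None]
        assert np.mean(idx) == pytest.approx(0.5, abs=0.02)

    def test_exclusion_rate_near_twenty_percent(self):
        sc = BehaviorScenario(n_animals_per_group=300, seed=5)
        data = generate_behavior(sc)
        exc = [recognition_index((e.time_novel, e.time_familiar)).excluded
               for e in data.explorations]
        assert np.mean(exc) == pytest.approx(0.2, abs=0.03)

    def test_determinism_and_per_group_settings(self):
        sc = BehaviorScenario(alternation_prob={"SHAM": 0.9, "UCCAO": 0.3,
                                                "UCCAO_MF": 0.7},
                              n_animals_per_group=80, seed=12)
        a = generate_behavior(sc)
        b = generate_behavior(sc)
        assert [s.entries for s in a.arm_sequences] == [s.entries for s in b.arm_sequences]
        mean = {g: np.mean([spontaneous_alternation(s) for s in a.arm_sequences
                            if s.group == g]) for g in sc.groups}
        assert mean["SHAM"] > mean["UCCAO_MF"] > mean["UCCAO"]

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            BehaviorScenario(alternation_prob=1.4)
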