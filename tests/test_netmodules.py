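"""Ego-module statistics against independent brute-force oracles."""

from itertools import combinations
from math import comb, sqrt

import numpy as np
import pytest

from egopath import (
    InteractionNetwork,
    Module,
    build_module,
    module_correlation,
    module_significance,
    module_stats,
    random_module_null,
    select_de_proteins,
)
from egopath.errors import ContractError, UsageError
from .conftest import make_contrast


def brute_force_mean_p(logfc: dict, module_members: set) -> float:
    """Exhaustive two-sided module-mean p by direct enumeration of every
    same-size subset of the background (independent of the package's
    permutation code)."""
    bg = sorted(logfc)
    k = len(module_members)
    means = [np.mean([logfc[p] for p in sub]) for sub in combinations(bg, k)]
    center = np.mean(means)
    obs = np.mean([logfc[p] for p in module_members])
    hits = sum(1 for m in means if abs(m - center) >= abs(obs - center) - 1e-12)
    return hits / len(means)


class TestBuildModule:
    def test_star_hub_takes_all(self, star_graph):
        bg = star_graph.nodes
        m = build_module(star_graph, "HUB", bg)
        assert m.members == frozenset(bg) - {"ISO"}

    def test_isolated_seed_is_singleton(self, star_graph):
        m = build_module(star_graph, "ISO", star_graph.nodes)
        assert m.members == frozenset({"ISO"}) and m.size == 1

    def test_background_restriction(self, path_graph):
        m = build_module(path_graph, "B", {"A", "B"})
        assert m.members == frozenset({"A", "B"})

    def test_unknown_seed_raises(self, path_graph):
        with pytest.raises(LookupError):
            build_module(path_graph, "Z", {"A", "B", "C"})
        with pytest.raises(LookupError):
            build_module(path_graph, "A", {"B", "C"})  # unmeasured seed


class TestModuleStats:
    @pytest.mark.parametrize("vals,mean,sd", [
        ({"A": 1.0, "B": 3.0}, 2.0, sqrt(2)),
        ({"A": 5.0}, 5.0, 0.0),
        ({"A": -1.0, "B": 0.0, "C": 1.0}, 0.0, 1.0),
    ])
    def test_mean_and_sample_sd(self, vals, mean, sd):
        mod = Module(seed_protein=next(iter(vals)), members=frozenset(vals))
        c = make_contrast(vals)
        assert module_stats(mod, c) == (pytest.approx(mean), pytest.approx(sd))

    def test_member_without_logfc_is_contract_error(self):
        mod = Module(seed_protein="A", members=frozenset({"A", "B"}))
        c = make_contrast({"A": 1.0, "B": np.nan})
        with pytest.raises(ContractError):
            module_stats(mod, c)


class TestRandomModuleNull:
    def test_exhaustive_three_choose_two_means(self):
        c = make_contrast({"A": 1.0, "B": 2.0, "C": 3.0})
        ns = random_module_null({"A", "B", "C"}, 2, c, exhaustive=True)
        assert sorted(ns.means) == pytest.approx([1.5, 2.0, 2.5])
        assert ns.exhaustive

    def test_full_background_draws_are_degenerate(self):
        c = make_contrast({"A": 1.0, "B": 3.0})
        ns = random_module_null({"A", "B"}, 2, c, n_perm=50, exhaustive=False, seed=0)
        assert np.all(ns.means == 2.0) and np.ptp(ns.means) == 0.0

    def test_fixed_seed_reproduces_null(self):
        c = make_contrast({f"P{i}": float(i) for i in range(30)})
        a = random_module_null(set(c.protein_ids), 5, c, n_perm=200, seed=42,
                               exhaustive=False)
        b = random_module_null(set(c.protein_ids), 5, c, n_perm=200, seed=42,
                               exhaustive=False)
        assert np.array_equal(a.means, b.means) and np.array_equal(a.sds, b.sds)

    def test_size_larger_than_background_rejected(self):
        c = make_contrast({"A": 1.0, "B": 2.0})
        with pytest.raises(UsageError):
            random_module_null({"A", "B"}, 3, c)


class TestModuleSignificance:
    def test_observed_at_null_center_gives_p_one(self):
        c = make_contrast({"A": 1.0, "B": 2.0, "C": 3.0})
        ns = random_module_null({"A", "B", "C"}, 2, c, exhaustive=True)
        res = module_significance((float(np.mean(ns.means)), 0.0), ns)
        assert res["mean"].p == 1.0

    def test_add_one_rule_floor(self):
        ns_vals = np.zeros(999)
        from egopath.netmodules import NullSample
        ns = NullSample(means=ns_vals, sds=ns_vals, size=3, exhaustive=False, seed=0)
        res = module_significance((5.0, 0.0), ns)
        assert res["mean"].p == pytest.approx(1 / 1000)

    def test_exhaustive_matches_brute_force_enumeration(self):
        logfc = {"A": 0.0, "B": 0.0, "C": 0.0, "D": 2.0}
        module = {"D", "A"}
        ns = random_module_null(set(logfc), 2, make_contrast(logfc), exhaustive=True)
        obs = (np.mean([logfc[p] for p in module]), np.std(list(map(logfc.get, module)), ddof=1))
        res = module_significance(obs, ns)
        assert res["mean"].p == pytest.approx(brute_force_mean_p(logfc, module))

    def test_shift_equivariance_of_two_sided_p(self):
        rng = np.random.default_rng(3)
        logfc = {f"P{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 10))}
        module = {"P0", "P3", "P7"}
        p0 = brute_force_mean_p(logfc, module)
        c = make_contrast(logfc)
        ns = random_module_null(set(logfc), 3, c, exhaustive=True)
        mod = Module(seed_protein="P0", members=frozenset(module))
        p_pkg = module_significance(module_stats(mod, c), ns)["mean"].p
        assert p_pkg == pytest.approx(p0)
        shifted = make_contrast({k: v + 17.5 for k, v in logfc.items()})
        ns2 = random_module_null(set(logfc), 3, shifted, exhaustive=True)
        p_shift = module_significance(module_stats(mod, shifted), ns2)["mean"].p
        assert p_shift == pytest.approx(p_pkg)

    def test_sampled_p_within_mc_error_of_exhaustive(self):
        """|background| <= 12, size <= 4: 5000 sampled draws agree with
        exact enumeration within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(8)
        logfc = {f"P{i:02d}": float(v) for i, v in enumerate(rng.normal(0, 1, 12))}
        c = make_contrast(logfc)
        for size, members in [(3, {"P00", "P05", "P11"}),
                              (4, {"P01", "P02", "P03", "P04"})]:
            mod = Module(seed_protein=sorted(members)[0], members=frozenset(members))
            obs = module_stats(mod, c)
            ns_ex = random_module_null(set(logfc), size, c, exhaustive=True)
            p_ex = module_significance(obs, ns_ex)["mean"].p
            ns_s = random_module_null(set(logfc), size, c, n_perm=5000,
                                      exhaustive=False, seed=1)
            p_s = module_significance(obs, ns_s)["mean"].p
            se = sqrt(p_ex * (1 - p_ex) / 5000)
            assert abs(p_s - p_ex) <= 3 * se + 2 / 5001


class TestModuleCorrelation:
    def _module_and_contrasts(self, a_vals, b_vals):
        ids = [f"P{i}" for i in range(len(a_vals))]
        extra = {f"B{i}": float(v) for i, v in
                 enumerate(np.random.default_rng(0).normal(0, 1, 20))}
        ca = make_contrast({**dict(zip(ids, a_vals)), **extra}, case="UCCAO")
        cb = make_contrast({**dict(zip(ids, b_vals)), **extra}, case="UCCAO_MF")
        mod = Module(seed_protein=ids[0], members=frozenset(ids))
        return mod, ca, cb

    @pytest.mark.parametrize("b_scale,expected_r", [(1.0, 1.0), (-1.0, -1.0), (2.0, 1.0)])
    def test_perfectly_linear_members(self, b_scale, expected_r):
        a = [1.0, 2.0, 3.0]
        mod, ca, cb = self._module_and_contrasts(a, [b_scale * x for x in a])
        res = module_correlation(mod, ca, cb, n_perm=99, seed=0)
        assert res.observed == pytest.approx(expected_r)
        assert res.p is not None and 0 < res.p <= 1

    def test_self_correlation_is_one(self):
        mod, ca, _ = self._module_and_contrasts([0.5, -1.0, 2.0], [0.0, 0.0, 1.0])
        res = module_correlation(mod, ca, ca, n_perm=99, seed=0)
        assert res.observed == pytest.approx(1.0)

    def test_undefined_below_three_members_or_zero_variance(self):
        mod, ca, cb = self._module_and_contrasts([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert module_correlation(mod, ca, cb).undefined  # zero variance in a
        small = Module(seed_protein="P0", members=frozenset({"P0", "P1"}))
        assert module_correlation(small, ca, cb).undefined


class TestSelectDeProteins:
    def test_planted_seed_selected_and_output_stable(self, null_scenario):
        from egopath import (PlantedModule, SimulationScenario, compute_contrast,
                             generate_abundances, generate_network)
        sc = SimulationScenario(n_proteins=60, seed=5,
                                planted_modules=(PlantedModule("P000007", "UCCAO",
                                                               3 * 0.35),))
        net = generate_network(sc)
        mat = generate_abundances(net, sc)
        contrasts = [compute_contrast(mat, "UCCAO")]
        sel1 = select_de_proteins(net, contrasts, n_perm=199, seed=9)
        sel2 = select_de_proteins(net, contrasts, n_perm=199, seed=9)
        assert sel1.per_seed.equals(sel2.per_seed)  # bit-identical
        row = sel1.per_seed.set_index("seed_protein").loc["P000007"]
        assert bool(row["selected"])
        assert row["p_mean"] == sel1.per_seed["p_mean"].min()

    def test_alpha_zero_selects_nothing(self, path_graph):
        c = make_contrast({"A": 0.1, "B": 5.0, "C": -0.2})
        sel = select_de_proteins(path_graph, [c], alpha=0.0, n_perm=49, seed=0,
                                 pair_correlation=False)
        assert not sel.per_seed["selected"].any()
        assert all(len(s) == 0 for s in sel.de_sets.values())

    def test_untestable_seeds_reported(self, path_graph):
        c = make_contrast({"A": 0.1, "B": 0.4, "C": -0.2, "ORPHAN": 1.0})
        sel = select_de_proteins(path_graph, [c], n_perm=19, seed=0,
                                 pair_correlation=False)
        assert sel.untestable == ["ORPHAN"]
        assert set(sel.per_seed["seed_protein"]) == {"A", "B", "C"}
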