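"""Star-sets, chokepoints, dead-end metabolites, classification,
essentiality, blocked reactions and dead-end removal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemvuln import (
    DEFAULT_BOUND,
    GrowthContext,
    blocked_reactions,
    build_model,
    chokepoints,
    classify_reactions,
    dead_end_metabolites,
    essential_reactions,
    growth_dependent_essential,
    growth_dependent_sets,
    make_fixture,
    max_growth,
    remove_dead_end_metabolites,
    star_consumers,
    star_producers,
    star_products,
    star_reactants,
)
from gemvuln.fixtures import FixtureSpec


@pytest.fixture(scope="module")
def mixed_net():
    """One forward, one reversible and one dead reaction on A/B."""
    return build_model(
        {
            "fwd": ({"A": -1.0, "B": 2.0}, 0.0, 1000.0),
            "rev": ({"A": -1.0, "B": 1.0}, -1000.0, 1000.0),
            "dead": ({"A": -1.0, "B": 1.0}, 0.0, 0.0),
        }
    )


class TestStarSets:
    def test_forward_reaction(self, mixed_net):
        assert star_reactants(mixed_net, "fwd") == {"A"}
        assert star_products(mixed_net, "fwd") == {"B"}

    def test_reversible_reaction(self, mixed_net):
        assert star_reactants(mixed_net, "rev") == {"A", "B"}
        assert star_products(mixed_net, "rev") == {"A", "B"}

    def test_dead_reaction_has_empty_stars(self, mixed_net):
        assert star_reactants(mixed_net, "dead") == set()
        assert star_products(mixed_net, "dead") == set()

    def test_sole_consumer(self, net1):
        assert star_consumers(net1, "ma") == {"r2"}

    def test_metabolite_of_only_dead_reactions(self):
        model = build_model({"dead": ({"X": -1.0, "Y": 1.0}, 0.0, 0.0)})
        assert star_consumers(model, "X") == set()
        assert star_producers(model, "X") == set()

    def test_unknown_ids(self, net1):
        with pytest.raises(KeyError):
            star_reactants(net1, "rX")
        with pytest.raises(KeyError):
            star_consumers(net1, "mX")

    def test_matches_literal_formula(self, random_models):
        for model in random_models[:4]:
            S = model.stoichiometry.toarray()
            L, U = model.lower_bounds, model.upper_bounds
            for i, m in enumerate(model.metabolites):
                cons = {
                    model.reactions[j]
                    for j in range(model.n_reactions)
                    if (S[i, j] < 0 and U[j] > 1e-6) or (S[i, j] > 0 and L[j] < -1e-6)
                }
                prod = {
                    model.reactions[j]
                    for j in range(model.n_reactions)
                    if (S[i, j] > 0 and U[j] > 1e-6) or (S[i, j] < 0 and L[j] < -1e-6)
                }
                assert star_consumers(model, m) == cons
                assert star_producers(model, m) == prod


class TestChokepoints:
    def test_sole_consumer_is_chokepoint(self, net1):
        assert "r2" in chokepoints(net1)

    def test_balanced_metabolite_contributes_none(self):
        model = build_model(
            {
                "p1": ({"X": 1.0}, 0.0, 10.0),
                "p2": ({"X": 1.0}, 0.0, 10.0),
                "c1": ({"X": -1.0}, 0.0, 10.0),
                "c2": ({"X": -1.0}, 0.0, 10.0),
            }
        )
        assert chokepoints(model) == frozenset()

    def test_structural_level_ignores_bounds(self):
        # with bounds, the dead reaction is no consumer; structurally it is
        model = build_model(
            {
                "p": ({"X": 1.0}, 0.0, 10.0),
                "c_live": ({"X": -1.0}, 0.0, 10.0),
                "c_dead": ({"X": -1.0}, 0.0, 0.0),
            }
        )
        assert "c_live" in chokepoints(model, level="flux")
        flux_cp = chokepoints(model, level="flux")
        structural_cp = chokepoints(model, level="structural")
        assert "c_live" in flux_cp  # unique live consumer
        assert "c_live" not in structural_cp  # two structural consumers

    def test_reversible_sole_producer_and_consumer_counts_once(self):
        model = build_model(
            {"rev": ({"X": -1.0, "Y": 1.0}, -1000.0, 1000.0)}
        )
        assert chokepoints(model) == frozenset({"rev"})

    def test_boundary_metabolites_excluded_by_default(self):
        model = build_model(
            {"r": ({"X": -1.0, "E": 1.0}, 0.0, 10.0),
             "p": ({"X": 1.0}, 0.0, 10.0)},
            boundary={"E"},
        )
        assert "r" in chokepoints(model)  # sole consumer of internal X
        # E's sole producer only counts when boundary metabolites included
        assert chokepoints(model, include_boundary=True) >= {"r", "p"}


class TestDeadEndMetabolites:
    def test_produced_never_consumed(self, net1):
        assert dead_end_metabolites(net1) == frozenset({"mg"})

    def test_reversible_partner_is_no_dem(self):
        model = build_model(
            {
                "rev": ({"A": -1.0, "B": 1.0}, -1000.0, 1000.0),
                "ex": ({"A": 1.0}, 0.0, 10.0),
            }
        )
        assert dead_end_metabolites(model) == frozenset()

    def test_dead_only_metabolite_is_dem(self):
        model = build_model({"dead": ({"X": -1.0, "Y": 1.0}, 0.0, 0.0)})
        assert dead_end_metabolites(model) == frozenset({"X", "Y"})


class TestClassification:
    @pytest.mark.parametrize(
        "lo,hi,cls",
        [
            (0.0, 0.0, "dead"),
            (-1000.0, 1000.0, "reversible"),
            (-1000.0, 0.0, "non_reversible"),
            (0.0, 1000.0, "non_reversible"),
            (5.0, 10.0, "non_reversible"),
        ],
    )
    def test_single_reaction(self, lo, hi, cls):
        model = build_model({"r": ({"A": -1.0, "B": 1.0}, lo, hi)})
        part = classify_reactions(model)
        assert "r" in getattr(part, cls)

    @given(
        bounds=st.lists(
            st.tuples(
                st.floats(-1000, 1000, allow_nan=False),
                st.floats(-1000, 1000, allow_nan=False),
            ).map(lambda t: (min(t), max(t))),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_partition_law(self, bounds):
        reactions = {
            f"r{j}": ({f"m{j}": 1.0}, lo, hi) for j, (lo, hi) in enumerate(bounds)
        }
        part = classify_reactions(build_model(reactions))
        assert part.all_reactions == set(reactions)
        total = len(part.dead) + len(part.reversible) + len(part.non_reversible)
        assert total == len(reactions)


class TestEssential:
    def test_unique_path_all_essential(self, chain_net):
        assert essential_reactions(chain_net) == {"ex", "rg"}

    def test_redundant_paths_not_essential(self, parallel_net):
        ers = essential_reactions(parallel_net)
        assert ers == {"r_growth"}

    def test_gamma_zero_always_empty(self, parallel_net, net1, net2):
        for model in (parallel_net, net1, net2):
            ctx = max_growth(model, gamma=0.0)
            assert growth_dependent_essential(model, ctx) == frozenset()

    def test_parallel_paths_thresholds(self, parallel_net):
        mu = max_growth(parallel_net).mu_max
        assert mu == pytest.approx(7.0)
        path3 = {"ex_0", "r_p0_bio"}
        path4 = {"ex_1", "r_p1_bio"}
        # optimal growth needs both paths
        er1 = growth_dependent_essential(parallel_net, GrowthContext(mu, 1.0))
        assert path3 <= er1 and path4 <= er1
        # at a floor of 3 (= gamma 3/7) either path alone suffices
        er37 = growth_dependent_essential(parallel_net, GrowthContext(mu, 3.0 / 7.0))
        assert not (path3 | path4) & er37
        # at a floor of 4 the capacity-4 path is required, capacity-3 is not
        er47 = growth_dependent_essential(parallel_net, GrowthContext(mu, 4.0 / 7.0))
        assert path4 <= er47
        assert not path3 & er47

    def test_er_subset_of_erog(self, net1, net2, random_models):
        for model in (net1, net2, *random_models[:4]):
            ctx = max_growth(model)
            er = essential_reactions(model)
            erog = growth_dependent_essential(model, ctx)
            if ctx.mu_max > 0:
                assert er <= erog


class TestBlocked:
    def test_dem_consumer_blocked(self, net2):
        assert "r6" in blocked_reactions(net2)

    def test_open_chain_has_none(self, chain_net):
        assert blocked_reactions(chain_net) == frozenset()

    def test_equals_dead_set_at_gamma_zero(self, random_models):
        for model in random_models[:6]:
            ctx = max_growth(model, gamma=0.0)
            report = growth_dependent_sets(model, ctx)
            assert blocked_reactions(model) == report.partition.dead


class TestGrowthDependentSets:
    def test_new_chokepoint_appears_at_optimum(self, net2):
        ctx = max_growth(net2, gamma=1.0)
        report = growth_dependent_sets(net2, ctx)
        assert "r4" in report.chokepoints
        assert "r4" not in chokepoints(net2)

    def test_chokepoint_lost_when_dead(self, net2):
        assert "r3" in chokepoints(net2)
        ctx = max_growth(net2, gamma=1.0)
        report = growth_dependent_sets(net2, ctx)
        assert "r3" not in report.chokepoints
        assert "r3" in report.partition.dead

    def test_report_is_tagged_and_valid(self, net2):
        ctx = max_growth(net2, gamma=0.5)
        report = growth_dependent_sets(net2, ctx)
        assert report.gamma == 0.5
        report.validate()
        assert not report.chokepoints & report.partition.dead
        if ctx.mu_max > 0:
            assert not report.essential & report.blocked


class TestTheorems:
    GRID = (0.0, 0.25, 0.5, 0.75, 0.99)

    def test_dead_sets_constant_below_one(self, random_models):
        for model in random_models[:8]:
            mu = max_growth(model).mu_max
            dead_sets = [
                growth_dependent_sets(model, GrowthContext(mu, g)).partition.dead
                for g in self.GRID
            ]
            assert all(d == dead_sets[0] for d in dead_sets)

    def test_dead_monotone_including_one(self, random_models):
        for model in random_models[:8]:
            mu = max_growth(model).mu_max
            prev = frozenset()
            for g in (*self.GRID, 1.0):
                dead = growth_dependent_sets(model, GrowthContext(mu, g)).partition.dead
                assert prev <= dead
                prev = dead

    def test_essential_monotone(self, random_models):
        for model in random_models[:8]:
            mu = max_growth(model).mu_max
            prev = frozenset()
            for g in (*self.GRID, 1.0):
                er = growth_dependent_essential(model, GrowthContext(mu, g))
                assert prev <= er
                prev = er

    def test_dead_reactions_never_chokepoints(self, random_models):
        for model in random_models[:8]:
            mu = max_growth(model).mu_max
            for g in (0.0, 1.0):
                report = growth_dependent_sets(model, GrowthContext(mu, g))
                assert not report.chokepoints & report.partition.dead


class TestRemoveDeadEnds:
    def test_single_pass(self):
        model = build_model(
            {
                "ex": ({"A": 1.0}, 0.0, 10.0),
                "r": ({"A": -1.0, "X": 1.0}, 0.0, 10.0),
                "sink": ({"A": -1.0}, 0.0, 10.0),
            }
        )
        pruned = remove_dead_end_metabolites(model)
        assert "X" not in pruned.metabolites
        assert set(pruned.reactions) == set(model.reactions)

    def test_cascade(self):
        # C is a dead end; removing it makes B one
        model = build_model(
            {
                "ex": ({"A": 1.0}, 0.0, 10.0),
                "ab": ({"A": -1.0, "B": 1.0}, 0.0, 10.0),
                "bc": ({"B": -1.0, "C": 1.0}, 0.0, 10.0),
                "sink": ({"A": -1.0}, 0.0, 10.0),
            }
        )
        pruned = remove_dead_end_metabolites(model)
        assert set(pruned.metabolites) == {"A"}
        # both chain reactions lost a whole side and were deactivated
        assert pruned.orphan_reactions == {"ab", "bc"}
        assert set(pruned.reactions) == set(model.reactions)

    def test_no_dems_identity(self, chain_net):
        pruned = remove_dead_end_metabolites(chain_net)
        assert pruned.metabolites == chain_net.metabolites
        assert np.allclose(
            pruned.stoichiometry.toarray(), chain_net.stoichiometry.toarray()
        )


def test_planted_structures_detected():
    spec = FixtureSpec(
        n_reactions=10, n_metabolites=8, include_dem=True, include_dead=True, seed=5
    )
    model = make_fixture(spec)
    assert dead_end_metabolites(model)
    mu = max_growth(model).mu_max
    for g in (0.0, 0.5, 1.0):
        part = growth_dependent_sets(model, GrowthContext(mu, g)).partition
        assert "r_dead" in part.dead
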