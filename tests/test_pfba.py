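"""Parsimonious FBA formulation, solution and butyrate rate extraction."""

import numpy as np
import pytest

from commfba.community import build_community
from commfba.gem import LUMEN, MetabolicModel, Metabolite, Reaction
from commfba.io import AbundanceTable
from commfba.pfba import (
    CommunityLPCache,
    butyrate_rate,
    formulate_pfba,
    sample_butyrate_capacity,
    solve,
)
from commfba.simulate import make_species_models, producer_model


class TestFormulate:
    def test_variable_count_is_2n_plus_1(self, s1_community):
        lp = formulate_pfba(s1_community)
        n = len(s1_community.reactions)
        assert lp.c.size == 2 * n + 1
        assert lp.A_eq.shape[1] == 2 * n + 1

    def test_negative_parsimony_rejected(self, s1_community):
        with pytest.raises(ValueError, match="parsimony"):
            formulate_pfba(s1_community, parsimony_coef=-1e-6)

    def test_missing_coupling_rejected(self, s1_community):
        s1_community.coupling = []
        with pytest.raises(ValueError, match="coupling"):
            formulate_pfba(s1_community)


class TestToyProducerOracle:
    """Hand-solved LP for the single producer: uptake saturates at 10,
    every biomass unit co-produces one butyrate, five reactions carry |v|=10."""

    def test_hand_solved_values(self, s1_community):
        sol = solve(formulate_pfba(s1_community))
        assert sol.status == "optimal"
        assert sol.mu == pytest.approx(10.0, abs=1e-6)
        assert sol.fluxes["EX_but"] == pytest.approx(10.0, abs=1e-6)
        assert sol.objective == pytest.approx(9.9995, abs=1e-6)
        assert butyrate_rate(sol, "EX_but") == pytest.approx(1.0, abs=1e-6)

    def test_no_carbon_source_means_zero_growth(self):
        starved = producer_model("S1", 0.0)  # exchange pinned to [0, 0]
        sol = solve(formulate_pfba(build_community([(starved, 1.0)])))
        assert sol.status == "zero_growth"

    def test_two_member_community_splits_glucose(self, s1, s2):
        cm = build_community([(s1, 0.5), (s2, 0.5)])
        sol = solve(formulate_pfba(cm))
        assert sol.mu == pytest.approx(10.0, abs=1e-6)
        assert sol.fluxes["EX_but"] == pytest.approx(5.0, abs=1e-6)
        assert butyrate_rate(sol, "EX_but") == pytest.approx(0.5, abs=1e-6)

    def test_zero_parsimony_is_plain_fba(self, s1_community):
        sol = solve(formulate_pfba(s1_community, parsimony_coef=0.0))
        assert sol.mu == pytest.approx(10.0, abs=1e-8)
        assert sol.objective == pytest.approx(10.0, abs=1e-8)

    def test_scale_coherence(self):
        """Doubling exchange bounds doubles growth, leaves the rate unchanged."""
        base = producer_model("S1", 10.0)
        doubled = producer_model("S1", 20.0)
        for model, expect_mu in ((base, 10.0), (doubled, 20.0)):
            sol = solve(formulate_pfba(build_community([(model, 1.0)])))
            assert sol.mu == pytest.approx(expect_mu, abs=1e-6)
            assert butyrate_rate(sol, "EX_but") == pytest.approx(1.0, abs=1e-8)


def redundant_pathway_model() -> MetabolicModel:
    """Producer with a 1-step and a parallel 3-step route from glucose to
    biomass precursor; only parsimony distinguishes them."""
    c = "c:R"
    return MetabolicModel(
        species_id="R",
        metabolites=[
            Metabolite("glc", "glucose", LUMEN),
            Metabolite("but", "butyrate", LUMEN),
            Metabolite("glc_c", "glc", c),
            Metabolite("a", "a", c),
            Metabolite("b", "b", c),
            Metabolite("pre", "precursor", c),
            Metabolite("but_c", "but", c),
        ],
        reactions=[
            Reaction("EX_glc", {"glc": -1.0}, -10.0, 0.0, is_exchange=True),
            Reaction("T_glc", {"glc": -1.0, "glc_c": 1.0}, 0.0, 1000.0),
            Reaction("SHORT", {"glc_c": -1.0, "pre": 1.0}, 0.0, 1000.0),
            Reaction("LONG1", {"glc_c": -1.0, "a": 1.0}, 0.0, 1000.0),
            Reaction("LONG2", {"a": -1.0, "b": 1.0}, 0.0, 1000.0),
            Reaction("LONG3", {"b": -1.0, "pre": 1.0}, 0.0, 1000.0),
            Reaction("GROW", {"pre": -1.0, "but_c": 1.0}, 0.0, 1000.0, is_biomass=True),
            Reaction("T_but", {"but_c": -1.0, "but": 1.0}, 0.0, 1000.0),
            Reaction("EX_but", {"but": -1.0}, 0.0, 1000.0, is_exchange=True),
        ],
        biomass_reaction_id="GROW",
    ).validate()


class TestParsimony:
    def test_redundant_pathway_carries_zero_flux(self):
        cm = build_community([(redundant_pathway_model(), 1.0)])
        sol = solve(formulate_pfba(cm, parsimony_coef=1e-5))
        for rxn in ("LONG1", "LONG2", "LONG3"):
            assert abs(sol.fluxes["R|" + rxn]) <= 1e-9
        assert sol.fluxes["R|SHORT"] == pytest.approx(10.0, abs=1e-6)

    def test_growth_loss_bounded_by_lambda_times_total_flux(self):
        cm = build_community([(redundant_pathway_model(), 1.0)])
        pure = solve(formulate_pfba(cm, parsimony_coef=0.0))
        total_flux_pure = sum(abs(v) for v in pure.fluxes.values())
        for lam in (1e-3, 1e-5, 1e-7):
            sol = solve(formulate_pfba(cm, parsimony_coef=lam))
            assert pure.mu - sol.mu <= lam * total_flux_pure + 1e-9
        assert solve(formulate_pfba(cm, parsimony_coef=1e-7)).mu == pytest.approx(
            pure.mu, abs=1e-5
        )

    def test_parsimonious_solution_minimizes_total_flux(self):
        cm = build_community([(redundant_pathway_model(), 1.0)])
        pfba = solve(formulate_pfba(cm, parsimony_coef=1e-5))
        # both routes achieve mu=10; the parsimonious one uses 5 reactions at 10
        assert sum(abs(v) for v in pfba.fluxes.values()) == pytest.approx(
            60.0, abs=1e-4
        )


class TestButyrateRate:
    def test_rate_arithmetic(self, s1, s2):
        sol = solve(formulate_pfba(build_community([(s1, 0.5), (s2, 0.5)])))
        assert butyrate_rate(sol, "EX_but") == pytest.approx(0.5)

    def test_zero_outflow_gives_zero_rate(self):
        # facultative producer: butyrate synthesis competes with growth, so
        # the optimum secretes nothing and the rate is exactly 0
        c = "c:F"
        model = MetabolicModel(
            species_id="F",
            metabolites=[
                Metabolite("glc", "glucose", LUMEN),
                Metabolite("but", "butyrate", LUMEN),
                Metabolite("glc_c", "glc", c),
                Metabolite("but_c", "but", c),
            ],
            reactions=[
                Reaction("EX_glc", {"glc": -1.0}, -10.0, 0.0, is_exchange=True),
                Reaction("T_glc", {"glc": -1.0, "glc_c": 1.0}, 0.0, 1000.0),
                Reaction("GROW", {"glc_c": -1.0}, 0.0, 1000.0, is_biomass=True),
                Reaction("MAKE_BUT", {"glc_c": -1.0, "but_c": 1.0}, 0.0, 1000.0),
                Reaction("T_but", {"but_c": -1.0, "but": 1.0}, 0.0, 1000.0),
                Reaction("EX_but", {"but": -1.0}, 0.0, 1000.0, is_exchange=True),
            ],
            biomass_reaction_id="GROW",
        ).validate()
        sol = solve(formulate_pfba(build_community([(model, 1.0)])))
        assert sol.mu == pytest.approx(10.0, abs=1e-6)
        assert butyrate_rate(sol, "EX_but") == pytest.approx(0.0, abs=1e-10)

    def test_zero_growth_rate_is_undefined(self):
        starved = producer_model("S1", 0.0)
        sol = solve(formulate_pfba(build_community([(starved, 1.0)])))
        assert butyrate_rate(sol, "EX_but") is None

    def test_unknown_exchange_rejected(self, s1_community):
        sol = solve(formulate_pfba(s1_community))
        with pytest.raises(KeyError, match="EX_propionate"):
            butyrate_rate(sol, "EX_propionate")

    def test_no_uptake_means_nonnegative_rate(self):
        reg = make_species_models(6, 0.5, seed=3)
        rng = np.random.default_rng(5)
        w = rng.dirichlet(np.ones(6))
        members = [(m, float(x)) for m, x in zip(reg.models.values(), w)]
        sol = solve(formulate_pfba(build_community(members)))
        rate = butyrate_rate(sol, "EX_but")
        assert rate is not None and rate >= -1e-12


class TestSampleCapacity:
    def make_table(self, entries):
        return AbundanceTable.from_entries(entries)

    def test_single_producer_sample(self, s1):
        table = self.make_table([("s", "S1", 0.9995), ("s", "X", 0.0005)])
        res = sample_butyrate_capacity("s", table, {"S1": s1})
        assert res.butyrate_rate == pytest.approx(1.0, abs=1e-8)
        assert res.n_members == 1

    def test_mixed_sample_rate(self, s1, s2):
        table = self.make_table([("s", "S1", 0.5), ("s", "S2", 0.5)])
        res = sample_butyrate_capacity("s", table, {"S1": s1, "S2": s2})
        assert res.butyrate_rate == pytest.approx(0.5, abs=1e-8)

    def test_all_taxa_unmodelled(self, s1):
        table = self.make_table([("s", "A", 0.6), ("s", "B", 0.4)])
        res = sample_butyrate_capacity("s", table, {"S1": s1})
        assert res.status == "empty_community"
        assert res.butyrate_rate is None
        assert res.dropped_mass == pytest.approx(1.0)

    def test_unresolved_mass_dropped_before_renormalization(self, s1, s2):
        table = self.make_table([("s", "S1", 0.3), ("s", "S2", 0.3), ("s", "Z", 0.4)])
        res = sample_butyrate_capacity("s", table, {"S1": s1, "S2": s2})
        assert res.dropped_mass == pytest.approx(0.4)
        assert res.butyrate_rate == pytest.approx(0.5, abs=1e-8)

    def test_taxon_map_aggregates_otus(self, s1, s2):
        table = self.make_table(
            [("s", "o1", 0.25), ("s", "o2", 0.25), ("s", "o3", 0.5)]
        )
        res = sample_butyrate_capacity(
            "s",
            table,
            {"S1": s1, "S2": s2},
            taxon_map={"o1": "S1", "o2": "S1", "o3": "S2"},
        )
        assert res.n_members == 2
        assert res.butyrate_rate == pytest.approx(0.5, abs=1e-8)

    def test_cache_path_matches_fresh_path(self, small_registry):
        rng = np.random.default_rng(7)
        species = sorted(small_registry.models)
        entries = []
        for sid in ("a", "b", "c"):
            w = rng.dirichlet(np.ones(len(species)))
            entries += [(sid, sp, float(x)) for sp, x in zip(species, w)]
        table = AbundanceTable.from_entries(entries)
        cache = CommunityLPCache()
        for sid in ("a", "b", "c", "a"):
            fresh = sample_butyrate_capacity(sid, table, small_registry.models)
            cached = sample_butyrate_capacity(
                sid, table, small_registry.models, cache=cache
            )
            assert cached.butyrate_rate == pytest.approx(
                fresh.butyrate_rate, abs=1e-12
            )
            assert cached.mu == pytest.approx(fresh.mu, abs=1e-12)
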