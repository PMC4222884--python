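"""LP engine behavior: FBA, FVA, parsimonious selection, deletions."""

import numpy as np
import pytest

from cljflux.core_model import CoreModelConfig, build_core_model, medium_preset
from cljflux.fba import (
    apply_medium,
    carbon_exchange_balance,
    fba,
    fva,
    parsimonious_solution,
    single_gene_deletion,
)
from cljflux.model import Metabolite, Reaction, build_model, stoichiometric_matrix
from cljflux.synthetic import brute_force_lp_oracle, random_feasible_network
from conftest import make_chain_model, make_parallel_model


def test_chain_optimum_is_uptake_cap():
    sol = fba(make_chain_model(uptake_cap=5.0))
    assert sol.ok
    assert sol.objective_value == pytest.approx(5.0, abs=1e-9)
    assert sol.fluxes["EX_a"] == pytest.approx(-5.0, abs=1e-9)


def test_solution_satisfies_steady_state_and_bounds():
    model = apply_medium(build_core_model(), medium_preset("fructose"))
    sol = fba(model)
    S = stoichiometric_matrix(model)
    v = np.array([sol.fluxes[r.id] for r in model.reactions])
    assert np.max(np.abs(S @ v)) <= 1e-9
    for r in model.reactions:
        assert r.lower_bound - 1e-9 <= sol.fluxes[r.id] <= r.upper_bound + 1e-9


def test_no_source_with_maintenance_is_infeasible():
    model = build_core_model(CoreModelConfig(ngam=1.0))
    closed = apply_medium(model, {})
    sol = fba(closed)
    assert sol.status == "infeasible"


def test_direction_minimize():
    sol = fba(make_chain_model(), direction="min")
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


# -- FVA ------------------------------------------------------------------

def test_fva_chain_zero_width():
    ranges = fva(make_chain_model(uptake_cap=3.0), objective_fraction=1.0)
    for lo, hi in ranges.values():
        assert hi - lo == pytest.approx(0.0, abs=1e-8)


def test_fva_parallel_paths_span_optimum():
    ranges = fva(make_parallel_model(cap=4.0), objective_fraction=1.0)
    for rid in ("P1", "P2"):
        lo, hi = ranges[rid]
        assert lo == pytest.approx(0.0, abs=1e-8)
        assert hi == pytest.approx(4.0, abs=1e-8)


def test_fva_fraction_zero_is_plain_min_max():
    model = make_chain_model(uptake_cap=3.0)
    ranges = fva(model, objective_fraction=0.0)
    assert ranges["AB"] == pytest.approx((0.0, 3.0), abs=1e-8)


# -- parsimonious ---------------------------------------------------------

def test_pfba_matches_fba_on_single_path():
    model = make_chain_model(uptake_cap=2.0)
    assert parsimonious_solution(model).fluxes == pytest.approx(fba(model).fluxes, abs=1e-8)


def test_pfba_zeroes_futile_cycle():
    """A reversible A<->B pair forms a cycle that optimal FBA may spin;
    the parsimonious solution must leave it at the minimal total flux."""
    mets = [
        Metabolite(id="a_e", compartment="e"),
        Metabolite(id="b_c", compartment="c"),
        Metabolite(id="c_e", compartment="e"),
    ]
    rxns = [
        Reaction(id="EX_a", stoichiometry={"a_e": -1.0}, lower_bound=-2.0,
                 upper_bound=0.0, is_exchange=True),
        Reaction(id="F", stoichiometry={"a_e": -1.0, "b_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="CYC1", stoichiometry={"b_c": -1.0, "c_e": 1.0},
                 lower_bound=-1000.0, upper_bound=1000.0),
        Reaction(id="CYC2", stoichiometry={"b_c": -1.0, "c_e": 1.0},
                 lower_bound=-1000.0, upper_bound=1000.0),
        Reaction(id="EX_c", stoichiometry={"c_e": -1.0}, lower_bound=0.0,
                 upper_bound=1000.0, is_exchange=True),
    ]
    model = build_model(mets, rxns, objective_id="EX_c")
    sol = parsimonious_solution(model)
    total = sum(abs(v) for v in sol.fluxes.values())
    # re-solve check: any optimum moves 2 units through 4 reactions + exchange
    assert total == pytest.approx(8.0, abs=1e-6)
    assert min(abs(sol.fluxes["CYC1"]), abs(sol.fluxes["CYC2"])) == pytest.approx(0.0, abs=1e-6)


def test_pfba_tie_break_prefers_earliest_reaction_id():
    sol = parsimonious_solution(make_parallel_model(cap=4.0), lexicographic=True)
    assert sol.fluxes["P1"] == pytest.approx(4.0, abs=1e-6)
    assert sol.fluxes["P2"] == pytest.approx(0.0, abs=1e-6)


def test_pfba_is_optimal_per_oracle():
    net = random_feasible_network(2, 2, seed=11)
    sol = parsimonious_solution(net.model)
    assert sol.objective_value == pytest.approx(brute_force_lp_oracle(net.model), abs=1e-6)


# -- deletions ------------------------------------------------------------

def test_gene_absent_from_gprs_has_ratio_one():
    model = apply_medium(build_core_model(), medium_preset("fructose"))
    model.genes.append("orphan_gene")
    (res,) = single_gene_deletion(model, genes=["orphan_gene"])
    assert res.growth_ratio == 1.0


def test_acka_deletion_on_fructose_reduces_but_keeps_growth():
    model = apply_medium(build_core_model(), medium_preset("fructose"))
    (res,) = single_gene_deletion(model, genes=["ackA"])
    assert 0.0 < res.growth_ratio < 1.0


def test_rnf_deletion_kills_autotrophic_growth():
    model = apply_medium(build_core_model(), medium_preset("h2_co2"))
    (res,) = single_gene_deletion(model, genes=["rnfC"])
    assert res.growth_ratio == 0.0


def test_zero_flux_zero_range_gene_deletion_is_neutral():
    """Genes whose reactions carry no flux in the parsimonious solution
    and have zero-width FVA ranges cannot affect the optimum."""
    model = apply_medium(build_core_model(), medium_preset("fructose"))
    psol = parsimonious_solution(model)
    ranges = fva(model, objective_fraction=1.0)
    results = {r.gene: r for r in single_gene_deletion(model)}
    for gene in model.genes:
        rxns = [r for r in model.reactions if gene in r.gpr.genes()]
        if not rxns:
            continue
        if all(
            abs(psol.fluxes[r.id]) < 1e-9
            and (ranges[r.id][1] - ranges[r.id][0]) < 1e-9
            for r in rxns
        ):
            assert results[gene].growth_ratio == pytest.approx(1.0, abs=1e-6)


# -- global invariants ----------------------------------------------------

@pytest.mark.parametrize("preset", ["fructose", "h2_co2", "co", "fructose_nitrate"])
def test_carbon_conservation(preset):
    cfg = CoreModelConfig()
    model = apply_medium(build_core_model(cfg), medium_preset(preset))
    sol = parsimonious_solution(model)
    bal = carbon_exchange_balance(model, sol, objective_carbon=cfg.biomass_carbon)
    assert abs(bal["residual"]) < 1e-6


def test_relaxing_uptake_never_decreases_growth():
    model = build_core_model()
    base = fba(apply_medium(model, medium_preset("fructose")))
    for uptake in (2.5, 5.0, 10.0):
        relaxed = fba(apply_medium(model, medium_preset("fructose", fructose_uptake=uptake)))
        assert relaxed.objective_value >= base.objective_value - 1e-9
        base = relaxed


def test_unknown_exchange_in_medium_raises():
    with pytest.raises(KeyError):
        apply_medium(build_core_model(), {"PTAr": (-1.0, 0.0)})


def test_empty_medium_closes_all_uptakes():
    model = apply_medium(build_core_model(), {})
    for r in model.exchanges:
        assert r.lower_bound == 0.0
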