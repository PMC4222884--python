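"""Scenario analyses: equivalent ledgers, ATP accounting, knockout panels.

Expected values are frozen from hand-balanced stoichiometry of the
Wood-Ljungdahl reaction set (worked out by hand before implementation):
per acetyl-CoA from 2 CO2 the methyl/carbonyl branches consume 1 NADPH
(MTHFD), net 1 reduced ferredoxin (FDH7 + CODH/ACS minus the MTHFR5
bifurcation return) and 2 NADH (MTHFR5), plus 1 ATP (FTHFLi); ethanol
adds 2 NADH (ACALD + ALCD2x).
"""

from fractions import Fraction

import pytest

from cljflux.core_model import medium_preset
from cljflux.errors import InfeasibleScenario
from cljflux.scenarios import (
    acka_panel,
    energy_gap_analysis,
    nitrate_scenario,
    reducing_equivalent_audit,
    rnf_flux_is_unique,
    substrate_growth_screen,
)


def test_accoa_demand_ledger_exact(core_model):
    led = reducing_equivalent_audit(core_model, "accoa", "co2")
    assert led.exact
    assert (led.nadh, led.nadph, led.fdx) == (Fraction(2), Fraction(1), Fraction(1))
    assert led.atp_substrate_level == Fraction(1)
    assert led.total_equivalents == Fraction(4)


def test_ethanol_adds_two_nadh(core_model):
    accoa = reducing_equivalent_audit(core_model, "accoa", "co2")
    etoh = reducing_equivalent_audit(core_model, "etoh", "co2")
    assert etoh.nadh - accoa.nadh == Fraction(2)
    assert etoh.total_equivalents == Fraction(6)
    # 6 two-electron units = the 12 electrons of ethanol from 2 CO2
    assert etoh.total_equivalents * 2 == 12


def test_co_supplies_all_six_as_ferredoxin(core_model):
    led = reducing_equivalent_audit(core_model, "etoh", "co", interconverters="enabled")
    assert led.view == "supply"
    assert led.fdx == Fraction(6)
    assert led.nadh == 0 and led.nadph == 0


def test_h2_supply_split_depends_on_hydrogenase(core_model, core_model_nad):
    nadp = reducing_equivalent_audit(core_model, "etoh", "h2", interconverters="enabled")
    assert (nadp.nadph, nadp.fdx, nadp.nadh) == (Fraction(3), Fraction(3), 0)
    nad = reducing_equivalent_audit(core_model_nad, "etoh", "h2", interconverters="enabled")
    assert (nad.nadh, nad.fdx, nad.nadph) == (Fraction(3), Fraction(3), 0)


def test_totals_invariant_to_hydrogenase_config(core_model, core_model_nad):
    for model in (core_model, core_model_nad):
        led = reducing_equivalent_audit(model, "etoh", "h2", interconverters="enabled")
        assert led.total_equivalents == Fraction(6)


def test_infeasible_product_raises(core_model):
    work = core_model.copy()
    work.knock_out_reaction("FTHFLi")
    with pytest.raises(InfeasibleScenario):
        reducing_equivalent_audit(work, "accoa", "co2")


# -- ATP accounting -------------------------------------------------------

def test_nadp_hydrogenase_yields_one_and_a_half_atp(core_model):
    rep = energy_gap_analysis(core_model, medium_preset("h2_co2"), "etoh", ("ackA",))
    assert rep.atp_from_pmf == pytest.approx(1.5, abs=1e-6)
    assert rep.translocated_proton_flux == pytest.approx(6.0, abs=1e-6)
    assert rep.atp_deficit == 0.0
    assert rep.atp_surplus == pytest.approx(0.5, abs=1e-6)
    assert rep.feasible_for_growth


def test_nad_hydrogenase_yields_three_quarter_atp(core_model_nad):
    rep = energy_gap_analysis(core_model_nad, medium_preset("h2_co2"), "etoh", ("ackA",))
    assert rep.atp_from_pmf == pytest.approx(0.75, abs=1e-6)
    assert rep.atp_deficit > 0.2  # shortfall against the 1 ATP of FTHFLi
    assert not rep.feasible_for_growth
    assert rep.fluxes["HYD"] == pytest.approx(3.0, abs=1e-6)


def test_at_most_one_of_deficit_surplus_positive(core_model, core_model_nad):
    for model in (core_model, core_model_nad):
        rep = energy_gap_analysis(model, medium_preset("h2_co2"), "etoh", ("ackA",))
        assert min(rep.atp_deficit, rep.atp_surplus) == 0.0


def test_co_yields_two_and_a_quarter_atp(core_model):
    rep = energy_gap_analysis(core_model, medium_preset("co"), "etoh", ("ackA",))
    assert rep.atp_from_pmf == pytest.approx(2.25, abs=1e-6)
    assert rep.atp_deficit == 0.0


def test_atp_from_pmf_invariant_across_alternate_optima(core_model, core_model_nad):
    assert rnf_flux_is_unique(core_model, medium_preset("h2_co2"), "etoh", ("ackA",))
    assert rnf_flux_is_unique(core_model_nad, medium_preset("h2_co2"), "etoh", ("ackA",))
    assert rnf_flux_is_unique(core_model, medium_preset("co"), "etoh", ("ackA",))


# -- ackA panel -----------------------------------------------------------

def test_acka_feasibility_pattern():
    df = acka_panel().set_index(["hydrogenase", "medium"])
    assert df.loc[("nadp", "fructose"), "ko_feasible"]
    assert df.loc[("nad", "fructose"), "ko_feasible"]
    assert df.loc[("nadp", "co"), "ko_feasible"]
    assert df.loc[("nad", "co"), "ko_feasible"]
    assert df.loc[("nadp", "h2_co2"), "ko_feasible"]
    assert not df.loc[("nad", "h2_co2"), "ko_feasible"]
    assert (df["wt_growth"] > 0).all()


def test_acka_knockout_shifts_flux_to_ethanol():
    df = acka_panel().set_index(["hydrogenase", "medium"])
    row = df.loc[("nadp", "fructose")]
    assert row["wt_main_product"] == "ac"
    assert row["ko_main_product"] == "etoh"


# -- nitrate --------------------------------------------------------------

def test_nitrate_lowers_acetate_flux():
    out = nitrate_scenario()
    assert out["relative_change"] < 0
    assert out["acetate_flux_no3"] < out["acetate_flux_nh4"]


def test_nitrate_nitrogen_balance_closes():
    out = nitrate_scenario()
    assert out["nitrogen_residual"] == pytest.approx(0.0, abs=1e-6)
    assert out["no3_consumption"] == pytest.approx(
        out["nh4_secretion"] + out["biomass_nitrogen"], abs=1e-6
    )


def test_forced_nitrate_without_biomass_is_stoichiometric(core_model):
    """All nitrogen of a forced nitrate uptake leaves as ammonium when
    biomass is blocked — nitrate -> nitrite -> hydroxylamine -> NH4."""
    from cljflux.fba import apply_medium, parsimonious_solution

    cond = apply_medium(core_model, medium_preset("fructose_nitrate"))
    cond.set_bounds("BIOMASS", 0.0, 0.0)
    cond.set_bounds("EX_no3", -1.0, -1.0)
    sol = parsimonious_solution(cond, "EX_nh4")
    assert sol.ok
    assert sol.fluxes["EX_nh4"] == pytest.approx(1.0, abs=1e-6)


def test_no_nitrogen_source_no_growth(core_model):
    from cljflux.fba import apply_medium, fba, knockout_genes

    cond = apply_medium(core_model, medium_preset("fructose_nitrate"))
    cond = knockout_genes(cond, ["CLJU_c23710"])  # nitrate reductase
    sol = fba(cond)
    assert not sol.ok or sol.objective_value < 1e-9


# -- substrate screen -----------------------------------------------------

def test_formate_is_slowest_substrate():
    df = substrate_growth_screen().set_index("substrate")
    formate = df.loc["formate", "growth"]
    assert formate > 1e-6
    assert formate <= df["growth"].min() + 1e-9
    for other in ("fructose", "pyruvate", "h2_co2"):
        assert formate < df.loc[other, "growth"] - 1e-9


def test_unknown_substrate_skipped_with_warning():
    with pytest.warns(UserWarning, match="glucose"):
        df = substrate_growth_screen(substrates=["glucose", "fructose"])
    assert list(df["substrate"]) == ["fructose"]
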