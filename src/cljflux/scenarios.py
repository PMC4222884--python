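"""Scenario analyses on the core model.

Four families of analyses, mirroring how acetogen energetics are audited
in the field:

* reducing-equivalent audits — how many two-electron carrier units
  (NADH, NADPH, reduced ferredoxin) and substrate-level ATP a product
  costs, either as pathway demand (carrier interconverters disabled,
  pseudo-supplies measured) or as realized supply (which donor reactions
  actually source the electrons);
* energy-gap analysis — ATP generated at the Rnf/ATP-synthase couple per
  unit product, with a penalized diagnostic ATP source quantifying any
  shortfall;
* the acetate-kinase knockout panel across electron donors and
  hydrogenase cofactor specificity;
* the nitrate-versus-ammonium nitrogen-source comparison on fructose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .core_model import (
    DONOR_REACTIONS,
    INTERCONVERTER_REACTIONS,
    CoreModelConfig,
    build_core_model,
    medium_preset,
)
from .errors import InfeasibleScenario
from .fba import (
    GROWTH_EPS,
    FluxSolution,
    apply_medium,
    fba,
    fva,
    knockout_genes,
    parsimonious_solution,
)
from .model import MetabolicModel, Reaction

__all__ = [
    "EquivalentLedger",
    "EnergyReport",
    "reducing_equivalent_audit",
    "energy_gap_analysis",
    "acka_panel",
    "nitrate_scenario",
    "substrate_growth_screen",
]

#: secreted fermentation products considered "competing" in fixed-product runs
PRODUCT_EXCHANGES = ("EX_ac", "EX_etoh", "EX_lac", "EX_23btd", "EX_for", "EX_h2")

_FEAS_TOL = 1e-6


@dataclass(frozen=True)
class EquivalentLedger:
    """Per-carrier two-electron equivalents per unit product flux.

    ``view`` is ``"demand"`` (net pathway consumption, interconverters
    disabled) or ``"supply"`` (carrier production by electron-donor
    reactions with the full network active).  Values are exact rationals
    whenever the underlying flux vector certifies exactly.
    """

    product_id: str
    nadh: Fraction | float
    nadph: Fraction | float
    fdx: Fraction | float
    atp_substrate_level: Fraction | float
    view: str = "demand"
    exact: bool = False

    @property
    def total_equivalents(self):
        return self.nadh + self.nadph + self.fdx


@dataclass(frozen=True)
class EnergyReport:
    """ATP bookkeeping at the Rnf/ATP-synthase couple for one scenario.

    ``translocated_proton_flux`` is protons pumped by Rnf per unit
    product; ``atp_from_pmf`` divides it by the synthase H+/ATP ratio.
    ``atp_deficit`` is the flux through a penalized diagnostic ATP source
    needed to sustain the product (0 when the scenario is self-
    sufficient); ``atp_surplus`` the maximal maintenance ATP drain with
    the diagnostic removed.  At most one of the two is positive.
    """

    product_id: str
    translocated_proton_flux: float
    atp_from_pmf: float
    atp_deficit: float
    atp_surplus: float
    feasible_for_growth: bool
    fluxes: dict[str, float] | None = None


def _rnf_atps_ratios(model: MetabolicModel) -> tuple[float, float]:
    """(protons translocated per Rnf turnover, protons per ATP at the synthase)."""
    p = model.reaction("RNF").stoichiometry.get("h_e", 0.0)
    q = -model.reaction("ATPS").stoichiometry.get("h_e", 0.0)
    if p <= 0 or q <= 0:
        raise ValueError("model lacks Rnf/ATPS proton stoichiometry")
    return p, q


def _block_products(model: MetabolicModel, keep: str | None) -> None:
    """Close secretion of every fermentation product except ``keep``.

    Uptake bounds are left untouched so a product species serving as the
    scenario's substrate (e.g. H2) is unaffected.
    """
    for ex in PRODUCT_EXCHANGES:
        if model.has_reaction(ex) and ex != keep:
            r = model.reaction(ex)
            model.set_bounds(ex, min(r.lower_bound, 0.0), 0.0)


def _fix_product(model: MetabolicModel, product_id: str) -> str:
    """Fix production of ``product_id`` at one unit; return the fixed reaction id.

    ``accoa`` (an internal precursor) gets a lumped drain returning the
    CoA moiety; secreted products are fixed at their exchange.
    """
    if product_id in ("accoa", "accoa_c"):
        model.add_reaction(
            Reaction(
                id="DM_accoa",
                stoichiometry={"accoa_c": -1.0, "coa_c": 1.0},
                lower_bound=1.0,
                upper_bound=1.0,
                subsystem="diagnostic",
                balance_exempt=True,
            )
        )
        return "DM_accoa"
    ex = f"EX_{product_id.removeprefix('EX_')}"
    if not model.has_reaction(ex):
        raise KeyError(f"no exchange for product {product_id!r}")
    model.set_bounds(ex, 1.0, 1.0)
    return ex


def _rationalize(model: MetabolicModel, sol: FluxSolution, max_den: int = 10000):
    """Certify a flux vector as exact rationals, or return None.

    Rounds each flux to a small-denominator rational and re-checks every
    metabolite balance in exact arithmetic against the (rational)
    stoichiometry.  Succeeds precisely when the LP vertex is rational
    with modest denominators — the case for all core-model audits.
    """
    rational = {
        rid: Fraction(v).limit_denominator(max_den) for rid, v in sol.fluxes.items()
    }
    for rid, v in sol.fluxes.items():
        if abs(float(rational[rid]) - v) > 1e-6:
            return None
    net: dict[str, Fraction] = {m.id: Fraction(0) for m in model.metabolites}
    for r in model.reactions:
        v = rational.get(r.id, Fraction(0))
        if v == 0:
            continue
        for met_id, coeff in r.stoichiometry.items():
            net[met_id] += Fraction(coeff).limit_denominator(max_den) * v
    if any(x != 0 for x in net.values()):
        return None
    return rational


def reducing_equivalent_audit(
    model: MetabolicModel,
    product_id: str,
    carbon_source: str = "co2",
    interconverters: str = "disabled",
) -> EquivalentLedger:
    """Audit the reducing equivalents behind one unit of product flux.

    With ``interconverters="disabled"`` (demand view) the carrier
    interconverters and electron-donor reactions are switched off,
    unbalanced pseudo-supplies for NADH/NADPH/reduced ferredoxin/ATP are
    added, product flux is fixed at 1, and the minimal total supply is
    attributed per carrier — the pathway's intrinsic requirement.

    With ``interconverters="enabled"`` (supply view) the full network
    runs on the stated carbon/electron source and the ledger reports the
    carrier production of the electron-donor reactions (hydrogenase, CO
    dehydrogenase, glycolysis, PFOR) in the parsimonious solution —
    i.e. in which currency the electrons actually arrive.
    """
    if interconverters not in ("disabled", "enabled"):
        raise ValueError("interconverters must be 'disabled' or 'enabled'")
    work = model.copy()
    # close every uptake, then open the carbon/electron source and minerals
    for r in work.exchanges:
        work.set_bounds(r.id, 0.0, max(r.upper_bound, 0.0))
    for ex in ("EX_h2o", "EX_h", "EX_pi"):
        work.set_bounds(ex, -1000.0, 1000.0)
    src = f"EX_{carbon_source.removeprefix('EX_')}"
    if not work.has_reaction(src):
        raise KeyError(f"unknown carbon source exchange {src!r}")
    work.set_bounds(src, -1000.0, 0.0)
    if carbon_source in ("co", "h2"):
        # oxidation of the donor releases CO2; let it leave/enter freely
        work.set_bounds("EX_co2", -1000.0, 1000.0)
    work.set_bounds("BIOMASS", 0.0, 0.0)

    keep = None if product_id in ("accoa", "accoa_c") else f"EX_{product_id.removeprefix('EX_')}"
    _block_products(work, keep)
    fixed_id = _fix_product(work, product_id)

    if interconverters == "disabled":
        return _demand_ledger(work, product_id)
    return _supply_ledger(work, product_id, fixed_id)


_SUPPLY_SPECS = {
    "SUP_nadh": {"nad_c": -1.0, "nadh_c": 1.0},
    "SUP_nadph": {"nadp_c": -1.0, "nadph_c": 1.0},
    "SUP_fdx": {"fdxo_c": -1.0, "fdxr_c": 1.0},
    "SUP_atp": {"adp_c": -1.0, "pi_c": -1.0, "atp_c": 1.0},
}


def _demand_ledger(work: MetabolicModel, product_id: str) -> EquivalentLedger:
    # the demand view strips out everything that trades carriers or ATP
    # for the proton-motive force: what remains is the pathway itself
    for rid in INTERCONVERTER_REACTIONS + DONOR_REACTIONS + ("ATPS", "ATPM"):
        if work.has_reaction(rid):
            work.knock_out_reaction(rid)
    for rid, stoich in _SUPPLY_SPECS.items():
        work.add_reaction(
            Reaction(id=rid, stoichiometry=dict(stoich), lower_bound=0.0,
                     upper_bound=1000.0, subsystem="diagnostic", balance_exempt=True)
        )
    # protons and water are not part of the equivalent count; free them
    for rid, met in (("SUP_h", "h_c"), ("SUP_h2o", "h2o_c")):
        work.add_reaction(
            Reaction(id=rid, stoichiometry={met: 1.0}, lower_bound=-1000.0,
                     upper_bound=1000.0, subsystem="diagnostic", balance_exempt=True)
        )
    # aggregate redox supply, to be minimized first
    tally = Reaction(
        id="SUP_total", stoichiometry={}, lower_bound=0.0, upper_bound=4000.0,
        subsystem="diagnostic", balance_exempt=True,
    )
    # implement the aggregate via a pseudo-metabolite produced by each supply
    eq = "redequiv_c"
    from .model import Metabolite, build_model  # local to avoid cycle at import

    mets = list(work.metabolites) + [Metabolite(id=eq, name="redox equivalent", compartment="c")]
    for rid in ("SUP_nadh", "SUP_nadph", "SUP_fdx"):
        work.reaction(rid).stoichiometry[eq] = 1.0
    tally.stoichiometry = {eq: -1.0}
    rebuilt = build_model(mets, [r.copy() for r in work.reactions] + [tally],
                          genes=work.genes, objective_id=work.objective_id)

    sol = fba(rebuilt, "SUP_total", direction="min")
    if not sol.ok:
        raise InfeasibleScenario(
            f"product {product_id!r} cannot be formed even with free carriers"
        )
    rebuilt.set_bounds("SUP_total", sol.objective_value, sol.objective_value)
    psol = parsimonious_solution(rebuilt, "SUP_total")
    rational = _rationalize(rebuilt, psol)
    get = (lambda rid: rational[rid]) if rational else (lambda rid: psol.fluxes[rid])
    return EquivalentLedger(
        product_id=product_id,
        nadh=get("SUP_nadh"),
        nadph=get("SUP_nadph"),
        fdx=get("SUP_fdx"),
        atp_substrate_level=get("SUP_atp"),
        view="demand",
        exact=rational is not None,
    )


def _supply_ledger(work: MetabolicModel, product_id: str, fixed_id: str) -> EquivalentLedger:
    # a diagnostic ATP source keeps ATP-infeasible scenarios auditable
    # (e.g. ethanol on H2 with the NAD-specific hydrogenase); it carries
    # zero flux whenever the scenario is self-sufficient
    work.add_reaction(
        Reaction(id="ATP_DIAG", stoichiometry={"adp_c": -1.0, "pi_c": -1.0, "atp_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0, subsystem="diagnostic",
                 balance_exempt=True)
    )
    probe = fba(work, "ATP_DIAG", direction="min")
    if not probe.ok:
        raise InfeasibleScenario(
            f"product {product_id!r} unreachable on this electron source"
        )
    work.set_bounds("ATP_DIAG", probe.objective_value, probe.objective_value)
    psol = parsimonious_solution(work, fixed_id, lexicographic=True)
    rational = _rationalize(work, psol)

    def production(carrier: str):
        total = Fraction(0) if rational else 0.0
        for rid in DONOR_REACTIONS:
            if not work.has_reaction(rid):
                continue
            coeff = work.reaction(rid).stoichiometry.get(carrier, 0.0)
            if coeff > 0:
                v = rational[rid] if rational else psol.fluxes[rid]
                total += (Fraction(coeff) if rational else coeff) * v
        return total

    # substrate-level ATP: net production by kinase-coupled steps
    slp = Fraction(0) if rational else 0.0
    for rid in ("ACKr", "GLYC"):
        if work.has_reaction(rid):
            coeff = work.reaction(rid).stoichiometry.get("atp_c", 0.0)
            v = rational[rid] if rational else psol.fluxes[rid]
            slp += (Fraction(coeff) if rational else coeff) * v
    return EquivalentLedger(
        product_id=product_id,
        nadh=production("nadh_c"),
        nadph=production("nadph_c"),
        fdx=production("fdxr_c"),
        atp_substrate_level=slp,
        view="supply",
        exact=rational is not None,
    )


def energy_gap_analysis(
    model: MetabolicModel,
    medium: dict,
    product_id: str,
    knockouts: tuple[str, ...] | list[str] = (),
    block_competing: bool = True,
) -> EnergyReport:
    """ATP balance at unit product flux under a medium and knockouts.

    Fixes the product at 1, applies the gene knockouts, adds a penalized
    diagnostic ATP source (ADP + Pi -> ATP) and minimizes its flux: the
    minimum is the ATP deficit the network cannot cover.  Reports Rnf
    proton translocation and the corresponding ATP at the synthase from
    the parsimonious solution with the deficit pinned; the surplus is the
    maximal maintenance (ATPM) flux with the diagnostic removed.
    """
    p, q = _rnf_atps_ratios(model)
    work = apply_medium(model, medium)
    if knockouts:
        work = knockout_genes(work, knockouts)
    work.set_bounds("BIOMASS", 0.0, 0.0)
    keep = f"EX_{product_id.removeprefix('EX_')}"
    if block_competing:
        _block_products(work, keep)
    _fix_product(work, product_id)

    work.add_reaction(
        Reaction(id="ATP_DIAG", stoichiometry={"adp_c": -1.0, "pi_c": -1.0, "atp_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0, subsystem="diagnostic",
                 balance_exempt=True)
    )
    diag_sol = fba(work, "ATP_DIAG", direction="min")
    if not diag_sol.ok:
        raise InfeasibleScenario(
            f"product {product_id!r} unreachable even with the diagnostic ATP source"
        )
    deficit = max(diag_sol.objective_value, 0.0)
    work.set_bounds("ATP_DIAG", deficit, deficit)
    psol = parsimonious_solution(work, "ATP_DIAG")
    translocated = p * psol.fluxes["RNF"]
    atp_from_pmf = translocated / q

    surplus = 0.0
    if deficit <= _FEAS_TOL:
        work.set_bounds("ATP_DIAG", 0.0, 0.0)
        smax = fba(work, "ATPM", direction="max")
        if smax.ok:
            surplus = max(smax.objective_value, 0.0)
    return EnergyReport(
        product_id=product_id,
        translocated_proton_flux=translocated,
        atp_from_pmf=atp_from_pmf,
        atp_deficit=deficit if deficit > _FEAS_TOL else 0.0,
        atp_surplus=surplus,
        feasible_for_growth=deficit <= _FEAS_TOL,
        fluxes=psol.fluxes,
    )


def acka_panel(fructose_uptake: float = 1.88) -> pd.DataFrame:
    """Acetate-kinase knockout feasibility across donors and hydrogenase cofactors.

    For each (hydrogenase cofactor) x (fructose, CO, H2/CO2) cell:
    wild-type growth, ackA-knockout growth, a feasibility flag and the
    dominant secreted product before/after the knockout.
    """
    rows = []
    for cofactor in ("nadp", "nad"):
        model = build_core_model(CoreModelConfig(hydrogenase_cofactor=cofactor))
        for preset in ("fructose", "co", "h2_co2"):
            medium = medium_preset(preset, fructose_uptake=fructose_uptake)
            cond = apply_medium(model, medium)
            wt = parsimonious_solution(cond)
            ko_model = knockout_genes(cond, ["ackA"])
            ko_fba = fba(ko_model)
            ko_growth = ko_fba.objective_value if ko_fba.ok else 0.0
            feasible = ko_growth > GROWTH_EPS
            ko = parsimonious_solution(ko_model) if feasible else None
            rows.append({
                "hydrogenase": cofactor,
                "medium": preset,
                "wt_growth": wt.objective_value if wt.ok else 0.0,
                "ko_growth": ko_growth if feasible else 0.0,
                "ko_feasible": feasible,
                "wt_main_product": _main_product(wt),
                "ko_main_product": _main_product(ko) if ko else None,
            })
    return pd.DataFrame(rows)


def _main_product(sol: FluxSolution | None) -> str | None:
    if sol is None or not sol.ok:
        return None
    best, best_v = None, GROWTH_EPS
    for ex in PRODUCT_EXCHANGES:
        v = sol.fluxes.get(ex, 0.0)
        if v > best_v:
            best, best_v = ex.removeprefix("EX_"), v
    return best


def nitrate_scenario(
    model: MetabolicModel | None = None, fructose_uptake: float = 1.88
) -> dict[str, float]:
    """Acetate flux and nitrogen balance: ammonium vs nitrate-only nitrogen.

    Runs growth-maximizing parsimonious FBA at equal fructose uptake on
    the ammonium medium and on the ammonium-free nitrate medium, and
    reports acetate fluxes, their relative change, and the nitrate-run
    nitrogen mass balance (consumed nitrate vs secreted ammonium plus
    biomass nitrogen).
    """
    model = model or build_core_model()
    n_per_biomass = -model.reaction("BIOMASS").stoichiometry.get("nh4_c", 0.0)

    out: dict[str, float] = {}
    sols = {}
    for label, preset in (("nh4", "fructose"), ("no3", "fructose_nitrate")):
        cond = apply_medium(model, medium_preset(preset, fructose_uptake=fructose_uptake))
        sol = parsimonious_solution(cond)
        if not sol.ok:
            raise InfeasibleScenario(f"{preset} medium does not support growth")
        sols[label] = sol
        out[f"growth_{label}"] = sol.objective_value
        out[f"acetate_flux_{label}"] = sol.fluxes.get("EX_ac", 0.0)
    out["relative_change"] = (
        (out["acetate_flux_no3"] - out["acetate_flux_nh4"]) / out["acetate_flux_nh4"]
    )
    no3 = sols["no3"]
    out["no3_consumption"] = -no3.fluxes.get("EX_no3", 0.0)
    out["nh4_secretion"] = no3.fluxes.get("EX_nh4", 0.0)
    out["biomass_nitrogen"] = n_per_biomass * no3.objective_value
    out["nitrogen_residual"] = (
        out["no3_consumption"] - out["nh4_secretion"] - out["biomass_nitrogen"]
    )
    return out


_SCREEN_PRIMARY = {
    "fructose": "EX_fru",
    "pyruvate": "EX_pyr",
    "formate": "EX_for",
    "co": "EX_co",
    "h2_co2": None,  # Table-style paired uptake kept at its preset values
}


def substrate_growth_screen(
    model: MetabolicModel | None = None,
    substrates: list[str] | None = None,
    uptake: float = 5.0,
) -> pd.DataFrame:
    """Growth and acetate production per substrate at a common uptake rate.

    Single-substrate conditions are capped at ``uptake`` mmol/gDW/h;
    the H2/CO2 condition keeps its paired 10/20 caps.  Unknown substrates
    are skipped with a warning.
    """
    model = model or build_core_model()
    substrates = substrates or list(_SCREEN_PRIMARY)
    rows = []
    for sub in substrates:
        if sub not in _SCREEN_PRIMARY:
            warnings.warn(f"substrate {sub!r} not in the core model; skipped", stacklevel=2)
            continue
        medium = medium_preset(sub if sub != "fructose" else "fructose")
        primary = _SCREEN_PRIMARY[sub]
        if primary is not None:
            lo, hi = medium[primary]
            medium[primary] = (-uptake, hi)
        cond = apply_medium(model, medium)
        sol = parsimonious_solution(cond)
        rows.append({
            "substrate": sub,
            "growth": sol.objective_value if sol.ok else 0.0,
            "acetate": sol.fluxes.get("EX_ac", 0.0) if sol.ok else 0.0,
        })
    return pd.DataFrame(rows)


def rnf_flux_is_unique(
    model: MetabolicModel,
    medium: dict,
    product_id: str,
    knockouts: tuple[str, ...] = (),
    tol: float = 1e-6,
) -> bool:
    """FVA check that Rnf flux is pinned in a fixed-product scenario.

    Supports the claim that atp_from_pmf is invariant across alternate
    optima: the Rnf range must have zero width once the product flux is
    fixed and the ATP deficit minimized.
    """
    work = apply_medium(model, medium)
    if knockouts:
        work = knockout_genes(work, knockouts)
    work.set_bounds("BIOMASS", 0.0, 0.0)
    _block_products(work, f"EX_{product_id.removeprefix('EX_')}")
    _fix_product(work, product_id)
    work.add_reaction(
        Reaction(id="ATP_DIAG", stoichiometry={"adp_c": -1.0, "pi_c": -1.0, "atp_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0, balance_exempt=True)
    )
    diag = fba(work, "ATP_DIAG", direction="min")
    if not diag.ok:
        raise InfeasibleScenario("scenario infeasible")
    work.set_bounds("ATP_DIAG", diag.objective_value, diag.objective_value)
    lo, hi = fva(work, objective_fraction=0.0, reactions=["RNF"])["RNF"]
    return (hi - lo) < tol
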