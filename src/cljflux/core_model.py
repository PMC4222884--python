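"""Curated core reconstruction of *Clostridium ljungdahlii* metabolism.

The model is executable data: the Wood-Ljungdahl pathway (methyl branch
FDH7 -> FTHFLi -> MTHFC -> MTHFD -> MTHFR5 -> METR plus the net CODH/ACS
carbonyl step), flavin-based electron bifurcation (MTHFR5, HydABC
hydrogenase, Nfn transhydrogenase), Rnf-dependent proton translocation
with ATP synthase, fermentation branches (acetate, ethanol, lactate,
2,3-butanediol), a nitrate -> nitrite -> hydroxylamine -> ammonium
assimilation pathway, a lumped EMP glycolysis, and a four-precursor
lumped biomass drain.

Every non-exchange, non-lumped reaction is elementally and charge
balanced using standard biochemistry formulas (protonation states at
pH 7).  Ferredoxin is a two-electron carrier pair fdxo/fdxr, so one
reduced ferredoxin is one reducing equivalent on the same footing as
NAD(P)H.  Cytosolic protons are mass-balanced; the extracellular proton
pool has an exchange, and the only reactions moving protons across the
membrane are Rnf, ATP synthase and acid/anion symporters — which makes
proton-motive-force accounting explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError
from .fba import Medium
from .model import MetabolicModel, Metabolite, Reaction, build_model, formula_from_string

__all__ = ["CoreModelConfig", "build_core_model", "medium_preset", "MEDIUM_PRESETS"]


@dataclass(frozen=True)
class CoreModelConfig:
    """Tunable stoichiometric parameters of the core model.

    hydrogenase_cofactor
        Cofactor of the electron-bifurcating hydrogenase: ``"nadp"``
        (default) or ``"nad"``.
    rnf_protons_per_fd / atps_protons_per_atp
        Protons translocated by Rnf per ferredoxin oxidized, and consumed
        by ATP synthase per ATP.  Defaults 2 and 4 give 0.5 ATP per
        ferredoxin, the ratio fixed by the published 1.5 / 0.75 ATP
        yields; only the ratio matters.
    biomass_* coefficients
        mmol of each precursor drained per gDW of biomass.
    protein_fraction
        Cell protein mass fraction (0.43); documentation of the biomass
        nitrogen demand's provenance.
    ngam
        Non-growth-associated maintenance ATP (lower bound of ATPM),
        mmol/gDW/h; default 0.
    """

    hydrogenase_cofactor: str = "nadp"
    rnf_protons_per_fd: int = 2
    atps_protons_per_atp: int = 4
    biomass_accoa: float = 20.0
    biomass_atp: float = 40.0
    biomass_nadph: float = 10.0
    biomass_nh4: float = 8.0
    protein_fraction: float = 0.43
    ngam: float = 0.0

    def validate(self) -> None:
        if self.hydrogenase_cofactor not in ("nadp", "nad"):
            raise ConfigError(
                f"hydrogenase_cofactor must be 'nadp' or 'nad', got "
                f"{self.hydrogenase_cofactor!r}"
            )
        for name in ("biomass_accoa", "biomass_atp", "biomass_nadph", "biomass_nh4", "ngam"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not (0 < self.protein_fraction < 1):
            raise ConfigError("protein_fraction must be in (0, 1)")
        if self.rnf_protons_per_fd < 1 or self.atps_protons_per_atp < 1:
            raise ConfigError("proton stoichiometries must be positive integers")
        # one fdxr carries two electrons; translocating >= 2 protons per
        # proton-ATP-equivalent would close a free-energy loop with the synthase
        if self.rnf_protons_per_fd >= 2 * self.atps_protons_per_atp:
            raise ConfigError(
                "rnf_protons_per_fd must be < 2 * atps_protons_per_atp "
                "(prevents an Rnf/ATP-synthase perpetuum mobile)"
            )

    @property
    def biomass_carbon(self) -> float:
        """mmol carbon drained per gDW (acetyl moiety of acetyl-CoA, 2 C)."""
        return 2.0 * self.biomass_accoa


# -- metabolite table -----------------------------------------------------
# (id stem, name, formula, charge); cytosolic unless listed in _E_SPECIES
_METS: list[tuple[str, str, str, int]] = [
    ("fru", "D-fructose", "C6H12O6", 0),
    ("pyr", "pyruvate", "C3H3O3", -1),
    ("accoa", "acetyl-CoA", "C23H34N7O17P3S", -4),
    ("coa", "coenzyme A", "C21H32N7O16P3S", -4),
    ("actp", "acetyl phosphate", "C2H3O5P", -2),
    ("ac", "acetate", "C2H3O2", -1),
    ("acald", "acetaldehyde", "C2H4O", 0),
    ("etoh", "ethanol", "C2H6O", 0),
    ("lac", "D-lactate", "C3H5O3", -1),
    ("23btd", "2,3-butanediol", "C4H10O2", 0),
    ("for", "formate", "CHO2", -1),
    ("co2", "carbon dioxide", "CO2", 0),
    ("co", "carbon monoxide", "CO", 0),
    ("h2", "dihydrogen", "H2", 0),
    ("thf", "tetrahydrofolate", "C19H21N7O6", -2),
    ("10fthf", "10-formyl-THF", "C20H21N7O7", -2),
    ("methf", "5,10-methenyl-THF", "C20H20N7O6", -1),
    ("mlthf", "5,10-methylene-THF", "C20H21N7O6", -2),
    ("5mthf", "5-methyl-THF", "C20H24N7O6", -1),
    ("cfesp", "corrinoid iron-sulfur protein", "", 0),
    ("mecfesp", "methyl-corrinoid iron-sulfur protein", "", 0),
    ("fdxo", "oxidized ferredoxin", "Fe2S2", 0),
    ("fdxr", "reduced ferredoxin", "Fe2S2", -2),
    ("nad", "NAD+", "C21H26N7O14P2", -1),
    ("nadh", "NADH", "C21H27N7O14P2", -2),
    ("nadp", "NADP+", "C21H25N7O17P3", -3),
    ("nadph", "NADPH", "C21H26N7O17P3", -4),
    ("atp", "ATP", "C10H12N5O13P3", -4),
    ("adp", "ADP", "C10H12N5O10P2", -3),
    ("pi", "orthophosphate", "HO4P", -2),
    ("h", "proton", "H", 1),
    ("h2o", "water", "H2O", 0),
    ("no3", "nitrate", "NO3", -1),
    ("no2", "nitrite", "NO2", -1),
    ("ham", "hydroxylamine", "H3NO", 0),
    ("nh4", "ammonium", "H4N", 1),
]

#: species that also exist extracellularly (and have an exchange)
_E_SPECIES = [
    "fru", "pyr", "h2", "co", "co2", "ac", "etoh", "lac", "23btd",
    "for", "no3", "no2", "nh4", "h", "h2o", "pi",
]

#: electron-donor reactions injecting reducing equivalents from a substrate
DONOR_REACTIONS = ("HYD", "CODH", "GLYC", "GAPN", "PFOR")
#: pure carrier interconverters (move equivalents between pools)
INTERCONVERTER_REACTIONS = ("RNF", "NFN")


def _metabolites() -> list[Metabolite]:
    mets = []
    for stem, name, formula, charge in _METS:
        mets.append(
            Metabolite(
                id=f"{stem}_c",
                name=name,
                formula=formula_from_string(formula) if formula else {},
                charge=charge,
                compartment="c",
            )
        )
    by_stem = {stem: (name, formula, charge) for stem, name, formula, charge in _METS}
    for stem in _E_SPECIES:
        name, formula, charge = by_stem[stem]
        mets.append(
            Metabolite(
                id=f"{stem}_e",
                name=name,
                formula=formula_from_string(formula) if formula else {},
                charge=charge,
                compartment="e",
            )
        )
    return mets


def build_core_model(config: CoreModelConfig | None = None) -> MetabolicModel:
    """Assemble the core network for the given configuration.

    Returns a validated :class:`MetabolicModel` with the biomass drain as
    objective.  Exchange bounds are wide open (+/-1000); apply a medium
    preset before simulating a growth condition.
    """
    cfg = config or CoreModelConfig()
    cfg.validate()

    p = cfg.rnf_protons_per_fd
    q = cfg.atps_protons_per_atp

    R: list[Reaction] = []

    def rxn(rid, stoich, lb, ub, gpr="", subsystem="", name="", **kw):
        R.append(
            Reaction(
                id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                gpr=gpr, subsystem=subsystem, name=name, **kw
            )
        )

    # --- central carbon -------------------------------------------------
    rxn("GLYC",
        {"fru_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
         "pyr_c": 2, "atp_c": 2, "nadh_c": 2, "h2o_c": 2, "h_c": 2},
        0, 1000, gpr="fruK and pfkA", subsystem="glycolysis",
        name="glycolysis, lumped EMP (fructose -> 2 pyruvate)")
    rxn("GAPN",
        {"fru_c": -1, "nadp_c": -2, "pyr_c": 2, "nadph_c": 2, "h_c": 4},
        0, 1000, gpr="gapN", subsystem="glycolysis",
        name="glycolysis via non-phosphorylating NADP-GAPDH (no net ATP)")
    rxn("PFOR",
        {"pyr_c": -1, "coa_c": -1, "fdxo_c": -1,
         "accoa_c": 1, "co2_c": 1, "fdxr_c": 1, "h_c": 1},
        0, 1000, gpr="nifJ", subsystem="pyruvate metabolism",
        name="pyruvate:ferredoxin oxidoreductase")

    # --- Wood-Ljungdahl methyl branch ------------------------------------
    rxn("FDH7",
        {"co2_c": -1, "fdxr_c": -1, "h_c": -1, "for_c": 1, "fdxo_c": 1},
        -1000, 1000, gpr="fdhA", subsystem="Wood-Ljungdahl pathway",
        name="formate dehydrogenase (ferredoxin)")
    rxn("FTHFLi",
        {"for_c": -1, "thf_c": -1, "atp_c": -1,
         "10fthf_c": 1, "adp_c": 1, "pi_c": 1},
        0, 1000, gpr="fhs", subsystem="Wood-Ljungdahl pathway",
        name="formate-tetrahydrofolate ligase")
    rxn("MTHFC",
        {"10fthf_c": -1, "h_c": -1, "methf_c": 1, "h2o_c": 1},
        -1000, 1000, gpr="fchA", subsystem="Wood-Ljungdahl pathway",
        name="methenyl-THF cyclohydrolase")
    rxn("MTHFD",
        {"methf_c": -1, "nadph_c": -1, "mlthf_c": 1, "nadp_c": 1},
        -1000, 1000, gpr="CLJU_c37630", subsystem="Wood-Ljungdahl pathway",
        name="methylene-THF dehydrogenase (NADP)")
    rxn("MTHFR5",
        {"mlthf_c": -1, "nadh_c": -2, "fdxo_c": -1, "h_c": -1,
         "5mthf_c": 1, "nad_c": 2, "fdxr_c": 1},
        0, 1000, gpr="CLJU_c37610 and CLJU_c37620",
        subsystem="Wood-Ljungdahl pathway",
        name="methylene-THF reductase, electron bifurcating")
    rxn("METR",
        {"5mthf_c": -1, "cfesp_c": -1, "thf_c": 1, "mecfesp_c": 1},
        0, 1000, gpr="acsE", subsystem="Wood-Ljungdahl pathway",
        name="methyl-THF:corrinoid methyltransferase")
    rxn("CODH_ACS",
        {"mecfesp_c": -1, "co2_c": -1, "fdxr_c": -1, "coa_c": -1, "h_c": -1,
         "accoa_c": 1, "cfesp_c": 1, "fdxo_c": 1, "h2o_c": 1},
        0, 1000, gpr="acsA and acsB", subsystem="Wood-Ljungdahl pathway",
        name="CO dehydrogenase / acetyl-CoA synthase (net)")
    rxn("CODH",
        {"co_c": -1, "h2o_c": -1, "fdxo_c": -1,
         "co2_c": 1, "fdxr_c": 1, "h_c": 2},
        0, 1000, gpr="CLJU_c09090 and CLJU_c09100 and CLJU_c09110",
        subsystem="Wood-Ljungdahl pathway",
        name="carbon monoxide dehydrogenase (CO oxidation)")

    # --- fermentation branches -------------------------------------------
    rxn("PTAr",
        {"accoa_c": -1, "pi_c": -1, "actp_c": 1, "coa_c": 1},
        -1000, 1000, gpr="pta", subsystem="acetate production",
        name="phosphotransacetylase")
    rxn("ACKr",
        {"actp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1},
        -1000, 1000, gpr="ackA", subsystem="acetate production",
        name="acetate kinase")
    rxn("ACALD",
        {"accoa_c": -1, "nadh_c": -1, "h_c": -1,
         "acald_c": 1, "coa_c": 1, "nad_c": 1},
        -1000, 1000, gpr="adhE", subsystem="ethanol production",
        name="acetaldehyde dehydrogenase")
    rxn("ALCD2x",
        {"acald_c": -1, "nadh_c": -1, "h_c": -1, "etoh_c": 1, "nad_c": 1},
        -1000, 1000, gpr="adhE", subsystem="ethanol production",
        name="ethanol dehydrogenase")
    rxn("LDH_D",
        {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "lac_c": 1, "nad_c": 1},
        -1000, 1000, gpr="ldhA", subsystem="fermentation",
        name="D-lactate dehydrogenase")
    rxn("BTDD",
        {"pyr_c": -2, "nadh_c": -1, "h_c": -3,
         "23btd_c": 1, "co2_c": 2, "nad_c": 1},
        0, 1000, gpr="budA and budC", subsystem="fermentation",
        name="2,3-butanediol production, lumped")

    # --- energy conservation ---------------------------------------------
    rxn("RNF",
        {"fdxr_c": -1, "nad_c": -1, "h_c": -(1 + p),
         "fdxo_c": 1, "nadh_c": 1, "h_e": p},
        0, 1000, gpr="rnfC", subsystem="energy conservation",
        name=f"Rnf complex (ferredoxin:NAD+ oxidoreductase, {p} H+ translocated)")
    rxn("ATPS",
        {"adp_c": -1, "pi_c": -1, "h_e": -q,
         "atp_c": 1, "h2o_c": 1, "h_c": q - 1},
        -1000, 1000, gpr="atpE", subsystem="energy conservation",
        name=f"ATP synthase ({q} H+ per ATP)")
    hyd_cof = ("nadp_c", "nadph_c") if cfg.hydrogenase_cofactor == "nadp" else ("nad_c", "nadh_c")
    rxn("HYD",
        {"h2_c": -2, "fdxo_c": -1, hyd_cof[0]: -1,
         "fdxr_c": 1, hyd_cof[1]: 1, "h_c": 3},
        0, 1000, gpr="hydA and hydB and hydC", subsystem="energy conservation",
        name=f"electron-bifurcating hydrogenase ({cfg.hydrogenase_cofactor.upper()}-specific)")
    rxn("NFN",
        {"fdxr_c": -1, "nadh_c": -1, "nadp_c": -2, "h_c": -1,
         "fdxo_c": 1, "nad_c": 1, "nadph_c": 2},
        -1000, 1000, gpr="CLJU_c37240", subsystem="energy conservation",
        name="Nfn electron-bifurcating transhydrogenase")
    rxn("ATPM",
        {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
        cfg.ngam, 1000, subsystem="maintenance",
        name="non-growth-associated maintenance ATPase")

    # --- nitrate reduction ------------------------------------------------
    rxn("NTRARf",
        {"no3_c": -1, "nadh_c": -1, "h_c": -1,
         "no2_c": 1, "nad_c": 1, "h2o_c": 1},
        0, 1000, gpr="CLJU_c23710", subsystem="nitrogen metabolism",
        name="nitrate reductase (soluble, NADH)")
    rxn("NTRIR5",
        {"no2_c": -1, "nadh_c": -2, "h_c": -3,
         "ham_c": 1, "nad_c": 2, "h2o_c": 1},
        0, 1000, gpr="CLJU_c23730", subsystem="nitrogen metabolism",
        name="nitrite reductase (to hydroxylamine, NADH)")
    rxn("HAMR",
        {"ham_c": -1, "nadh_c": -1, "h_c": -2,
         "nh4_c": 1, "nad_c": 1, "h2o_c": 1},
        0, 1000, gpr="hcp", subsystem="nitrogen metabolism",
        name="hydroxylamine reductase (NADH)")

    # --- biomass -----------------------------------------------------------
    a, t, np_, nn = cfg.biomass_accoa, cfg.biomass_atp, cfg.biomass_nadph, cfg.biomass_nh4
    rxn("BIOMASS",
        {"accoa_c": -a, "atp_c": -t, "nadph_c": -np_, "nh4_c": -nn, "h2o_c": -t,
         "coa_c": a, "adp_c": t, "pi_c": t, "nadp_c": np_, "h_c": t},
        0, 1000, subsystem="biomass",
        name="biomass drain (lumped, per gDW)", balance_exempt=True)

    # --- transport ----------------------------------------------------------
    def uniport(rid, stem, lb=-1000, ub=1000, gpr=""):
        rxn(rid, {f"{stem}_e": -1, f"{stem}_c": 1}, lb, ub, gpr=gpr,
            subsystem="transport")

    def symport(rid, stem, lb=-1000, ub=1000, gpr=""):
        rxn(rid, {f"{stem}_e": -1, "h_e": -1, f"{stem}_c": 1, "h_c": 1},
            lb, ub, gpr=gpr, subsystem="transport")

    uniport("FRUt", "fru", 0, 1000)
    symport("PYRt2r", "pyr")
    uniport("H2t", "h2")
    uniport("COt", "co")
    uniport("CO2t", "co2")
    symport("ACt2r", "ac")
    uniport("ETOHt", "etoh")
    symport("LACt2r", "lac")
    uniport("BTDt", "23btd")
    symport("FORt2r", "for")
    symport("NO3t2", "no3", 0, 1000, gpr="CLJU_c23700")
    symport("NO2t2r", "no2", gpr="nirC")
    uniport("NH4t", "nh4", gpr="amt")
    uniport("H2Ot", "h2o")
    uniport("PIt", "pi")

    # --- exchanges -----------------------------------------------------------
    for stem in _E_SPECIES:
        rxn(f"EX_{stem}", {f"{stem}_e": -1}, -1000, 1000,
            subsystem="exchange", is_exchange=True)

    return build_model(_metabolites(), R, genes=None, objective_id="BIOMASS")


_MINERALS: Medium = {
    "EX_h2o": (-1000.0, 1000.0),
    "EX_h": (-1000.0, 1000.0),
    "EX_pi": (-1000.0, 1000.0),
}

MEDIUM_PRESETS = ("fructose", "fructose_nitrate", "h2_co2", "co", "pyruvate", "formate")


def medium_preset(name: str, fructose_uptake: float = 1.88) -> Medium:
    """Exchange-bound sets for the growth conditions analyzed.

    ``fructose``: fructose capped at the measured 1.88 mmol/gDW/h uptake
    with ammonium as nitrogen source; ``fructose_nitrate``: the same but
    ammonium-free with nitrate; ``h2_co2``: CO2 uptake <= 10 and H2 <= 20;
    ``co``: CO uptake <= 20 as sole carbon and electron source;
    ``pyruvate``/``formate``: heterotrophic screens at 5 mmol/gDW/h.
    Water, phosphate and extracellular protons are freely exchanged.
    """
    base: Medium = dict(_MINERALS)
    if name == "fructose":
        base.update({"EX_fru": (-fructose_uptake, 0.0), "EX_nh4": (-10.0, 1000.0)})
    elif name == "fructose_nitrate":
        base.update({
            "EX_fru": (-fructose_uptake, 0.0),
            "EX_no3": (-10.0, 1000.0),
            "EX_nh4": (0.0, 1000.0),  # ammonium-free: secretion only
        })
    elif name == "h2_co2":
        base.update({
            "EX_co2": (-10.0, 1000.0),
            "EX_h2": (-20.0, 0.0),
            "EX_nh4": (-10.0, 1000.0),
        })
    elif name == "co":
        base.update({"EX_co": (-20.0, 0.0), "EX_nh4": (-10.0, 1000.0)})
    elif name == "pyruvate":
        base.update({"EX_pyr": (-5.0, 0.0), "EX_nh4": (-10.0, 1000.0)})
    elif name == "formate":
        base.update({"EX_for": (-5.0, 1000.0), "EX_nh4": (-10.0, 1000.0)})
    else:
        raise KeyError(f"unknown medium preset {name!r}; known: {MEDIUM_PRESETS}")
    return base
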