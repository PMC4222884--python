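# Methods

## Model scope and conventions

The core reconstruction covers central acetogenic metabolism of
*C. ljungdahlii*: a lumped EMP glycolysis, pyruvate:ferredoxin
oxidoreductase, the full Wood-Ljungdahl pathway (FDH7, FTHFLi, MTHFC,
MTHFD, MTHFR5, METR and the net CODH/ACS step, plus a separate CODH for
CO oxidation), fermentation branches to acetate, ethanol, lactate and
2,3-butanediol, the energy-conservation machinery (Rnf, ATP synthase,
electron-bifurcating hydrogenase and Nfn transhydrogenase), a nitrate →
nitrite → hydroxylamine → ammonium assimilation pathway, and a lumped
biomass drain.  Two compartments (cytosol `c`, extracellular `e`); all
bounds in mmol/gDW/h with the COBRA conventions (reversible ±1000,
irreversible [0, 1000], negative exchange flux = uptake).

Every non-exchange, non-lumped reaction is elementally and charge
balanced against standard formulas at pH 7 (the THF-C1 series uses the
usual biochemistry formulas; ferredoxin is a two-electron pair
fdxo/fdxr modeled as Fe2S2 with a 2− charge difference, so one reduced
ferredoxin counts as one reducing equivalent on the same footing as
NAD(P)H).  The corrinoid protein pair cfesp/mecfesp and the biomass
drain are lumped species with empty formulas, skipped by the balance
audit; the METR + CODH/ACS *pair* nets to a balanced conversion, so the
invisible methyl group is consistent.

## Protons and the proton-motive force

Cytosolic protons are an ordinary mass-balanced species.  The only
reactions crossing the membrane with protons are Rnf (translocates
`rnf_protons_per_fd` = 2 H⁺ per ferredoxin oxidized, plus the scalar
proton of NAD⁺ reduction), the ATP synthase (`atps_protons_per_atp` = 4
H⁺ consumed per ATP, 3 returned to the cytosol by the ADP + Pi + H⁺ →
ATP + H₂O chemistry), and the acid/anion proton symporters (acetate,
lactate, formate, pyruvate, nitrate, nitrite).  There is deliberately
no free proton uniporter, so chemiosmotic ATP is only available through
Rnf; with water/phosphate/protons as the only exchangeable species the
maximal maintenance flux is exactly zero (tested).  The two proton
integers are configurable; their ratio (0.5 ATP per ferredoxin) is
fixed by the published ATP yields (1.5 and 0.75 ATP per ethanol), and
the configuration validator rejects combinations that would let the
Rnf–synthase loop create free energy.  Only the ratio enters the ATP
yields; doubling both integers leaves every yield unchanged, though
absolute growth rates shift by ~2% because the scalar proton turnover
of the two machines doubles.

A consequence of exact proton bookkeeping worth noting: in the
NAD-hydrogenase H₂/CO₂ ethanol scenario the diagnostic ATP deficit is
1/3 rather than the 0.25 that naive subtraction (1 − 0.75) suggests,
because covering the last fraction of ATP at the synthase would itself
consume cytosolic protons the scenario cannot supply.  The ATP-at-Rnf
yields themselves (1.5 / 0.75 / 2.25) are read from the Rnf flux, which
is pinned by the carrier balances, and are unaffected.

## Biomass and media

Biomass is a four-precursor lumped drain per gDW: 20 mmol acetyl-CoA
(≈ 40 mmol C, a realistic cellular carbon content), 40 mmol ATP
(growth-associated maintenance in the usual range), 10 mmol NADPH
(anabolic reduction), and 8 mmol NH₄⁺ (cell nitrogen at 43% protein
plus nucleic acids).  These defaults were chosen once as field-typical
values; absolute growth rates of the core model are therefore
order-of-magnitude realistic (0.06–0.13 1/h on the presets) but are not
calibration targets — genome-scale growth-rate predictions belong to
the published-model loader path.  Non-growth-associated maintenance
defaults to 0 and is configurable.

Media presets: fructose at the measured 1.88 mmol/gDW/h with ammonium;
the same ammonium-free with nitrate; H₂/CO₂ at 20/10; CO at 20;
pyruvate and formate at 5 for the heterotrophic screens.  Water,
phosphate and extracellular protons are always freely exchanged;
`apply_medium` closes every unnamed uptake and leaves secretion open.

One reaction was added beyond the minimal published set: GAPN, a lumped
glycolysis variant through the non-phosphorylating NADP-dependent
glyceraldehyde-3-phosphate dehydrogenase (no net ATP).  Acetogens
possess this enzyme, and without it the network would have no
heterotrophic NADPH source other than the Nfn transhydrogenase — the
Nfn knockout would then (wrongly) be lethal on fructose.  Under normal
conditions the LP prefers EMP + Nfn (cheaper in ATP), so GAPN carries
flux only when Nfn is removed.

## Scenario analyses

**Reducing-equivalent audits** come in two views.  The *demand* view
disables the carrier interconverters (Rnf, Nfn), the electron donors
(hydrogenase, CODH, glycolysis, PFOR) and the ATP synthase/maintenance,
adds unbalanced pseudo-supplies for NADH, NADPH, reduced ferredoxin and
ATP (protons and water are free in this view), fixes the product flux
at 1 and minimizes total redox supply: the supply fluxes are the
pathway's intrinsic requirement.  The *supply* view runs the full
network on the stated electron source with the product fixed at 1 and
reports the carrier production of the donor reactions in the
parsimonious solution — the currency in which electrons actually
arrive.  Audit fluxes are certified in exact rational arithmetic:
the LP vertex is rounded to small-denominator rationals and every
metabolite balance re-verified with `fractions.Fraction`; all shipped
audits certify (`exact=True`), and a failed certification falls back to
floats rather than failing.

**Energy-gap analysis** fixes the product at 1, applies knockouts,
blocks competing product secretion, adds a diagnostic ATP source
(ADP + Pi → ATP) and minimizes its flux; the minimum is the ATP deficit.
With the deficit pinned, the parsimonious solution provides the Rnf
proton translocation, reported as `atp_from_pmf` = translocated / 4.
The surplus is the maximal maintenance flux with the diagnostic
removed.  An FVA check (`rnf_flux_is_unique`) confirms the Rnf flux has
a zero-width range in these scenarios, so the reported yields are
invariant across alternate LP optima.  "ATP generated" is deliberately
the gross chemiosmotic yield at Rnf, not net of the formate-THF ligase
ATP — matching how the yields are quoted in the acetogen literature.

**Nitrate scenario** compares growth-maximizing parsimonious FBA at
equal fructose uptake under ammonium vs nitrate-only nitrogen.  The
comparison basis (equal uptake, growth objective) is a design choice;
the direction of the acetate response does not depend on it: nitrate
reduction (4 NADH per NH₄⁺ formed) drains the electrons that otherwise
refix fermentation CO₂ into additional acetate, so acetate falls.  The
core model, lacking the genome-scale network's competing sinks,
overstates the magnitude (−73% vs the published −15%); the magnitude is
a loader-path target, the direction and the stoichiometric nitrogen
closure (N consumed = N secreted + N in biomass, residual < 1e-6) are
core results.

## Engine numerics

LPs are solved with HiGHS (scipy.linprog) at 1e-10 feasibility/
optimality tolerances; growth below 1e-9 counts as no growth.
Parsimonious FBA pins the objective, minimizes Σ|v| via a split-variable
LP, and (on models ≤ 150 reactions) runs an exact lexicographic
refinement that minimizes each |v_j| in reverse-sorted id order — among
equal-total optima the lexicographically earliest reactions keep the
flux, making ledger audits deterministic.  Gap-filling is a MILP
(binary indicators gating candidate bounds, cardinality objective,
integer cuts for alternate minimal sets) solved with HiGHS through
`scipy.optimize.milp`; every returned set is verified against the
minimality witness by LP re-solves.  Degenerate inputs: empty models
give 0×0 matrices; infeasible/unbounded statuses are returned, not
raised, by `fba`; fixed (lb = ub) bounds are handled throughout.

## Synthetic benchmarks and what they show

`random_feasible_network` builds parallel source→sink chains with
random uptake caps (uniform 0.5–5, seeded), whose optimum is the sum of
the caps by construction.  The brute-force oracle enumerates all
bound-fixing patterns of the polytope's vertices (3ⁿ worst case, hence
n ≤ 10) and shares no code with the simplex path; engine ≡ oracle is
checked on 100 seeded instances at 1e-6.  These networks exercise LP
correctness (bounded vertices, degeneracy, reproducibility), not
biological realism: they contain no cofactor coupling, reversibility
cycles or compartment structure, so passing them validates the solver
layer while the curated-model tests validate the biology.

## Known limitations

No thermodynamic (ΔG) constraints or metabolite concentrations; the
lumped glycolysis folds PTS-vs-kinase uptake energetics into its net
stoichiometry; additional heterotrophic substrates of the genome-scale
model (glucose, arabinose, amino acids, …) are not encoded; SBML input
is not supported (COBRA JSON/MAT are); absolute growth rates depend on
the lumped biomass and are not calibrated to measurements.
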