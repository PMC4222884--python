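# cljflux

Constraint-based analysis of acetogenic metabolism in *Clostridium
ljungdahlii* — a flux-balance-analysis engine plus a curated,
elementally balanced core reconstruction of the Wood-Ljungdahl pathway
and its energy-conservation machinery, built for studying how an
acetogen makes a living at the thermodynamic edge.

## The scientific problem

Acetogens fix CO₂ (or CO) into acetyl-CoA through the Wood-Ljungdahl
pathway (WLP) and conserve energy without substrate-level ATP to spare:
the WLP itself consumes one ATP (formate-THF ligase) and regains one at
acetate kinase, so net chemiosmotic ATP must come from the
membrane-bound Rnf complex, which translocates protons while oxidizing
reduced ferredoxin to NADH, coupled to the ATP synthase.  The low-
potential ferredoxin is produced by flavin-based electron bifurcation —
the methylene-THF reductase, the HydABC hydrogenase, and the Nfn
transhydrogenase.  This package encodes that machinery as executable
stoichiometry and asks the quantitative questions: how many reducing
equivalents does each product cost, in which carrier currency do they
arrive from each electron donor, and when does the ATP budget close?

The flux model is standard FBA: maximize an objective cᵀv over
steady-state fluxes, S·v = 0, lb ≤ v ≤ ub, with the stoichiometric
matrix S (rows metabolites, columns reactions) and exchange fluxes
negative for uptake.  On top of the LP core the package provides flux
variability analysis, parsimonious flux selection, single-gene deletion
screens via gene-protein-reaction (GPR) boolean rules, SMILEY-style
MILP gap-filling, and synthetic benchmark networks with a brute-force
vertex-enumeration oracle.

## Headline stoichiometry

Per acetyl-CoA fixed from 2 CO₂ the WLP consumes exactly

    1 NADPH + 1 Fd²⁻ + 2 NADH  (4 two-electron equivalents) + 1 ATP

with the methylene-THF reductase bifurcation returning one ferredoxin
that the formate dehydrogenase and CODH/ACS steps consume.  Ethanol
adds 2 NADH (6 equivalents total = its 12 electrons from 2 CO₂).  With
acetate kinase deleted and ethanol the product, the Rnf/ATP-synthase
couple yields per ethanol: 2.25 ATP on CO (all 6 equivalents arrive as
ferredoxin), 1.5 ATP on H₂ with the NADP-specific bifurcating
hydrogenase (equimolar NADPH/ferredoxin supply), but only 0.75 ATP with
the NAD-specific one (3 NADH + 3 ferredoxin) — short of the 1 ATP the
WLP needs, which is why acetate kinase is essential for autotrophic
growth on H₂/CO₂ in that configuration and only in that one.

## Worked example

```python
from cljflux import (build_core_model, medium_preset, apply_medium,
                     parsimonious_solution, reducing_equivalent_audit)

model = build_core_model()                      # NADP hydrogenase default
cond = apply_medium(model, medium_preset("h2_co2"))
sol = parsimonious_solution(cond)
print(round(sol.objective_value, 4), round(sol.fluxes["EX_ac"], 4))
# 0.0594 3.6634   -> growth 0.0594 1/h, acetate secretion 3.66 mmol/gDW/h

led = reducing_equivalent_audit(model, "etoh", "co", interconverters="enabled")
print(led.fdx, led.total_equivalents)
# 6 6             -> on CO, all six equivalents arrive as reduced ferredoxin
```

The same analyses from the shell:

```
cljflux simulate --medium co --knockout ackA
cljflux panel-acka
cljflux audit --product ethanol --source co --view supply
cljflux validate
```

The numbered drivers under `analysis/` run the full study —
`01_validate_core.py` (balance audit, substrate screen),
`02_reducing_equivalents.py`, `03_energy_conservation.py` (ackA panel),
`04_nitrate.py` (ammonium-vs-nitrate nitrogen source),
`05_gapfill_demo.py` — and write their tables under `results/`.

A published genome-scale model file (COBRA JSON or MAT) can be loaded
with `cljflux.load_published_model` / `cljflux info --model FILE`; the
genome-scale tests activate when such a file is placed under
`data/published/`.

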