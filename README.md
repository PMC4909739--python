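# ptracer

Isotope-dilution partitioning of plant phosphorus uptake for soil-labeling
³²P pot experiments, with companion calculations for fertilizer budgets,
soil respiration and treatment statistics.

## The problem

Whether a recycled P source (here: thermally conditioned sewage sludge,
TCSS) fertilizes as well as a water-soluble mineral reference (triple super
phosphate, TSP) cannot be read off total uptake alone — plants draw P from
the soil's plant-available pool, from seed reserves, and from the
fertilizer, in proportions that shift with treatment. Labeling the soil
pool with carrier-free ³²P before fertilization makes the sources
separable: soil-derived P carries the label, fertilizer- and seed-derived P
do not.

With `Pt` the shoot P uptake (mg P kg⁻¹ soil), `r/R` the fraction of
introduced radioactivity recovered in shoots (decay-corrected to the
labeling date), and subscript 0 the unfertilized control:

```
Pt = Pseed + Psoil + Pfert                      (mass balance)
IC0     = r0 / (Pt0 − Pseed0)                   (control isotopic composition)
Psoil_f = (Pt0 − Pseed0) · r_f / r0             (equal-SA assumption)
Pfert_f = Pt_f − Pseed_f − Psoil_f
Pdff    = 100 · Pfert / Pt                      (% of uptake from fertilizer)
CPU     = 100 · Pfert / dose                    (% of the dose recovered)
L       = Pt / (r/R)        SA = (r/R) / Pt     (L·SA = 1)
AE_CPU  = 100 · Pfert_test / Pfert_ref          AE_Pdff = 100 · Pdff_test / Pdff_ref
```

Seed-derived P is estimated from a parallel unlabeled experiment (sown
minus residual seed P, allocated by the shoot share of whole-plant uptake)
and is treated as zero from the second cut on.

The package also computes fertilizer dry-matter doses, co-applied
nutrient/contaminant rates per kg soil and per hectare, and heavy-metal
compliance against the French sludge limits; converts NaOH-trap
back-titration volumes into daily and cumulative soil respiration
(6 mg C per meq of NaOH consumed); runs one-way ANOVA with
Student–Newman–Keuls letter groupings; and generates seeded synthetic pot
and incubation experiments with known ground truth.

## Worked example

```sh
python examples/02_desk_scale_ratio_chain.py
```

```
control  L =  39.0 mg P/kg   SA = 0.026 /mg P/kg
TSP      L =  98.0 mg P/kg   SA = 0.010 /mg P/kg
TCSS     L =  89.3 mg P/kg   SA = 0.011 /mg P/kg
TSP      Pdff = 55.3 %   CPU = 21.8 %
TCSS     Pdff = 56.0 %   CPU = 14.0 %
AE_CPU (TCSS vs TSP)  = 64 %
AE_Pdff (TCSS vs TSP) = 102 %
```

Fertilization roughly doubles the plant-available soil P the crop "sees"
(L-value 39 → 90–98 mg P kg⁻¹). Both fertilizers supply just over half of
shoot P (Pdff ≈ 55–56 %), but the sludge dose is recovered at 14 % against
the mineral reference's 22 % — agronomic effectiveness 64 % by recovery,
yet ≈ 100 % by contribution to nutrition, the signature of microbial
P immobilization competing with the crop for both soil and fertilizer P.

Other examples: `01_partition_pot_experiment.py` (full pipeline on a
simulated experiment vs. ground truth), `03_fertilizer_budget.py`,
`04_soil_respiration.py`, `05_group_stats.py`. The same capabilities are
scriptable through the `ptracer` CLI (`partition`, `simulate`, `budget`,
`respire`, `stats`; exit status 2 = schema error, 3 = compliance failure).

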