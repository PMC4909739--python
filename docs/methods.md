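# Methods

## Isotope-dilution source partitioning

The partitioning assumes the indirect soil-labeling design: carrier-free
³²P is mixed into the soil before fertilization, so only the
plant-available soil pool is labeled. Three assumptions carry the method:

1. **Equal specific activity across treatments.** P taken up from the soil
   pool has the same isotopic composition in fertilized and unfertilized
   pots (`IC0 = r0/(Pt0 − Pseed0)`). Fertilizer-induced changes to the
   labeled pool (e.g. microbial turnover) violate this; the simulator's
   `sa_multiplier` reproduces the resulting bias, which is exactly
   `Psoil_true·(m − 1)` for a multiplier `m` on the treatment's soil-pool
   SA, with the opposite sign appearing in `Pfert` through the mass
   balance.
2. **Unlabeled fertilizer and seed P.** Both dilute the tracer; the seed
   contribution is measured in a parallel unlabeled experiment and
   subtracted before the tracer ratio is formed.
3. **Decay correction.** Measured activities are corrected to the labeling
   timestamp with T½ = 14.276 d before normalizing by the introduced
   activity R. ³²P decays ≈ 5 % per day, so uncorrected counts from
   harvests weeks apart would not be commensurable. The correction is
   `A·2^(t/T½)` with `t` the elapsed time from labeling to counting; the
   inverse (negative `t`) makes the round trip exact.

**Computation mode.** The default partitions each pot at each cut against
the control means of that cut, then cumulates the additive quantities
(Pt, Pseed, Psoil, Pfert, r/R) per pot before recomputing the ratio
quantities (Pdff, CPU, SA, L) — the arithmetic appropriate to a replicated
multi-cut experiment, and the one that supports replicate-level ANOVA. An
`aggregate` mode evaluates the equations once on cumulative treatment
means; it is a diagnostic/teaching device. The two modes do not coincide:
on the published cumulative means of the motivating experiment the
aggregate evaluation gives Psoil_TSP = 6.78 and Pfert_TSP = 12.03
mg P kg⁻¹ where the published per-replicate cumulation printed 8.8 and
10.9 — the per-cut recoveries needed to reproduce the absolute pools were
not published. All ratio-level quantities (L, SA, Pdff, CPU, AE) are exact
from the printed inputs, and the test suite pins the documented gap.

**L-value.** `L = Pt/(r/R)` without seed correction, which reproduces the
published L-values (39, 98) exactly; a seed-corrected variant is available
by passing `Pt − Pseed` explicitly. `L·SA = 1` identically.

**Edge cases.** Negative `Pfert`/`Psoil` estimates (noise) are retained
and flagged, never clipped, so replicate means stay unbiased. Zero control
recovery, `Pt0 ≤ Pseed0`, missing control, or mixed treatments in a
cumulation raise typed errors. Seed P is zero from cut 2 on (seed reserves
are depleted after the first regrowth).

## Fertilizer budget

Dose arithmetic is linear: `g DM kg⁻¹ soil = dose_mg / total_p_g_per_kg`;
co-applied constituent rates scale by the same DM mass and keep their unit
tags (g kg⁻¹ vs mg kg⁻¹ — no silent inference); per-hectare conversion
assumes 3500 t soil ha⁻¹ (25 cm layer, bulk density 1.4), overridable. The
TCSS total P of 23.30 g kg⁻¹ DM (the composition text's value, not the
sheet's rounded 23.0) is used in examples because it reproduces the
published 0.459 g C kg⁻¹ co-application entry; the sheet's own per-ha
total-P entry (173 kg) is inconsistent with its first two columns
(0.050 g kg⁻¹ × 3500 t = 175 kg) — documented, not resolved. Heavy-metal
compliance is a static concentration-vs-limit conjunction with the French
sludge limits as the shipped default.

## Soil respiration

Back titration at the phenolphthalein endpoint: 1 meq of NaOH consumed per
meq of trapped CO₂, i.e. 6 mg C per meq (12 g C per 2 eq from
CO₂ + 2 NaOH → Na₂CO₃). Interval masses are `(v_blank − v_sample) × N × 6`
mg C, divided by jar soil mass; daily fluxes are interval-averaged and
assigned to the interval's end day; the cumulative curve is the running
sum. Negative masses (sample titration above blank) are flagged and kept
in QC output but excluded from cumulative sums by default. The
substrate-induced-respiration biomass estimate is the literature factor 40
× flush C — a labeled heuristic, not a measurement.

## Group statistics

One-way ANOVA is the classical between/within decomposition; with zero
within-variance and equal means F is reported NA with a flag. SNK is
implemented directly from the studentized-range distribution: means sorted
descending (ties broken by label), spans tested step-down with
q(α, span, df_within) at the pooled MS, spans inside a non-significant
span never declared significant; unequal n uses the harmonic mean
(flagged). Letters are the maximal runs of mutually non-significant
consecutive groups, so the display is a valid cover: significant pairs
share no letter, non-significant pairs share at least one. At k = 2 the
SNK decision coincides with the pooled t-test. Reconstructing the
published p-values from means ± SE is deliberately not attempted (raw
replicates unavailable). Dispersion is reported as SE (SD/√n) throughout.

## Synthetic data

The pot generator draws, per treatment × cut, seed-, soil- and
fertilizer-derived uptake from configured truths (`Pt = (soil + seed)/(1 − f)`
for fertilizer fraction `f`), attaches radioactivity as soil-pool SA ×
soil-derived uptake (only soil P is labeled), applies one multiplicative
lognormal draw per pot to all P pools (pot-level vigor, so per-pot
fractions stay exact), independent lognormal noise to dry matter, additive
Gaussian counting error, and decays activities forward to count dates two
days after each harvest — the analysis must decay-correct to recover
truth. Defaults are calibrated to the motivating trial's magnitudes:
cumulative Pt ≈ 4.6/19.7/12.5 mg P kg⁻¹ for control/TSP/TCSS, fertilizer
fractions ≈ 0.55/0.56, dose 50 mg P kg⁻¹, n = 5, cuts at 27/38/59 days,
R = 3.7 MBq kg⁻¹, CVs 10 % (biological) and 5 % (counting). Because
per-cut tracer recoveries were never published, per-cut defaults are
calibrated only to the cumulative magnitudes. A seed is mandatory;
identical config + seed reproduces byte-identical tables.

The incubation generator integrates `flux(t) = basal + A·e^(−kt)` in
closed form over the 1, 2, 3, 5, 8, 10, 15, 23, 32, 42, 63-day schedule
and inverts interval masses into titration volumes (raising on trap
saturation). Defaults (TCSS-like: basal 1.8, A 65 mg C kg⁻¹ d⁻¹,
k 0.5 d⁻¹) put the day-1 flux inside the published 49–61 mg C kg⁻¹ d⁻¹
range and the 63-day cumulative (243 mg C kg⁻¹) inside the published
214–255 envelope; the published curves themselves are not reconstructable
without the raw titrations.

What the generator does **not** emulate: root-uptake kinetics, sorption
chemistry, mechanistic microbial immobilization (the violation mode is a
phenomenological SA perturbation), counting statistics beyond a Gaussian
CV, or between-cut correlation beyond the shared pot vigor draw. Passing
tests therefore certify the algebra and its statistical behavior under the
stated noise model, not field realism.

## Problem sizes

The stochastic-recovery checks run 200 seeded replicate simulations of the
default 3 × 5 × 3 design (a few seconds); all other tests are desk-scale.
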