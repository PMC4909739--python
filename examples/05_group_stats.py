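"""ANOVA + SNK letters on per-pot cumulative P uptake."""

import ptracer as pt

cfg = pt.default_pot_config(seed=4)
obs, seed_budgets, truth, labeling = pt.simulate_pot_experiment(cfg)
doses = {t: c.dose for t, c in cfg.treatments.items()}
table = pt.partition_experiment(obs, seed_budgets, labeling, doses)

cum = table.per_pot_cumulative
groups = {t: g["Pt"].tolist() for t, g in cum.groupby("treatment")}

res = pt.snk_letters(groups, alpha=0.05)
print(f"one-way ANOVA: F = {res.anova.F:.2f}, p = {res.anova.p:.4g}")
for s in res.summaries:
    print(f"  {s.group:<8} {s.mean:6.2f} +/- {s.se:4.2f} mg P/kg  {s.letters}")
print("Treatments sharing no letter differ at alpha = 0.05 by the "
      "Student-Newman-Keuls studentized-range procedure.")
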