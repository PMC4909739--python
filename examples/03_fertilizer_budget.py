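"""Dose, co-application and compliance budget for a sewage-sludge fertilizer."""

import ptracer as pt
from ptracer.fertilizer import Quantity

tcss = pt.FertilizerSpec(
    name="TCSS",
    total_p=23.30,  # g P per kg dry matter
    constituents={
        "Organic C": Quantity(214.0, "g/kg"),
        "Total N": Quantity(13.0, "g/kg"),
        "Cu": Quantity(731.0, "mg/kg"),
        "Zn": Quantity(2408.0, "mg/kg"),
        "Cd": Quantity(15.0, "mg/kg"),
        "Hg": Quantity(7.0, "mg/kg"),
    },
)

dose = 50.0  # mg P per kg soil
dm = pt.dm_for_dose(dose, tcss)
print(f"{dm:.3f} g sludge DM per kg soil delivers {dose:.0f} mg P per kg soil")

for name, q in pt.coapplication_rates(dose, tcss).items():
    print(f"  co-applied {name:<10} {q.value:10.4f} {q.unit} soil "
          f"= {pt.per_hectare(q):8.2f} kg/ha (3500 t soil/ha)")

report = pt.heavy_metal_compliance(tcss)
for c in report.checks:
    print(f"  {c.metal:<3} {c.concentration_mg_kg:7.1f} mg/kg vs limit "
          f"{c.limit_mg_kg:6.0f} -> {'pass' if c.passes else 'FAIL'}")
print(f"overall: {'PASS' if report.overall_pass else 'FAIL'} "
      "(French sludge limits)")
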