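"""The isotope-dilution ratio chain on cumulative treatment means.

Feeds the cumulative shoot P uptake, tracer recovery and fertilizer-derived
P of a grass pot trial (control / TSP / TCSS at 50 mg P per kg soil)
through the elementary operations.
"""

import ptracer as pt

Pt = {"control": 4.6, "TSP": 19.7, "TCSS": 12.5}   # mg P / kg soil
r = {"control": 11.8, "TSP": 20.1, "TCSS": 14.0}   # % of introduced R
Pfert = {"TSP": 10.9, "TCSS": 7.0}                  # mg P / kg soil
dose = 50.0

for trt in ("control", "TSP", "TCSS"):
    L = pt.l_value(Pt[trt], r[trt])
    SA = pt.specific_activity(r[trt], Pt[trt])
    print(f"{trt:<8} L = {L:5.1f} mg P/kg   SA = {SA:.3f} /mg P/kg")

for trt in ("TSP", "TCSS"):
    print(f"{trt:<8} Pdff = {pt.pdff(Pfert[trt], Pt[trt]):.1f} %   "
          f"CPU = {pt.cpu(Pfert[trt], dose):.1f} %")

print(f"AE_CPU (TCSS vs TSP)  = {100 * Pfert['TCSS'] / Pfert['TSP']:.0f} %")
print(f"AE_Pdff (TCSS vs TSP) = {100 * 56.0 / 55.0:.0f} %")
print("\nL is the plant-available soil P each treatment 'sees'; fertilization "
      "raises it well above the control's. Pdff says over half the shoot P came "
      "from the fertilizer in both treatments, while CPU shows the sludge dose "
      "is recovered less efficiently than the mineral reference.")
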