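"""Calibrated Na+/H+ exchange activity from a pH-probe trace.

Cells are acid-loaded in Na⁺-free buffer; re-adding Na⁺ lets NHE extrude
protons, alkalinizing the cytosol. The probe signal is calibrated
against nigericin clamps at pH 6, 7, 8 recorded at the end of the
trace, and recovery is quantified as ΔpH and an initial rate. The
healthy condition plants a 0.5-unit recovery, the disease (MVID)
condition 0.05 — near-complete loss of NHE activity.
"""

from enteroquant.analysis import analyze_ph_trace
from enteroquant.simulate import gen_ph_trace, nhe_config

for condition in ("healthy", "mvid"):
    trace, truth = gen_ph_trace(nhe_config(condition, seed=3))
    result = analyze_ph_trace(trace)
    print(f"{condition}: dpH = {result.delta_ph:.3f} "
          f"(planted {truth.data['delta_ph']:.2f}), "
          f"initial rate = {result.initial_rate * 1000:.2f} mpH/s")
print("dpH is the Na+-dependent alkalinization over the recovery window; "
      "its collapse in MVID reflects loss of apical NHE3.")
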