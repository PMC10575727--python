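"""Fit the crofelemer dose-response from a simulated Isc run.

A combined forskolin+carbachol stimulus establishes a chloride-secretory
plateau; cumulative crofelemer doses knock it down following a
four-parameter logistic with true IC50 30 µM and maximal inhibition
80%. The analysis measures percent inhibition at each dose from the
trace plateaus and fits the 4PL back.
"""

from enteroquant import fit_dose_response
from enteroquant.analysis import measure_dose_inhibition
from enteroquant.simulate import crofelemer_dose_config, gen_isc_trace

trace, truth = gen_isc_trace(crofelemer_dose_config(seed=0))
doses, inhibition = measure_dose_inhibition(trace)
for d, i in zip(doses, inhibition):
    print(f"  {d:6.1f} uM -> {i:5.1f}% inhibition")
fit = fit_dose_response(doses, inhibition)
print(f"fitted IC50 = {fit.ic50:.1f} uM (true 30), "
      f"maximal inhibition = {fit.ceiling:.1f}% (true 80)")
print("IC50 is the dose halving the stimulated current; the ceiling is "
      "the maximal achievable block of secretion.")
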