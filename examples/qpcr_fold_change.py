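"""Relative qPCR quantification by the 2^-ddCt method.

Cq values for a target gene are normalized to a housekeeping gene
(GAPDH) within each sample (ΔCt), referenced to a control sample
(ΔΔCt), and expressed as fold change 2^-ΔΔCt. Here the treated sample's
target amplifies two cycles earlier at equal GAPDH, i.e. a 4-fold
induction.
"""

import pandas as pd

from enteroquant import QpcrPlate, delta_delta_ct

rows = (
    [("healthy", "SGK2", 26.0)] * 3 + [("healthy", "GAPDH", 20.0)] * 3
    + [("mvid+dapt", "SGK2", 24.0)] * 3 + [("mvid+dapt", "GAPDH", 20.0)] * 3
)
plate = QpcrPlate(pd.DataFrame(rows, columns=["sample", "gene", "cq"]))
result = delta_delta_ct(plate, reference_sample="healthy")
print(result.round(3).to_string(index=False))
print("fold_change > 1 means the gene is induced relative to the "
      "reference sample after housekeeping normalization.")
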