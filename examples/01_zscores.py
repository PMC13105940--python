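"""Compute weight-for-age z-scores against a reference table and classify
underweight children (WAZ strictly below -2)."""

import numpy as np
import pandas as pd

from geowaz import AnthroReference, classify_underweight, compute_zscore

# a toy reference table: median and SD of weight (kg) per age/sex stratum
reference = AnthroReference(pd.DataFrame({
    "stratum_age_months": [6, 6, 24, 24],
    "sex": ["male", "female", "male", "female"],
    "median": [7.9, 7.3, 12.2, 11.5],
    "sd": [0.95, 0.91, 1.30, 1.26],
}))

weights = np.array([6.1, 7.3, 9.4, 12.0])
ages = [6, 6, 24, 24]
sexes = ["male", "female", "male", "female"]

z = reference.zscores(weights, ages, sexes)
flags = classify_underweight(z)
for w, a, s, zi, f in zip(weights, ages, sexes, z, flags):
    print(f"age {a:>2} mo {s:>6}  weight {w:4.1f} kg  WAZ {zi:+.2f}  underweight={f}")

# the same formula directly: (index - reference median) / reference SD
print("direct formula check:", compute_zscore(6.1, 7.9, 0.95))
# A WAZ of -1.89 is low but not underweight; the cut-off at -2 is strict.
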