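"""Turn monthly burnt-area fractions into average fire intervals.

The average fire interval AFI = 1/(BA + 1e-4) is the expected fire return
time of a cell; the regularizer caps unburnt cells at 10,000 years, and the
analysis uses log10(AFI) because intervals span orders of magnitude.
"""

import numpy as np

from tgbcover import annual_burnt_fraction, fire_interval

# three cells x 3 years x 12 months of burnt-area fractions
monthly = np.zeros((3, 3, 12))
monthly[0, :, 7] = 0.45          # burns most years: frequent fire
monthly[1, 0, 7] = 0.12          # burned once in three years
monthly[2] = 0.0                 # never burns

ba = annual_burnt_fraction(monthly)
fm = fire_interval(ba)
for i in range(3):
    print(
        f"cell {i}: BA = {fm.ba[i]:.4f} 1/y -> AFI = {fm.afi[i]:9.1f} y, "
        f"log10(AFI) = {fm.log_afi[i]:.2f}"
    )
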