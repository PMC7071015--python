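"""Fit a 4PL dose-response curve and report IC50.

A simulated reporter-assay plate (620 nm absorbances, duplicates, noise)
is normalised to percent inhibition between the negative control (0 %)
and the neutralising-antibody positive control (100 %), then fitted with
the four-parameter logistic to obtain IC50 and the Hill slope.
"""

import numpy as np

from cyclomimic import fit_4pl, normalize_inhibition, simulate_assay
from cyclomimic.bioassay import summarize_inhibition

doses = list(np.geomspace(1.0, 1000.0, 8))
plate = simulate_assay(ic50=133.7, hill=1.2, doses=doses, noise_sd=3.0,
                       replicates=2, seed=42, compound="macrocycle-1")

points = normalize_inhibition(plate)
print(summarize_inhibition(points).to_string(index=False,
                                             float_format="%.1f"))

fit = fit_4pl(points)
flag = " (by extrapolation)" if fit.extrapolated else ""
print(f"\nIC50       : {fit.ic50:.1f} +/- {fit.se[2]:.1f} uM{flag}")
print(f"Hill slope : {fit.hill:.2f}")
print(f"bottom/top : {fit.bottom:.1f} % / {fit.top:.1f} %")

# The IC50 is the dose giving half-maximal inhibition.  When the fitted
# IC50 lies above the highest tested dose the flag marks it as an
# extrapolated estimate, which must be reported as such.
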