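"""Fit a single-drug dose-response curve and derive panel doses."""

import numpy as np

import qpop

# eight-point serial dilution of a synthetic drug (IC50 0.5 uM, hill 1.3)
doses = np.logspace(-3, 2, 8)
table = qpop.simulate_dose_response(
    top=1.0, bottom=0.02, ic50=0.5, hill=1.3, doses=doses, noise_sd=0.01, seed=4
)

fit = qpop.fit_4pl(table["dose_uM"], table["viability"])
print(
    f"4PL fit: IC50 = {fit.ic50:.3f} uM, hill = {fit.hill:.2f}, "
    f"top = {fit.top:.3f}, bottom = {fit.bottom:.3f} (rss {fit.rss:.2e})"
)

ic10 = qpop.invert_4pl(fit, 0.10)
ic20 = qpop.invert_4pl(fit, 0.20)
print(f"derived panel doses: IC10 = {ic10:.4f} uM, IC20 = {ic20:.4f} uM")
print(
    "these are the level-1 and level-2 doses of this drug in the combination "
    "screen; level 0 is drug absent (IC0)."
)

fa = 1.0 - table["viability"].clip(1e-6, 1 - 1e-6)
me = qpop.fit_median_effect(table["dose_uM"], fa)
print(
    f"\nmedian-effect fit: m = {me.m:.2f}, Dm = {me.dm:.3f} uM "
    f"(r^2 = {me.r_squared:.4f}); Dm approximates the IC50."
)
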