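"""Express a parameter change as the chart-relevant shift sizes.

A shift of the LTPHR parameters from (mu0, lam0) to (mu1, lam1) enters the
charts only through delta1 = lam0 * ln(Fbar(mu0)/Fbar(mu1)) (location) and
delta2 = lam0 / lam1 (hazard exponent). Here: the change from the
conventional-environment mouse population to the germ-free one.
"""

import ltphrcharts as lc

ic = lc.ICSpec(sbar_mu0=0.9587, lambda0=0.5444)   # conventional housing fit
ooc = (0.8069, 0.2302)                            # germ-free housing fit

shift = lc.shift_of(ic, ooc)
print(f"delta1 = {shift.delta1:.4f}  (location shift; > 0 means later onset)")
print(f"delta2 = {shift.delta2:.4f}  (lam0/lam1; > 1 means flatter hazard)")

back = lc.apply_shift(ic, shift)
print(f"round trip -> Fbar(mu1) = {back[0]:.4f}, lam1 = {back[1]:.4f}")
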