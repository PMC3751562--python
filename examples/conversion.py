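"""Acinar-to-islet conversion after losing lateral signals.

Runs the conversion protocol on a 12x12 adult tissue (everything starts
acinar; the coupling is switched at t=0 after a 20-time-unit burn-in) for
three signal manipulations and prints the conversion statistics.
"""

import numpy as np

from pancfate import run_conversion

kw = dict(width=12, height=12, replicates=3, seed=5, t_end=150.0)

for variant, label in [("stab", "lose stabilization (b=0)"),
                       ("both", "lose both signals (a=b=0)"),
                       ("inhibition", "lose inhibition only (a=0)")]:
    res = run_conversion(variant=variant, **kw)
    conv = res.conversion_fraction
    tth = res.time_to_half
    tth_txt = "never" if np.isnan(tth).all() else f"{np.nanmean(tth):5.1f}"
    print(f"{label:<28s} conversion = {conv.mean():.2f}  time to 50% islet = {tth_txt}")

print()
print("Losing stabilization converts every cell, but slowly: lateral")
print("inhibition forces an alternating, sequential commitment.  Losing both")
print("signals converts directly and much faster.  Losing inhibition alone")
print("leaves the acinar tissue intact.")
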