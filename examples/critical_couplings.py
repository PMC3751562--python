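"""Critical lateral-coupling strengths of the 3-cell minimal tissue.

Locates the two saddle-node (fold) bifurcations that organize fate
conversion: the stabilization strength b_c below which the acinar fate
cannot be maintained, and the inhibition strength a_c at which the
multipotent progenitor branch vanishes (with stabilization lost, b=0).
"""

from pancfate import ModelParams, critical_inhibition, critical_stabilization

p = ModelParams()

b_c_single = critical_stabilization(p, branch="mixed")
b_c_hom = critical_stabilization(p, branch="acinar")
a_c = critical_inhibition(p)

print(f"b_c (acinar cell with one acinar neighbour)  = {b_c_single:.4g}")
print(f"b_c (fully surrounded homogeneous acinar)    = {b_c_hom:.4g}")
print(f"a_c (progenitor branch saddle-node at b=0)   = {a_c:.4g}")
print()
print("Below the first b_c an acinar cell that keeps only one acinar")
print("neighbour dedifferentiates; the homogeneous tissue persists to a")
print(f"2^n = 8-fold smaller value.  Below a_c = {a_c:.2g} there is no")
print("multipotent intermediate, so conversion proceeds as a direct switch.")
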