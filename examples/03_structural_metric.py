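"""The structural metric on strictly ascending vectors.

The metric compares increment structure, so vectors of different lengths
are comparable: d(v, w) = (||dv|| + ||dw||)/2 - ||dz||, with z the
"common parts" — all entries of either vector inside the overlap window.
"""

import radialforage as rf

v, w = rf.load_fixture("example4_vectors")
z = rf.common_parts(v, w)

print("v =", [float(x) for x in v])
print("w =", [float(x) for x in w])
print("common parts z =", [float(x) for x in z])
print(f"structural distance d(v, w) = {rf.structural_distance(v, w):.6f}")
print(f"identity check    d(v, v) = {rf.structural_distance(v, v):.6f}")
print()
print("A small distance means the two sequences accumulate in a similar")
print("rhythm, regardless of where or how densely their entries sit.")
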