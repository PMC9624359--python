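"""LMRFT and SMRFT optimal paths on a packaged 20-food arena.

LMRFT (long-term memory) picks, among all remaining foods, the one whose
k-th least distance to the remaining domain is minimal; SMRFT (short-term
memory) restricts candidates to the radial ball around the current
position.  Both deplete the domain after every step.
"""

import radialforage as rf

arena = rf.load_fixture("table1_animal1")
D = rf.distance_matrix(arena)

lm = rf.lmrft_path(arena, 4, 14, D=D)
sm = rf.smrft_path(arena, 7, 4, 14, D=D)

print("LMRFT level 4:", " -> ".join(map(str, lm.labels)))
print("  first scores:", [round(s, 4) for s in lm.scores[:5]])
print("SMRFT level 4 from food 7:", " -> ".join(map(str, sm.labels)))
print(f"  total travel: LMRFT {sum(lm.legs):.2f}, SMRFT {sum(sm.legs):.2f}")
print()
print("Each score is the winning k-th-least distance at that step: the")
print("eaten food sits where 4 foods (itself included) crowd most tightly.")
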