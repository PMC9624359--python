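"""Relative minima and radial balls on a four-point toy space.

The toy space has foods x=(1,2), y=(-2,4), p=(0,5), q=(3,1), relabeled
1..4.  The k-th relative minimum from a center is the k-th least distance
to the set (self-distance 0 counts first when the center belongs to it);
the radial ball collects every food within that radius.
"""

import radialforage as rf

toy = rf.load_fixture("example1_toy")
D = rf.distance_matrix(toy)
names = {1: "x", 2: "y", 3: "p", 4: "q"}
full = set(toy.labels)

for k in range(1, 5):
    q = rf.relative_min(4, full, k, D)  # center q
    ball = rf.radial_ball(4, full, k, D)
    print(f"k={k}: min_q({k}) = {q.value:.4f} (achieved by "
          f"{names[q.achiever]}), ball = {sorted(names[b] for b in ball)}")

print()
print("The level-3 radius from q is exactly 5 (food p); a level-k forager")
print("standing at q perceives every food inside that ball as reachable.")
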