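"""Counting independent pattern origins and strict-clock dating.

Simulates an ultrametric tree with 13 leaves carrying the yellow/black
pattern planted as isolated terminals, counts the minimum number of
independent origins over all most-parsimonious reconstructions, then
converts Poisson-noised per-gene branch lengths back to time with the
beetle mitochondrial rates and recovers a planted 15 My split.
"""

from elytra import PAPER_RATE_TABLE, min_origins, split_age, time_scale
from elytra.simulate import ClockSimSpec, gen_clock_tree

sim = gen_clock_tree(
    ClockSimSpec(n_leaves=40, n_focal_origins=13, focal_state="B",
                 poisson_noise=True, seed=21)
)
rep = min_origins(sim.pattern_tree, "B")
print(f"{rep.focal_leaf_count} yellow/black leaves on a 40-leaf tree")
print(f"minimum independent origins over all MPRs: {rep.min_origins}")
print(f"every focal leaf its own origin (single terminals): {rep.terminal_only}")
print("  -> the high-contrast signal arose repeatedly, never forming clades")

pair = gen_clock_tree(
    ClockSimSpec(n_leaves=2, crown_age=15.0, poisson_noise=True, seed=5)
)
tt = time_scale(pair.pattern_tree, PAPER_RATE_TABLE)
a, b = pair.pattern_tree.leaf_labels
age = split_age(tt, a, b)
print(f"\nplanted 15 My split, estimated from noisy branch lengths: {age:.2f} My")
print("  -> strict-clock inversion at rates cox1 0.0115 / nad5 0.0177 / "
      "rrnL 0.0054 subs/site/My")
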