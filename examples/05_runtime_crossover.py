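"""Runtime-model crossover: pruned quadratic scan vs k-d-tree search.

The pruned engine is a heavily improved brute-force scan, so its runtime
grows quadratically with residue count n, while a k-d-tree neighbor search
grows linearly but pays a large per-structure construction overhead.  With
the fitted curves f(n) (pruned) and h(n) (k-d tree), solving f(n) = h(n)
gives the protein size beyond which the tree would win.
"""

from caprune import (
    KDTREE_RUNTIME_FIT,
    PRUNED_RUNTIME_FIT,
    STATIC_RUNTIME_FIT,
    solve_crossover,
)

for model in (PRUNED_RUNTIME_FIT, STATIC_RUNTIME_FIT, KDTREE_RUNTIME_FIT):
    print(f"{model.label:7s} t(n) = {model.a:.2e} n^2 + {model.b:.2e} n "
          f"+ {model.c:+.2e}  (seconds)")

n = solve_crossover(PRUNED_RUNTIME_FIT, KDTREE_RUNTIME_FIT)
print(f"\npruned engine overtaken by the k-d tree at n = {n:.0f} residues "
      f"(~{round(n, -3):.0f})")
print(f"at n = 1000: pruned {PRUNED_RUNTIME_FIT(1000):.3f} s vs "
      f"k-d tree {KDTREE_RUNTIME_FIT(1000):.3f} s")
n_static = solve_crossover(STATIC_RUNTIME_FIT, KDTREE_RUNTIME_FIT)
print(f"static-cutoff engine overtaken already at n = {n_static:.0f}")
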