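"""Generate a planted-module network and compute the four seed-aware features.

A 300-gene graph hides a 30-gene disease module (dense internal wiring);
70% of the module genes carry association scores and act as seeds.  The
printed rows show that module genes — including the unscored ones — get
systematically larger feature values than background genes.
"""

import numpy as np

from netpu import assemble_features, generate

inst = generate(n=300, module_size=30, p_in=0.3, p_out=0.01,
                hidden_fraction=0.3, rng_seed=7)
F = assemble_features(inst.net, inst.visible_seeds)

groups = {
    "visible seed": set(inst.visible_seeds.members),
    "hidden module": set(inst.hidden_positives),
    "background": set(inst.net.nodes) - inst.module,
}
print(f"{'group':<14}" + "".join(f"{c:>10}" for c in F.columns))
for name, members in groups.items():
    rows = [F.X[i] for i, g in enumerate(F.order) if g in members]
    mean = np.mean(rows, axis=0)
    print(f"{name:<14}" + "".join(f"{v:>10.3f}" for v in mean))
print("\nEach column is min-max normalized to [0,1]; larger = closer to the "
      "seed set.  Hidden module genes sit between seeds and background, "
      "which is the gradient the labeling exploits.")
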