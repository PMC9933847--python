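"""Assign the five classes P / LP / WN / LN / RN by restart propagation.

Seeds are P; the genes farthest from the P feature centroid become RN;
a Markov process with restart (alpha = 0.8) over the feature-similarity
graph ranks everything else, and the ranking is cut into equal thirds.
"""

from netpu import assemble_features, generate, label_genes

inst = generate(n=300, module_size=30, p_in=0.3, p_out=0.01,
                hidden_fraction=0.3, rng_seed=7)
F = assemble_features(inst.net, inst.visible_seeds)
out = label_genes(F, inst.visible_seeds.members)

print("class sizes:", out.counts())
hidden_labels = {g: out.label[g] for g in sorted(inst.hidden_positives)}
print("labels of the 9 hidden module genes:", sorted(hidden_labels.values()))
n_lp = sum(1 for v in hidden_labels.values() if v == "LP")
print(f"\n{n_lp}/9 unscored module genes landed in LP (likely positive): "
      "the class from which new candidate disease genes are read off.")
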