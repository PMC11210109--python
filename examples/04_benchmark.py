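"""Benchmark the seven connectivity scores by average precision.

Generates datasets of 60 interconnected pairs with true connectivities
evenly spaced on [0, 1], ranks the pairs by each method's estimate, and
scores retrieval of the truly most-connected pairs (top-N) by average
precision, averaged over 5 regenerated datasets.  Raw signatures are used
here to keep the example fast; pass use_count_pipeline=True for
DE-re-inferred signatures.
"""

from consig import SimulationConfig, evaluate_methods

params = SimulationConfig(n_genes=1000)
result = evaluate_methods(
    params,
    methods=("cmap1", "cmap2", "css", "xsum", "xcos", "xpearson", "xspearman"),
    top_n_grid=(1, 5, 10),
    n_pairs=60,
    n_dataset_replicates=5,
    seed=7,
    top_k=10,
    n_extreme=50,
)

print("mean average precision (5 dataset replicates, 60 pairs):")
print(result.summary.pivot(index="method", columns="top_n", values="mean_ap").round(3))
print("AP = 1 means the truly most-connected pairs were ranked first;")
print("the extreme similarity scores typically lead, cmap1 trails.")
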