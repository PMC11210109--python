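"""From a simulated signature to read counts and back.

Builds triplicate treated/control read counts for one signature (negative
binomial, library size 2e6) and re-infers the signature with the NB-Wald
test.  The printed correlation measures how well the inference pipeline
recovers strong deregulation; the near-zero peak of the raw simulated LFC
distribution is flattened by the added experimental variability.
"""

import numpy as np

from consig import (
    CountModel,
    ModalityDistribution,
    compose_lfc,
    default_realistic_bank,
    nb_wald_de,
    sample_base_expression,
    sample_primary_layers,
    simulate_count_matrix,
)

bank = default_realistic_bank()
omega = ModalityDistribution(omega=(0.07, 0.80, 0.13))
n_genes = 3000

layers = sample_primary_layers(omega, bank, n_genes, seed=1)
truth = compose_lfc(layers, bank)
base = sample_base_expression(n_genes, seed=2)
model = CountModel(total_reads=2_000_000)

counts = simulate_count_matrix(layers, bank, base, model, seed=3)
result = nb_wald_de(counts)

sel = (np.abs(truth.lfc) >= 1) & (base.mu_tilde >= 50)
corr = np.corrcoef(truth.lfc[sel], result.lfc_hat[sel])[0, 1]
peak_before = (np.abs(truth.lfc) < 0.05).mean()
peak_after = (np.abs(result.lfc_hat) < 0.05).mean()
n_sig = (result.padj < 0.05).sum()

print(f"count matrix:                  {counts.counts.shape[0]} genes x "
      f"{counts.counts.shape[1]} samples")
print(f"library sizes (reads):         {counts.counts.sum(axis=0).tolist()}")
print(f"recovery corr (|LFC|>=1, mu>=50): {corr:.3f}")
print(f"genes with padj < 0.05:        {n_sig}")
print(f"fraction |LFC| < 0.05 before:  {peak_before:.3f}  after: {peak_after:.3f}")
print("The re-inferred signature keeps strong deregulation but spreads the")
print("non-deregulated spike, as a real RNA-seq analysis would.")
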