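"""Small seeded synthetic fixtures so tests and examples need no downloads.

All generators are deterministic in the seed; ``make_fixture_dataset``
writes plain-text files (TSV) and returns their paths.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .benchmark import SimulationConfig, generate_benchmark
from .counts import CountModel, sample_base_expression, simulate_count_matrix
from .io import write_count_matrix, write_signature_table
from .signature_model import (
    SignatureVector,
    as_rng,
    default_gene_ids,
    default_realistic_bank,
    sample_primary_layers,
    spawn_rngs,
)
from .signature_model import ModalityDistribution

__all__ = ["trimodal_lfc_vector", "make_fixture_dataset"]


def trimodal_lfc_vector(
    n_genes: int = 18_000,
    seed=0,
    centers=(-2.0, 0.0, 2.0),
    sd: float = 0.1,
    weights=(1 / 3, 1 / 3, 1 / 3),
) -> SignatureVector:
    """Equal-mixture trimodal Gaussian LFC vector (mode-detection fixture)."""
    rng = as_rng(seed)
    comp = rng.choice(len(centers), size=n_genes, p=np.asarray(weights) / np.sum(weights))
    lfc = rng.normal(np.asarray(centers)[comp], sd)
    return SignatureVector(gene_ids=default_gene_ids(n_genes), lfc=lfc)


def make_fixture_dataset(kind: str, seed=0, outdir=".") -> list[Path]:
    """Write a named fixture to ``outdir`` and return the file paths.

    Kinds: ``lfc_vector`` (trimodal LFC TSV), ``count_matrix`` (200-gene
    3v3 counts + sample sheet), ``benchmark_small`` (20 interconnected
    pairs in long format + truth table).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind == "lfc_vector":
        path = outdir / "fixture_lfc.tsv"
        write_signature_table(trimodal_lfc_vector(seed=seed), path)
        return [path]
    if kind == "count_matrix":
        bank = default_realistic_bank()
        r_layers, r_base, r_counts = spawn_rngs(seed, 3)
        layers = sample_primary_layers(
            ModalityDistribution(omega=(0.1, 0.8, 0.1)), bank, 200, r_layers
        )
        base = sample_base_expression(200, r_base)
        model = CountModel(total_reads=200_000)
        cm = simulate_count_matrix(layers, bank, base, model, r_counts)
        counts_path = outdir / "fixture_counts.tsv"
        samples_path = outdir / "fixture_samples.tsv"
        write_count_matrix(cm, counts_path, samples_path)
        return [counts_path, samples_path]
    if kind == "benchmark_small":
        params = SimulationConfig(n_genes=500)
        pairs = generate_benchmark(20, params, use_count_pipeline=False, seed=seed)
        long_rows = []
        truth_rows = []
        for p in pairs:
            truth_rows.append(
                {"pair_id": p.pair_id, "true_connectivity": p.true_connectivity}
            )
            long_rows.append(
                pd.DataFrame(
                    {
                        "pair_id": p.pair_id,
                        "gene_id": p.primary.gene_ids,
                        "lfc_primary": p.primary.lfc,
                        "lfc_secondary": p.secondary.lfc,
                    }
                )
            )
        pairs_path = outdir / "fixture_benchmark_pairs.tsv"
        truth_path = outdir / "fixture_benchmark_truth.tsv"
        pd.concat(long_rows).to_csv(pairs_path, sep="\t", index=False)
        pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
        return [pairs_path, truth_path]
    raise ValueError(f"unknown fixture kind {kind!r}")
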