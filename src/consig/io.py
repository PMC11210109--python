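"""Tabular and YAML I/O: signatures, banks, count matrices, run configs.

All tabular formats are TSV with headers; configurations are YAML.  A run
is reproducible from (config, seed) alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
import numpy as np
import pandas as pd
import yaml

from .counts import BaseExpression, CountMatrix, CountModel
from .signature_model import (
    ModalityBlock,
    SignatureVector,
    SubmodalityBank,
    build_submodality_bank,
)
from .transitions import ProbabilityTransitionConfig, SubmodalityTransitionConfig

__all__ = [
    "read_signature_table",
    "write_signature_table",
    "read_bank_config",
    "write_bank_config",
    "bank_to_config",
    "write_count_matrix",
    "read_count_matrix",
    "write_base_expression",
    "read_base_expression",
    "RunConfig",
]

_SIGNATURE_COLUMNS = ("gene_id", "lfc")


def read_signature_table(path) -> SignatureVector:
    """Read a signature TSV (gene_id, lfc[, pvalue, padj]).

    Malformed rows are reported with their 1-based file line numbers
    (header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in _SIGNATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    numeric_cols = ["lfc"] + [c for c in ("pvalue", "padj") if c in df.columns]
    for col in numeric_cols:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(values)]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:10])
            raise ValueError(
                f"{path}: non-numeric or non-finite {col!r} at line(s) {lines}"
            )
        df[col] = values
    return SignatureVector(
        gene_ids=df.gene_id.to_numpy(),
        lfc=df.lfc.to_numpy(),
        pvalue=df.pvalue.to_numpy() if "pvalue" in df.columns else None,
        padj=df.padj.to_numpy() if "padj" in df.columns else None,
    )


def write_signature_table(sig: SignatureVector, path) -> None:
    data = {"gene_id": sig.gene_ids, "lfc": sig.lfc}
    if sig.pvalue is not None:
        data["pvalue"] = sig.pvalue
    if sig.padj is not None:
        data["padj"] = sig.padj
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def bank_to_config(bank: SubmodalityBank) -> dict:
    """Serialize a bank back into the YAML configuration structure."""

    def side(blocks: dict[int, ModalityBlock]) -> dict:
        keys = {1: "up", 2: "null", 3: "down"}
        out = {}
        for m, key in keys.items():
            block = blocks[m]
            out[key] = [
                {
                    "family": d.family,
                    "params": list(d.params),
                    "proportion": p,
                }
                for d, p in zip(block.descriptors, block.proportions)
            ]
        return out

    config = {"modalities": side(bank.primary)}
    if bank.secondary is not bank.primary:
        config["secondary"] = {"modalities": side(bank.secondary)}
    return config


def read_bank_config(path) -> SubmodalityBank:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    return build_submodality_bank(config)


def write_bank_config(bank: SubmodalityBank, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(bank_to_config(bank), fh, sort_keys=False)


def write_count_matrix(cm: CountMatrix, counts_path, samples_path) -> None:
    """Counts TSV (first column gene_id) + sample sheet TSV."""
    df = cm.to_dataframe()
    df.insert(0, "gene_id", df.index)
    df.to_csv(counts_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_id": [f"{c}_{r}" for c, r in zip(cm.condition, cm.replicate)],
            "condition": cm.condition,
            "replicate": cm.replicate,
        }
    ).to_csv(samples_path, sep="\t", index=False)


def read_count_matrix(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", dtype={"gene_id": str})
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    gene_ids = counts.pop("gene_id").to_numpy()
    mat = counts.to_numpy()
    if not np.issubdtype(mat.dtype, np.integer):
        raise ValueError(f"{counts_path}: counts must be integers")
    if list(counts.columns) != samples.sample_id.tolist():
        raise ValueError("count columns and sample sheet disagree")
    return CountMatrix(
        counts=mat,
        condition=samples.condition.tolist(),
        replicate=samples.replicate.tolist(),
        gene_ids=gene_ids,
    )


def write_base_expression(base: BaseExpression, gene_ids, path) -> None:
    pd.DataFrame(
        {"gene_id": gene_ids, "mu_tilde": base.mu_tilde, "length": base.lengths}
    ).to_csv(path, sep="\t", index=False)


def read_base_expression(path) -> tuple[np.ndarray, BaseExpression]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "mu_tilde"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    lengths = df.length.to_numpy() if "length" in df.columns else None
    return df.gene_id.to_numpy(), BaseExpression(
        mu_tilde=df.mu_tilde.to_numpy(), lengths=lengths
    )


@dataclass
class RunConfig:
    """Serializable description of a full simulation run."""

    seed: int = 0
    n_genes: int = 10_000
    omega: tuple[float, float, float] = (0.07, 0.80, 0.13)
    connectivity: float = 0.5
    gamma: float = 0.02
    sub_strategy: str = "deterministic"
    sub_copula_family: str | None = None
    sub_target_correlation: float | None = None
    prob_strategy: str = "deterministic"
    prob_copula_family: str | None = None
    prob_target_correlation: float | None = None
    total_reads: int = 10_000_000
    size_factor: float = 1.0 / 3.0
    control_noise_sd: float = 0.5
    n_replicates: int = 3
    n_pairs: int = 100
    top_n_grid: tuple[int, ...] = (1, 5, 10, 50)
    n_dataset_replicates: int = 20

    def sub_config(self) -> SubmodalityTransitionConfig:
        return SubmodalityTransitionConfig(
            strategy=self.sub_strategy,
            copula_family=self.sub_copula_family,
            target_correlation=self.sub_target_correlation,
        )

    def prob_config(self) -> ProbabilityTransitionConfig:
        return ProbabilityTransitionConfig(
            strategy=self.prob_strategy,
            copula_family=self.prob_copula_family,
            target_correlation=self.prob_target_correlation,
        )

    def count_model(self) -> CountModel:
        return CountModel(
            total_reads=self.total_reads,
            size_factor=self.size_factor,
            control_noise_sd=self.control_noise_sd,
        )

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["omega"] = list(data["omega"])
        data["top_n_grid"] = list(data["top_n_grid"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["omega"] = tuple(data["omega"])
        data["top_n_grid"] = tuple(data["top_n_grid"])
        return cls(**data)
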