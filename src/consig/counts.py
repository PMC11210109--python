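"""From simulated signatures to read counts and back to re-inferred DE.

The pipeline mimics how real bulk RNA-seq differential-expression data are
produced: the simulated LFC acts on a control expression level chosen so
that the mean of control and treated expression equals a supplied base
expression; per-sample read counts are negative-binomial with library-size
normalization; a simplified NB-Wald two-group test re-infers per-gene LFC
estimates and Benjamini-Hochberg adjusted p-values.

The NB parameterization uses a mean ``delta`` and size ``r = f * delta``
(variance ``delta * (1 + 1/f)``), i.e. a constant variance/mean ratio set
by the size factor ``f``.  Large ``f`` approaches the Poisson limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signature_model import (
    LayerSet,
    SignatureVector,
    SubmodalityBank,
    as_rng,
    compose_lfc,
    default_gene_ids,
    spawn_rngs,
)
from .transitions import (
    ConnectivityModel,
    ProbabilityTransitionConfig,
    SubmodalityTransitionConfig,
    simulate_secondary,
)

__all__ = [
    "BaseExpression",
    "CountModel",
    "CountMatrix",
    "DEResult",
    "simulate_replicate_layers",
    "control_expression",
    "perturb_control",
    "simulate_counts",
    "median_of_ratios_size_factors",
    "nb_wald_de",
    "simulate_count_matrix",
    "reinfer_signature",
    "sample_base_expression",
    "xi_per_gene",
]


@dataclass(frozen=True)
class BaseExpression:
    """Mean expression across conditions (TPM-like) and gene lengths."""

    mu_tilde: np.ndarray
    lengths: np.ndarray | None = None

    def __post_init__(self):
        mu = np.asarray(self.mu_tilde, dtype=float)
        if (mu < 0).any() or not np.isfinite(mu).all():
            raise ValueError("base expression must be finite and nonnegative")
        if self.lengths is None:
            lengths = np.ones_like(mu)  # 3'RNA-seq convention
        else:
            lengths = np.asarray(self.lengths, dtype=float)
            if lengths.shape != mu.shape or (lengths <= 0).any():
                raise ValueError("gene lengths must be positive and match mu")
        object.__setattr__(self, "mu_tilde", mu)
        object.__setattr__(self, "lengths", lengths)


@dataclass(frozen=True)
class CountModel:
    """Read-count generation parameters.

    ``size_factor`` f sets the NB size r = f * delta (default 1/3, i.e.
    dispersion factor delta/3); ``control_noise_sd`` is the sd of the
    log2-scale Gaussian noise applied to control replicates.
    """

    total_reads: int = 10_000_000
    size_factor: float = 1.0 / 3.0
    control_noise_sd: float = 0.5

    def __post_init__(self):
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.size_factor <= 0:
            raise ValueError("size_factor must be positive")
        if self.control_noise_sd < 0:
            raise ValueError("control_noise_sd must be nonnegative")


@dataclass
class CountMatrix:
    """Genes x samples integer counts with condition/replicate labels."""

    counts: np.ndarray
    condition: list[str]
    replicate: list[int]
    gene_ids: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or (c < 0).any():
            raise ValueError("counts must be a nonnegative genes x samples matrix")
        if not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be integers")
        if c.shape[1] != len(self.condition) or c.shape[1] != len(self.replicate):
            raise ValueError("per-sample labels must match the column count")
        for cond in ("treated", "control"):
            if cond not in self.condition:
                raise ValueError(f"condition {cond!r} needs at least one sample")
        self.counts = c
        self.gene_ids = np.asarray(self.gene_ids)

    def columns(self, condition: str) -> np.ndarray:
        idx = [i for i, c in enumerate(self.condition) if c == condition]
        return self.counts[:, idx]

    def to_dataframe(self) -> pd.DataFrame:
        names = [f"{c}_{r}" for c, r in zip(self.condition, self.replicate)]
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=names)


@dataclass
class DEResult:
    """Simplified NB-Wald differential-expression output."""

    gene_ids: np.ndarray
    lfc_hat: np.ndarray
    se: np.ndarray
    wald_stat: np.ndarray
    pvalue: np.ndarray
    padj: np.ndarray

    def to_signature(self) -> SignatureVector:
        return SignatureVector(
            gene_ids=self.gene_ids, lfc=self.lfc_hat, pvalue=self.pvalue, padj=self.padj
        )


def simulate_replicate_layers(
    layers: LayerSet,
    n_replicates: int,
    bank: SubmodalityBank,
    seed,
    rep_connectivity: float = 0.9,
    rep_noise: float = 0.02,
) -> list[LayerSet]:
    """In-silico replicates of a signature via near-identity transitions.

    Each replicate is a secondary signature of the same parent with
    deterministic sub-modality/probability transitions and a connectivity
    close to 1 (defaults c = 0.9, gamma = 0.02).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    model = ConnectivityModel(c=rep_connectivity, gamma=rep_noise)
    sub = SubmodalityTransitionConfig(strategy="deterministic")
    prob = ProbabilityTransitionConfig(strategy="deterministic")
    rngs = spawn_rngs(seed, n_replicates)
    return [
        simulate_secondary(layers, model, sub, prob, bank, rng)[0] for rng in rngs
    ]


def control_expression(base: BaseExpression, xi: np.ndarray) -> np.ndarray:
    """Control expression level mu_Ct = 2 * mu_tilde / (1 + 2^xi).

    ``xi`` is each gene's sub-modality mean LFC.  The identity
    (mu_Ct + mu_Ct * 2^xi) / 2 = mu_tilde holds exactly, so the supplied
    base expression is the mean of the control and treated levels.
    """
    xi = np.asarray(xi, dtype=float)
    if xi.shape != base.mu_tilde.shape:
        raise ValueError("xi must match the base expression length")
    return 2.0 * base.mu_tilde / (1.0 + np.exp2(xi))


def xi_per_gene(layers: LayerSet, bank: SubmodalityBank, signature_index: int = 1) -> np.ndarray:
    """Mean LFC of each gene's assigned sub-modality distribution."""
    out = np.empty(layers.n_genes, dtype=float)
    for m in (1, 2, 3):
        block = bank.block(signature_index, m)
        xi = block.xi
        sel = layers.modality == m
        out[sel] = xi[layers.submodality[sel] - 1]
    return out


def perturb_control(mu_control: np.ndarray, seed, sd: float = 0.5) -> np.ndarray:
    """Multiplicative log2-scale Gaussian noise: mu * 2^eps, eps ~ N(0, sd)."""
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    mu = np.asarray(mu_control, dtype=float)
    if sd == 0:
        return mu.copy()
    eps = as_rng(seed).normal(0.0, sd, size=mu.shape)
    return mu * np.exp2(eps)


def expected_counts(
    mu_control: np.ndarray,
    fold_change: np.ndarray,
    base: BaseExpression,
    model: CountModel,
) -> np.ndarray:
    """Per-gene NB means delta = mu_Ct * X * L / S * N, summing exactly to N."""
    mu = np.asarray(mu_control, dtype=float)
    x = np.asarray(fold_change, dtype=float)
    if (x <= 0).any():
        raise ValueError("fold changes must be positive (linear scale)")
    w = mu * x * base.lengths
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero expression: library composition undefined")
    return w / total * model.total_reads


def simulate_counts(
    mu_control: np.ndarray,
    fold_change: np.ndarray,
    base: BaseExpression,
    model: CountModel,
    seed,
) -> np.ndarray:
    """Draw one sample's counts: K_i ~ NB(mean delta_i, size f * delta_i)."""
    delta = expected_counts(mu_control, fold_change, base, model)
    rng = as_rng(seed)
    f = model.size_factor
    counts = np.zeros(delta.size, dtype=np.int64)
    pos = delta > 0
    # numpy's NB takes (n=size, p); with size r = f*delta, p = f/(1+f)
    counts[pos] = rng.negative_binomial(f * delta[pos], f / (1.0 + f))
    return counts


def median_of_ratios_size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Per-sample median of count / geometric-mean ratios (library scaling)."""
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene with nonzero counts in every sample")
    sub = mat[all_nonzero]
    geo_mean = np.exp(np.log(sub).mean(axis=1))
    return np.median(sub / geo_mean[:, None], axis=0)


_PSEUDOCOUNT = 0.5
_DISPERSION_FLOOR = 1e-8


def nb_wald_de(counts: CountMatrix) -> DEResult:
    """Two-group NB Wald test on normalized counts (simplified).

    Median-of-ratios normalization; per-gene dispersion by method of
    moments with a floor; log2 ratio of group means with a pseudocount;
    delta-method standard errors; two-sided normal p-values; BH adjustment.
    This is a transparent stand-in for a full NB-GLM analysis, not a
    re-implementation of one.
    """
    treated = [i for i, c in enumerate(counts.condition) if c == "treated"]
    control = [i for i, c in enumerate(counts.condition) if c == "control"]
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need at least two replicates per condition")
    sf = median_of_ratios_size_factors(counts)
    norm = counts.counts / sf[None, :]
    nt = norm[:, treated]
    nc = norm[:, control]
    mt, mc = nt.mean(axis=1), nc.mean(axis=1)
    vt = nt.var(axis=1, ddof=1)
    vc = nc.var(axis=1, ddof=1)

    # method-of-moments NB dispersion alpha: var = m + alpha * m^2, pooled
    with np.errstate(divide="ignore", invalid="ignore"):
        at = np.where(mt > 0, (vt - mt) / mt**2, 0.0)
        ac = np.where(mc > 0, (vc - mc) / mc**2, 0.0)
    alpha = np.clip((at + ac) / 2.0, _DISPERSION_FLOOR, None)

    mt_p = mt + _PSEUDOCOUNT
    mc_p = mc + _PSEUDOCOUNT
    lfc_hat = np.log2(mt_p / mc_p)
    var_mt = (mt + alpha * mt**2) / len(treated)
    var_mc = (mc + alpha * mc**2) / len(control)
    se = np.sqrt(var_mt / mt_p**2 + var_mc / mc_p**2) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, lfc_hat / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(wald))
    padj = multipletests(pvalue, method="fdr_bh")[1]
    return DEResult(
        gene_ids=counts.gene_ids,
        lfc_hat=lfc_hat,
        se=se,
        wald_stat=wald,
        pvalue=pvalue,
        padj=np.clip(padj, 0.0, 1.0),
    )


def sample_base_expression(n_genes: int, seed, median_tpm: float = 50.0, log_sd: float = 1.2) -> BaseExpression:
    """Log-normal TPM-like base expression (3'RNA-seq: unit lengths)."""
    rng = as_rng(seed)
    mu = rng.lognormal(mean=np.log(median_tpm), sigma=log_sd, size=n_genes)
    return BaseExpression(mu_tilde=mu)


def simulate_count_matrix(
    layers: LayerSet,
    bank: SubmodalityBank,
    base: BaseExpression,
    model: CountModel,
    seed,
    n_replicates: int = 3,
    rep_connectivity: float = 0.9,
    rep_noise: float = 0.02,
) -> CountMatrix:
    """Replicated treated/control counts for one simulated signature.

    Treated variability comes from in-silico signature replicates
    (c = rep_connectivity, gamma = rep_noise); control variability from
    multiplicative log2 Gaussian noise on the control expression level.
    """
    rng_rep, rng_treat, rng_ctrl_noise, rng_ctrl = spawn_rngs(seed, 4)
    replicates = simulate_replicate_layers(
        layers, n_replicates, bank, rng_rep,
        rep_connectivity=rep_connectivity, rep_noise=rep_noise,
    )
    xi = xi_per_gene(layers, bank, signature_index=1)
    mu_ctrl = control_expression(base, xi)

    columns, condition, replicate = [], [], []
    treat_rngs = spawn_rngs(rng_treat, n_replicates)
    for r, (rep_layers, rng) in enumerate(zip(replicates, treat_rngs), start=1):
        lfc = compose_lfc(rep_layers, bank, signature_index=2).lfc
        columns.append(simulate_counts(mu_ctrl, np.exp2(lfc), base, model, rng))
        condition.append("treated")
        replicate.append(r)
    noise_rngs = spawn_rngs(rng_ctrl_noise, n_replicates)
    ctrl_rngs = spawn_rngs(rng_ctrl, n_replicates)
    ones = np.ones(layers.n_genes)
    for r, (rng_n, rng_c) in enumerate(zip(noise_rngs, ctrl_rngs), start=1):
        mu_rep = perturb_control(mu_ctrl, rng_n, sd=model.control_noise_sd)
        columns.append(simulate_counts(mu_rep, ones, base, model, rng_c))
        condition.append("control")
        replicate.append(r)
    return CountMatrix(
        counts=np.column_stack(columns),
        condition=condition,
        replicate=replicate,
        gene_ids=default_gene_ids(layers.n_genes),
    )


def reinfer_signature(
    layers: LayerSet,
    bank: SubmodalityBank,
    base: BaseExpression,
    model: CountModel,
    seed,
    n_replicates: int = 3,
) -> SignatureVector:
    """Full pipeline: layers -> replicates -> counts -> NB-Wald signature."""
    cm = simulate_count_matrix(layers, bank, base, model, seed, n_replicates=n_replicates)
    return nb_wald_de(cm).to_signature()
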