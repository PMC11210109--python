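"""Layer-wise transitions from a primary to a secondary signature.

The secondary signature is generated conditionally on the primary, one
layer at a time:

1. **Modality** -- each gene's secondary status is drawn from the row of a
   3x3 row-stochastic transition matrix indexed by its primary status.  The
   matrix is either given in full or built from the symmetric connectivity
   model with connectivity ``c`` in [-1, 1] and non-deregulated noise factor
   ``gamma`` in [0, 0.5]:

       lambda_11 = lambda_33 = (1/2)(1 + c)(1 - gamma/2)
       lambda_13 = lambda_31 = (1/2)(1 - c)(1 - gamma/2)
       lambda_12 = lambda_21 = lambda_32 = lambda_23 = gamma/2
       lambda_22 = 1 - gamma

2. **Sub-modality** -- independent, deterministic, stochastic (binomial
   link) or copula-coupled; whenever a gene is non-deregulated in either
   signature an independent draw is used.

3. **Probability** -- independent, deterministic, or copula-coupled.

All transitions are gene-wise independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .copulas import (
    COPULA_FAMILIES,
    DiscreteCopulaJoint,
    copula_conditional_sample,
    fit_copula_theta,
    fit_discrete_copula,
)
from .signature_model import (
    DOWN,
    MODALITIES,
    NULL,
    UP,
    LayerSet,
    SignatureVector,
    SubmodalityBank,
    as_rng,
    compose_lfc,
    sample_submodalities,
    spawn_rngs,
)

__all__ = [
    "ConnectivityModel",
    "TransitionMatrix",
    "SubmodalityTransitionConfig",
    "ProbabilityTransitionConfig",
    "symmetric_transition_matrix",
    "transition_modalities",
    "transition_submodalities",
    "transition_probabilities",
    "simulate_secondary",
]


@dataclass(frozen=True)
class ConnectivityModel:
    """Symmetric connectivity model parameters: (c, gamma)."""

    c: float
    gamma: float = 0.02

    def __post_init__(self):
        if not -1.0 <= self.c <= 1.0:
            raise ValueError(f"connectivity c must lie in [-1, 1], got {self.c}")
        if not 0.0 <= self.gamma <= 0.5:
            raise ValueError(f"noise gamma must lie in [0, 0.5], got {self.gamma}")


@dataclass(frozen=True)
class TransitionMatrix:
    """3x3 row-stochastic modality transition matrix Lambda."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("transition matrix must be 3x3")
        if ((m < 0) | (m > 1)).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12, rtol=0):
            raise ValueError("transition matrix rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    def row(self, modality: int) -> np.ndarray:
        return self.matrix[modality - 1]


@dataclass(frozen=True)
class SubmodalityTransitionConfig:
    strategy: str = "deterministic"
    copula_family: str | None = None
    target_correlation: float | None = None

    def __post_init__(self):
        if self.strategy not in ("independent", "deterministic", "stochastic", "copula"):
            raise ValueError(f"unknown sub-modality strategy {self.strategy!r}")
        _check_copula_fields(self.strategy, self.copula_family, self.target_correlation)


@dataclass(frozen=True)
class ProbabilityTransitionConfig:
    strategy: str = "deterministic"
    copula_family: str | None = None
    target_correlation: float | None = None

    def __post_init__(self):
        if self.strategy not in ("independent", "deterministic", "copula"):
            raise ValueError(f"unknown probability strategy {self.strategy!r}")
        _check_copula_fields(self.strategy, self.copula_family, self.target_correlation)


def _check_copula_fields(strategy, family, target):
    if strategy == "copula":
        if family not in COPULA_FAMILIES:
            raise ValueError("copula strategy requires copula_family in "
                             f"{COPULA_FAMILIES}")
        if target is None or not -1 < float(target) < 1:
            raise ValueError("copula strategy requires target_correlation in (-1, 1)")
    elif family is not None or target is not None:
        raise ValueError("copula fields are only valid with the copula strategy")


def symmetric_transition_matrix(model: ConnectivityModel) -> TransitionMatrix:
    """Build Lambda from the symmetric connectivity model (c, gamma)."""
    c, g = model.c, model.gamma
    keep = 0.5 * (1.0 + c) * (1.0 - g / 2.0)
    flip = 0.5 * (1.0 - c) * (1.0 - g / 2.0)
    half_g = g / 2.0
    matrix = np.array(
        [
            [keep, half_g, flip],
            [half_g, 1.0 - g, half_g],
            [flip, half_g, keep],
        ]
    )
    return TransitionMatrix(matrix=matrix)


def transition_modalities(
    primary_modality: np.ndarray,
    matrix: TransitionMatrix,
    seed,
) -> np.ndarray:
    """Sample each secondary modality from its primary modality's row."""
    primary_modality = np.asarray(primary_modality, dtype=np.int64)
    rng = as_rng(seed)
    u = rng.uniform(size=primary_modality.size)
    out = np.empty(primary_modality.size, dtype=np.int64)
    for alpha in MODALITIES:
        sel = primary_modality == alpha
        if not sel.any():
            continue
        cum = np.cumsum(matrix.row(alpha))
        out[sel] = 1 + np.searchsorted(cum, u[sel], side="right").clip(max=2)
    return out


def transition_submodalities(
    primary: LayerSet,
    secondary_modality: np.ndarray,
    bank: SubmodalityBank,
    config: SubmodalityTransitionConfig,
    seed,
) -> np.ndarray:
    """Generate the secondary sub-modality layer.

    Genes non-deregulated in either signature always get an independent
    draw from the secondary bank proportions; doubly-deregulated genes
    follow the configured strategy.
    """
    secondary_modality = np.asarray(secondary_modality, dtype=np.int64)
    if secondary_modality.shape != primary.modality.shape:
        raise ValueError("secondary modality length mismatch")
    rng_indep, rng_strategy = spawn_rngs(seed, 2)

    out = sample_submodalities(secondary_modality, bank, 2, rng_indep)
    if config.strategy == "independent":
        return out

    linked = (primary.modality != NULL) & (secondary_modality != NULL)
    if not linked.any():
        return out

    if config.strategy in ("deterministic", "stochastic"):
        pairs = set(
            zip(primary.modality[linked].tolist(), secondary_modality[linked].tolist())
        )
        for alpha, beta in pairs:
            if bank.count(1, alpha) != bank.count(2, beta):
                raise ValueError(
                    f"{config.strategy} sub-modality transition requires equal "
                    f"sub-modality counts; N(1,{alpha}) != N(2,{beta})"
                )
        if config.strategy == "deterministic":
            out[linked] = primary.submodality[linked]
        else:
            tau = primary.submodality[linked]
            n = np.array([bank.count(1, a) for a in primary.modality[linked]])
            draws = rng_strategy.binomial(n, tau / n)
            out[linked] = np.clip(draws, 1, n)  # 0 falls outside rank support
        return out

    # copula strategy: one fitted joint per (alpha, beta) modality pair
    cache: dict[tuple[int, int], DiscreteCopulaJoint] = {}
    for alpha in (UP, DOWN):
        for beta in (UP, DOWN):
            sel = linked & (primary.modality == alpha) & (secondary_modality == beta)
            if not sel.any():
                continue
            key = (alpha, beta)
            if key not in cache:
                cache[key] = fit_discrete_copula(
                    bank.block(1, alpha).proportions,
                    bank.block(2, beta).proportions,
                    config.copula_family,
                    config.target_correlation,
                )
            joint = cache[key]
            tau = primary.submodality[sel]
            u = rng_strategy.uniform(size=tau.size)
            n2 = joint.joint.shape[1]
            drawn = np.empty(tau.size, dtype=np.int64)
            for t in np.unique(tau):
                row = joint.conditional_row(int(t))
                cum = np.cumsum(row)
                mask = tau == t
                drawn[mask] = 1 + np.searchsorted(
                    cum, u[mask], side="right"
                ).clip(max=n2 - 1)
            out[sel] = drawn
    return out


def transition_probabilities(
    primary_probability: np.ndarray,
    config: ProbabilityTransitionConfig,
    seed,
) -> np.ndarray:
    """Generate the secondary probability layer."""
    psi = np.asarray(primary_probability, dtype=float)
    if ((psi < 0) | (psi > 1)).any():
        raise ValueError("primary probabilities must lie in [0, 1]")
    if config.strategy == "deterministic":
        return psi.copy()
    if config.strategy == "independent":
        return as_rng(seed).uniform(size=psi.size)
    theta = fit_copula_theta(config.copula_family, config.target_correlation)
    return copula_conditional_sample(psi, config.copula_family, theta, seed)


def simulate_secondary(
    primary: LayerSet,
    model: ConnectivityModel | TransitionMatrix,
    sub_config: SubmodalityTransitionConfig,
    prob_config: ProbabilityTransitionConfig,
    bank: SubmodalityBank,
    seed,
    gene_ids: np.ndarray | None = None,
) -> tuple[LayerSet, SignatureVector]:
    """Generate the secondary layers and LFC vector from a primary signature.

    Modality, sub-modality and probability transitions are applied in that
    order; the LFC is composed with the bank's secondary quantile functions.
    """
    if isinstance(model, ConnectivityModel):
        matrix = symmetric_transition_matrix(model)
    else:
        matrix = model
    rng_mod, rng_sub, rng_prob = spawn_rngs(seed, 3)
    modality = transition_modalities(primary.modality, matrix, rng_mod)
    submodality = transition_submodalities(primary, modality, bank, sub_config, rng_sub)
    probability = transition_probabilities(primary.probability, prob_config, rng_prob)
    layers = LayerSet(modality=modality, submodality=submodality, probability=probability)
    signature = compose_lfc(layers, bank, signature_index=2, gene_ids=gene_ids)
    return layers, signature
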