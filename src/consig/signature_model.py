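"""Three-layer model of differential-expression signatures.

A signature is a per-gene vector of log2 fold changes (LFC).  Each gene's
LFC is decomposed into three layers:

* **modality** -- the deregulation status: up-regulated (1), non-deregulated
  (2) or down-regulated (3);
* **sub-modality** -- a rank within the modality selecting one amplitude
  distribution (its quantile function);
* **probability** -- a uniform value in [0, 1] mapped through the selected
  quantile function to yield the LFC.

Primary signatures are simulated independently: the modality is drawn from a
categorical distribution ``omega``, the sub-modality from per-modality
proportions ``phi``, and the probability uniformly.  Deregulated amplitudes
are gamma-distributed (signed), the non-deregulated mode is a Gaussian
centered near zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = [
    "UP",
    "NULL",
    "DOWN",
    "MODALITIES",
    "ModalityDistribution",
    "SubmodalityDescriptor",
    "ModalityBlock",
    "SubmodalityBank",
    "LayerSet",
    "SignatureVector",
    "build_submodality_bank",
    "default_realistic_bank",
    "sample_primary_layers",
    "compose_lfc",
]

#: Modality codes.  Fixed: transition-matrix rows/columns are indexed by them.
UP, NULL, DOWN = 1, 2, 3
MODALITIES = (UP, NULL, DOWN)

_MODALITY_KEYS = {"up": UP, "null": NULL, "down": DOWN}
_MODALITY_SIGNS = {UP: 1, NULL: 1, DOWN: -1}


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_rngs(seed, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators deterministically.

    One seeded generator per top-level call; child streams per layer so that
    draws for one layer never reshuffle another.
    """
    if isinstance(seed, np.random.Generator):
        return [as_rng(s) for s in seed.bit_generator.seed_seq.spawn(n)]
    return [as_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass(frozen=True)
class ModalityDistribution:
    """Categorical law of the modality layer: (P(up), P(null), P(down))."""

    omega: tuple[float, float, float]

    def __post_init__(self):
        om = tuple(float(w) for w in self.omega)
        if len(om) != 3:
            raise ValueError("omega must have exactly three entries")
        if any(w < 0 or w > 1 for w in om):
            raise ValueError(f"omega entries must lie in [0, 1], got {om}")
        if abs(sum(om) - 1.0) > 1e-12:
            raise ValueError(f"omega must sum to 1, got sum {sum(om)!r}")
        object.__setattr__(self, "omega", om)

    @property
    def as_array(self) -> np.ndarray:
        return np.asarray(self.omega, dtype=float)


@dataclass(frozen=True)
class SubmodalityDescriptor:
    """One amplitude distribution: a signed quantile function.

    ``family`` is ``"gamma"`` (params: shape, scale) or ``"gaussian"``
    (params: mean, sd).  ``sign`` is applied to the base quantile, so a
    down-regulated gamma sub-modality maps probability p to −Q_gamma(p).
    """

    family: str
    params: tuple[float, float]
    sign: int = 1

    def __post_init__(self):
        if self.family not in ("gamma", "gaussian"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        p = tuple(float(x) for x in self.params)
        if len(p) != 2:
            raise ValueError("params must hold exactly two values")
        if self.family == "gamma" and (p[0] <= 0 or p[1] <= 0):
            raise ValueError(f"gamma shape/scale must be positive, got {p}")
        if self.family == "gaussian" and p[1] < 0:
            raise ValueError("gaussian sd must be nonnegative")
        object.__setattr__(self, "params", p)

    @property
    def xi(self) -> float:
        """Mean LFC of the sub-modality (analytic)."""
        if self.family == "gamma":
            return self.sign * self.params[0] * self.params[1]
        return self.sign * self.params[0]

    def quantile(self, p: np.ndarray) -> np.ndarray:
        """Signed image of probability p under the base quantile function."""
        p = np.asarray(p, dtype=float)
        if self.family == "gamma":
            base = stats.gamma.ppf(p, a=self.params[0], scale=self.params[1])
        else:
            base = stats.norm.ppf(p, loc=self.params[0], scale=self.params[1])
        return self.sign * base


@dataclass(frozen=True)
class ModalityBlock:
    """Sub-modalities of one modality: descriptors + selection proportions."""

    descriptors: tuple[SubmodalityDescriptor, ...]
    proportions: tuple[float, ...]

    def __post_init__(self):
        if len(self.descriptors) < 1:
            raise ValueError("a modality needs at least one sub-modality")
        if len(self.descriptors) != len(self.proportions):
            raise ValueError("descriptors and proportions length mismatch")
        pr = tuple(float(x) for x in self.proportions)
        if any(x < 0 for x in pr):
            raise ValueError("proportions must be nonnegative")
        if abs(sum(pr) - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {sum(pr)!r}")
        object.__setattr__(self, "proportions", pr)

    @property
    def count(self) -> int:
        return len(self.descriptors)

    @property
    def xi(self) -> np.ndarray:
        return np.array([d.xi for d in self.descriptors])


@dataclass(frozen=True)
class SubmodalityBank:
    """Quantile functions, proportions and mean LFCs per signature/modality.

    ``primary`` / ``secondary`` map modality code -> :class:`ModalityBlock`.
    """

    primary: Mapping[int, ModalityBlock]
    secondary: Mapping[int, ModalityBlock]

    def __post_init__(self):
        for side in (self.primary, self.secondary):
            if set(side) != set(MODALITIES):
                raise ValueError("bank must define modalities 1, 2 and 3")
            _validate_signs(side)

    def block(self, signature_index: int, modality: int) -> ModalityBlock:
        if signature_index == 1:
            return self.primary[modality]
        if signature_index == 2:
            return self.secondary[modality]
        raise ValueError("signature_index must be 1 or 2")

    def count(self, signature_index: int, modality: int) -> int:
        return self.block(signature_index, modality).count


def _validate_signs(side: Mapping[int, ModalityBlock]) -> None:
    for m, block in side.items():
        signs = {d.sign for d in block.descriptors}
        if m == UP and signs != {1}:
            raise ValueError("up-modality descriptors must have sign +1")
        if m == DOWN and signs != {-1}:
            raise ValueError("down-modality descriptors must have sign -1")
        if m == NULL:
            for d in block.descriptors:
                if d.family != "gaussian" or abs(d.params[0]) > 0.5:
                    raise ValueError(
                        "non-deregulated descriptors must be Gaussians "
                        "centered near 0"
                    )
        if m in (UP, DOWN) and block.count > 1:
            mags = np.abs(block.xi)
            if not np.all(np.diff(mags) > 0):
                raise ValueError(
                    f"sub-modality ranks for modality {m} must be ordered "
                    f"by strictly increasing |xi|, got {mags.tolist()}"
                )


@dataclass(frozen=True)
class LayerSet:
    """The three per-gene layers of one signature."""

    modality: np.ndarray
    submodality: np.ndarray
    probability: np.ndarray

    def __post_init__(self):
        mod = np.asarray(self.modality, dtype=np.int64)
        sub = np.asarray(self.submodality, dtype=np.int64)
        prob = np.asarray(self.probability, dtype=float)
        if not (mod.shape == sub.shape == prob.shape) or mod.ndim != 1:
            raise ValueError("the three layers must be 1-D and equal length")
        if mod.size < 1:
            raise ValueError("layers must describe at least one gene")
        if not np.isin(mod, MODALITIES).all():
            raise ValueError("modality values must be in {1, 2, 3}")
        if (sub < 1).any():
            raise ValueError("sub-modality ranks start at 1")
        if ((prob < 0) | (prob > 1)).any() or not np.isfinite(prob).all():
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "modality", mod)
        object.__setattr__(self, "submodality", sub)
        object.__setattr__(self, "probability", prob)

    @property
    def n_genes(self) -> int:
        return self.modality.size

    def validate_against(self, bank: SubmodalityBank, signature_index: int = 1):
        """Check every rank fits within the bank's count for its modality."""
        for m in MODALITIES:
            sel = self.modality == m
            if sel.any() and self.submodality[sel].max() > bank.count(signature_index, m):
                raise ValueError(
                    f"sub-modality rank exceeds bank count for modality {m}"
                )


@dataclass
class SignatureVector:
    """Composed per-gene LFC values, optionally with (adjusted) p-values."""

    gene_ids: np.ndarray
    lfc: np.ndarray
    pvalue: np.ndarray | None = None
    padj: np.ndarray | None = None

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids)
        self.lfc = np.asarray(self.lfc, dtype=float)
        if self.gene_ids.shape != self.lfc.shape or self.lfc.ndim != 1:
            raise ValueError("gene_ids and lfc must be 1-D and equal length")
        if not np.isfinite(self.lfc).all():
            raise ValueError("lfc values must be finite")
        for name in ("pvalue", "padj"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.lfc.shape or ((v < 0) | (v > 1)).any():
                    raise ValueError(f"{name} must match length and lie in [0, 1]")
                setattr(self, name, v)

    @property
    def n_genes(self) -> int:
        return self.lfc.size


def default_gene_ids(n: int) -> np.ndarray:
    width = max(6, len(str(n)))
    return np.array([f"g{i:0{width}d}" for i in range(1, n + 1)])


def _parse_entry(entry: Mapping, modality: int) -> tuple[SubmodalityDescriptor, float]:
    family = entry["family"]
    params = entry["params"]
    if isinstance(params, Mapping):
        if family == "gamma":
            params = (params["shape"], params["scale"])
        else:
            params = (params.get("mean", 0.0), params["sd"])
    descriptor = SubmodalityDescriptor(
        family=family, params=tuple(params), sign=_MODALITY_SIGNS[modality]
    )
    return descriptor, float(entry["proportion"])


def _build_side(side_cfg: Mapping) -> dict[int, ModalityBlock]:
    side: dict[int, ModalityBlock] = {}
    for key, modality in _MODALITY_KEYS.items():
        if key not in side_cfg:
            raise ValueError(f"bank configuration misses modality {key!r}")
        entries = [_parse_entry(e, modality) for e in side_cfg[key]]
        # order deregulated ranks by |xi|; reject ties (ranks must be strict)
        if modality in (UP, DOWN):
            entries.sort(key=lambda e: abs(e[0].xi))
        block = ModalityBlock(
            descriptors=tuple(e[0] for e in entries),
            proportions=tuple(e[1] for e in entries),
        )
        side[modality] = block
    return side


def build_submodality_bank(config: Mapping) -> SubmodalityBank:
    """Build and validate a :class:`SubmodalityBank` from a configuration.

    ``config`` holds ``modalities: {up: [...], null: [...], down: [...]}``
    where each entry is ``{family, params, proportion}``.  An optional
    ``secondary`` key (same structure) gives the secondary signature its own
    bank; otherwise primary and secondary share one.

    Mean LFCs ``xi`` are computed analytically (gamma: sign*shape*scale,
    gaussian: mean) and deregulated ranks are ordered by increasing |xi|.
    """
    if "modalities" not in config:
        raise ValueError("bank configuration requires a 'modalities' key")
    primary = _build_side(config["modalities"])
    if "secondary" in config and config["secondary"] is not None:
        sec_cfg = config["secondary"]
        secondary = _build_side(sec_cfg.get("modalities", sec_cfg))
    else:
        secondary = primary
    return SubmodalityBank(primary=primary, secondary=secondary)


#: Default deregulated amplitudes: mean |LFC| per rank and mixing weights.
_DEFAULT_XI = (0.8, 1.6, 3.0)
_DEFAULT_WEIGHTS = (1.0, 0.6, 0.36)
#: Gamma shape for every deregulated sub-modality (CV = 1/sqrt(20) ~ 22%).
_DEFAULT_SHAPE = 20.0


def default_realistic_bank() -> SubmodalityBank:
    """A documented default bank emulating a realistic LFC decomposition.

    Gaussian(0, 0.1) non-deregulated mode; three up and three down gamma
    sub-modalities with mean amplitudes |xi| = {0.8, 1.6, 3.0} and
    geometrically decaying proportions (ratio 0.6); identical for the
    primary and secondary signature.  Deterministic: no hidden randomness.
    """
    total = sum(_DEFAULT_WEIGHTS)
    proportions = [w / total for w in _DEFAULT_WEIGHTS]

    def entries():
        return [
            {
                "family": "gamma",
                "params": (_DEFAULT_SHAPE, xi / _DEFAULT_SHAPE),
                "proportion": prop,
            }
            for xi, prop in zip(_DEFAULT_XI, proportions)
        ]

    config = {
        "modalities": {
            "up": entries(),
            "null": [{"family": "gaussian", "params": (0.0, 0.1), "proportion": 1.0}],
            "down": entries(),
        }
    }
    return build_submodality_bank(config)


def sample_primary_layers(
    omega: ModalityDistribution,
    bank: SubmodalityBank,
    n_genes: int,
    seed,
) -> LayerSet:
    """Sample the three layers of an independent primary signature.

    Modality i.i.d. from ``omega``; sub-modality from the bank's primary
    proportions conditional on each gene's modality; probability i.i.d.
    uniform on [0, 1].  Same seed, same output.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng_mod, rng_sub, rng_prob = spawn_rngs(seed, 3)
    modality = rng_mod.choice(MODALITIES, size=n_genes, p=omega.as_array)
    submodality = sample_submodalities(modality, bank, 1, rng_sub)
    probability = rng_prob.uniform(size=n_genes)
    return LayerSet(modality=modality, submodality=submodality, probability=probability)


def sample_submodalities(
    modality: np.ndarray,
    bank: SubmodalityBank,
    signature_index: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw sub-modality ranks from the bank proportions, per modality."""
    submodality = np.ones(modality.size, dtype=np.int64)
    # fixed modality order keeps draws reproducible regardless of content
    for m in MODALITIES:
        sel = np.flatnonzero(modality == m)
        if sel.size == 0:
            continue
        block = bank.block(signature_index, m)
        ranks = rng.choice(
            np.arange(1, block.count + 1), size=sel.size, p=block.proportions
        )
        submodality[sel] = ranks
    return submodality


def compose_lfc(
    layers: LayerSet,
    bank: SubmodalityBank,
    signature_index: int = 1,
    gene_ids: np.ndarray | None = None,
) -> SignatureVector:
    """Compose the LFC vector from the three layers.

    ``lfc[i]`` is the signed image of ``probability[i]`` under the quantile
    function selected by (modality[i], submodality[i]).  Deterministic given
    layers and bank.
    """
    layers.validate_against(bank, signature_index)
    lfc = np.empty(layers.n_genes, dtype=float)
    for m in MODALITIES:
        block = bank.block(signature_index, m)
        for s in range(1, block.count + 1):
            sel = (layers.modality == m) & (layers.submodality == s)
            if sel.any():
                lfc[sel] = block.descriptors[s - 1].quantile(layers.probability[sel])
    if gene_ids is None:
        gene_ids = default_gene_ids(layers.n_genes)
    return SignatureVector(gene_ids=gene_ids, lfc=lfc)
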