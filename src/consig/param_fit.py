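"""Inference of simulation parameters from an observed LFC vector.

Real (or synthetic) LFC distributions are multimodal: a large Gaussian-like
mass of non-deregulated genes near zero plus gamma-like up/down tails.
This module detects the modes of such a distribution (diagnostic) and fits
a full simulation parameter set from it: modality proportions from a
deregulation threshold, a Gaussian for the central mass, and per-tail
gamma mixtures for the deregulation amplitudes.

Tail sub-modalities are fitted by seeded Gaussian-mixture EM on |LFC| and
converted to gamma distributions by method of moments; quantile-band
averaging was rejected because band means are biased estimators of
component means whenever the components overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln as special_gammaln, logsumexp
from sklearn.mixture import GaussianMixture

from .signature_model import (
    ModalityDistribution,
    SubmodalityBank,
    build_submodality_bank,
)

__all__ = ["ModeEstimate", "detect_lfc_modes", "fit_bank_from_lfc"]


@dataclass(frozen=True)
class ModeEstimate:
    """Locations (LFC, ascending) and KDE densities of detected modes."""

    locations: np.ndarray
    densities: np.ndarray

    def __post_init__(self):
        loc = np.asarray(self.locations, dtype=float)
        den = np.asarray(self.densities, dtype=float)
        if loc.shape != den.shape or loc.ndim != 1:
            raise ValueError("locations and densities must be 1-D, equal length")
        if not np.all(np.diff(loc) > 0):
            raise ValueError("mode locations must be sorted ascending")
        if (den <= 0).any():
            raise ValueError("mode densities must be positive")
        object.__setattr__(self, "locations", loc)
        object.__setattr__(self, "densities", den)

    @property
    def n_modes(self) -> int:
        return self.locations.size


def detect_lfc_modes(
    lfc,
    bandwidth=None,
    grid_size: int = 1024,
    rel_height: float = 0.05,
) -> ModeEstimate:
    """Strict local maxima of a Gaussian KDE of the LFC distribution.

    Modes below ``rel_height`` times the global density maximum are
    discarded (spurious ripples).  Needs at least 100 observations.
    """
    x = np.asarray(lfc, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("mode detection needs at least 100 LFC values")
    if not np.isfinite(x).all():
        raise ValueError("LFC values must be finite")
    kde = stats.gaussian_kde(x, bw_method=bandwidth)
    pad = 3.0 * np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    density = kde(grid)
    interior = np.flatnonzero(
        (density[1:-1] > density[:-2]) & (density[1:-1] > density[2:])
    ) + 1
    floor = rel_height * density.max()
    interior = interior[density[interior] >= floor]
    if interior.size == 0:
        raise ValueError("no mode above the relative-height floor")
    return ModeEstimate(locations=grid[interior], densities=density[interior])


def _fit_tail_mixture(
    magnitudes: np.ndarray, n_sub: int, seed: int
) -> list[tuple[float, float, float]]:
    """Gamma components (shape, scale, proportion) ordered by mean |LFC|.

    Gamma-mixture EM with a moment-based M-step, initialized by a seeded
    Gaussian mixture.  Deregulation amplitudes are right-skewed, so a
    gamma likelihood removes the bias a Gaussian mixture leaves on the
    component means.
    """
    x = magnitudes.astype(float)
    if n_sub == 1:
        m, v = x.mean(), max(x.var(), 1e-8)
        return [(m**2 / v, v / m, 1.0)]
    quantile_probs = (2 * np.arange(1, n_sub + 1) - 1) / (2 * n_sub)
    means_init = np.quantile(x, quantile_probs).reshape(-1, 1)
    gmm = GaussianMixture(
        n_components=n_sub,
        means_init=means_init,
        random_state=seed,
        n_init=1,
        max_iter=200,
        reg_covar=1e-6,
    ).fit(x.reshape(-1, 1))
    order = np.argsort(gmm.means_.ravel())
    means = gmm.means_.ravel()[order]
    variances = np.maximum(gmm.covariances_.ravel()[order], 1e-6)
    weights = gmm.weights_[order]
    shapes = means**2 / variances
    scales = variances / means

    log_x = np.log(x)
    prev_ll = -np.inf
    for _ in range(500):
        log_dens = (
            np.log(weights)[None, :]
            + (shapes - 1.0)[None, :] * log_x[:, None]
            - x[:, None] / scales[None, :]
            - (special_gammaln(shapes) + shapes * np.log(scales))[None, :]
        )
        norm = logsumexp(log_dens, axis=1)
        resp = np.exp(log_dens - norm[:, None])
        ll = float(norm.sum())
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, 1e-8)
        shapes = means**2 / variances
        scales = variances / means
        if abs(ll - prev_ll) < 1e-8 * max(1.0, abs(ll)):
            break
        prev_ll = ll

    comps = [
        (float(s), float(sc), float(w)) for s, sc, w in zip(shapes, scales, weights)
    ]
    comps.sort(key=lambda c: c[0] * c[1])
    # enforce strictly increasing means (EM can return near-duplicates)
    for i in range(1, len(comps)):
        prev_mean = comps[i - 1][0] * comps[i - 1][1]
        mean_i = comps[i][0] * comps[i][1]
        if mean_i <= prev_mean:
            bumped = prev_mean * 1.001
            comps[i] = (comps[i][0], bumped / comps[i][0], comps[i][2])
    return comps


def fit_bank_from_lfc(
    lfc,
    n_sub_up: int = 3,
    n_sub_down: int = 3,
    dereg_threshold: float = 0.5,
    seed: int = 0,
) -> tuple[ModalityDistribution, SubmodalityBank]:
    """Fit (omega, bank) from an LFC vector.

    Modality proportions come from the |LFC| > ``dereg_threshold`` split;
    the central mass gets a Gaussian; each tail gets ``n_sub`` gamma
    sub-modalities (mixture EM on |LFC|, proportions = mixture weights).
    Each tail must hold at least ``20 * n_sub`` genes.
    """
    x = np.asarray(lfc, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("bank fitting needs at least 100 LFC values")
    if not np.isfinite(x).all():
        raise ValueError("LFC values must be finite")
    up = x[x > dereg_threshold]
    down = -x[x < -dereg_threshold]
    mid = x[np.abs(x) <= dereg_threshold]
    if up.size < 20 * n_sub_up or down.size < 20 * n_sub_down:
        raise ValueError(
            "insufficient deregulated tail mass: need at least 20 genes per "
            f"sub-modality, got {up.size} up / {down.size} down"
        )
    omega = ModalityDistribution(
        omega=(up.size / x.size, mid.size / x.size, down.size / x.size)
    )
    center_mean = float(np.clip(mid.mean(), -0.45, 0.45))
    center_sd = float(max(mid.std(), 1e-6))
    up_comps = _fit_tail_mixture(up, n_sub_up, seed)
    down_comps = _fit_tail_mixture(down, n_sub_down, seed + 1)

    def entries(comps):
        total = sum(c[2] for c in comps)
        return [
            {
                "family": "gamma",
                "params": (shape, scale),
                "proportion": weight / total,
            }
            for shape, scale, weight in comps
        ]

    config = {
        "modalities": {
            "up": entries(up_comps),
            "null": [
                {
                    "family": "gaussian",
                    "params": (center_mean, center_sd),
                    "proportion": 1.0,
                }
            ],
            "down": entries(down_comps),
        }
    }
    return omega, build_submodality_bank(config)
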