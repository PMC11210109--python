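"""Bivariate copulas (Frank, Plackett, Gaussian) for layer transitions.

Provides the copula CDF, the conditional CDF/sampler ``V | U = u``, the
Spearman rho (= Pearson correlation of the two uniform margins) and its
inversion, plus the discrete copula construction of a joint pmf over two
rank margins whose parameter is optimized so that the exact Pearson
correlation of the ranks matches a target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "COPULA_FAMILIES",
    "copula_cdf",
    "conditional_cdf",
    "copula_conditional_sample",
    "rho_uniform",
    "fit_copula_theta",
    "DiscreteCopulaJoint",
    "fit_discrete_copula",
]

COPULA_FAMILIES = ("frank", "plackett", "gauss")

# parameter brackets used by the correlation-matching optimizers
_FRANK_MAX = 35.0          # |theta|; Spearman rho ~ +/-0.97 at the cap
_PLACKETT_LOG_MAX = 14.0   # log(theta); rho ~ +/-0.99 at the cap
_GAUSS_MAX = 0.9999


def _check_theta(family: str, theta: float) -> float:
    theta = float(theta)
    if family == "frank":
        if not np.isfinite(theta) or abs(theta) > _FRANK_MAX:
            raise ValueError(f"frank theta must lie in [-{_FRANK_MAX}, {_FRANK_MAX}]")
    elif family == "plackett":
        if theta <= 0 or not np.isfinite(theta):
            raise ValueError("plackett theta must be positive and finite")
    elif family == "gauss":
        if not -1 < theta < 1:
            raise ValueError("gauss theta (correlation) must lie in (-1, 1)")
    else:
        raise ValueError(f"unknown copula family {family!r}")
    return theta


def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate standard-normal CDF via Owen's T (vectorized, ~1e-14)."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    # nudge exact zeros; the formula divides by h and k
    eps = 1e-12
    h = np.where(np.abs(h) < eps, eps, h)
    k = np.where(np.abs(k) < eps, eps, k)
    denom = np.sqrt(1.0 - rho * rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = (k - rho * h) / (h * denom)
        ak = (h - rho * k) / (k * denom)
    ah = np.nan_to_num(ah, nan=0.0, posinf=np.inf, neginf=-np.inf)
    ak = np.nan_to_num(ak, nan=0.0, posinf=np.inf, neginf=-np.inf)
    beta = np.where((h * k > 0) | ((h * k == 0) & (h + k >= 0)), 0.0, 0.5)
    cdf = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, ah)
        - special.owens_t(k, ak)
        - beta
    )
    return np.clip(cdf, 0.0, 1.0)


def copula_cdf(family: str, theta: float, u, v) -> np.ndarray:
    """C(u, v; theta), vectorized, with exact uniform-boundary handling."""
    theta = _check_theta(family, theta)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    u, v = np.broadcast_arrays(u, v)
    out = np.empty(u.shape, dtype=float)

    interior = (u > 0) & (u < 1) & (v > 0) & (v < 1)
    ui, vi = u[interior], v[interior]
    if family == "frank":
        if abs(theta) < 1e-10:
            ci = ui * vi
        else:
            num = np.expm1(-theta * ui) * np.expm1(-theta * vi) / np.expm1(-theta)
            ci = -np.log1p(num) / theta
    elif family == "plackett":
        if abs(theta - 1.0) < 1e-10:
            ci = ui * vi
        else:
            s = 1.0 + (theta - 1.0) * (ui + vi)
            d = np.sqrt(s * s - 4.0 * theta * (theta - 1.0) * ui * vi)
            ci = (s - d) / (2.0 * (theta - 1.0))
    else:  # gauss
        if abs(theta) < 1e-12:
            ci = ui * vi
        else:
            ci = _bvn_cdf(stats.norm.ppf(ui), stats.norm.ppf(vi), theta)
    out[interior] = ci
    out[(u <= 0) | (v <= 0)] = 0.0
    edge_u = (u >= 1) & (v > 0) & (v < 1)
    edge_v = (v >= 1) & (u > 0) & (u < 1)
    out[edge_u] = v[edge_u]
    out[edge_v] = u[edge_v]
    out[(u >= 1) & (v >= 1)] = 1.0
    return np.clip(out, 0.0, 1.0)


def conditional_cdf(family: str, theta: float, u, v) -> np.ndarray:
    """P(V <= v | U = u) = dC(u, v)/du, vectorized."""
    theta = _check_theta(family, theta)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    u, v = np.broadcast_arrays(u, v)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    v = np.clip(v, 0.0, 1.0)
    if family == "frank":
        if abs(theta) < 1e-10:
            return v.copy()
        eu = np.expm1(-theta * u)
        ev = np.expm1(-theta * v)
        return (eu + 1.0) * ev / (np.expm1(-theta) + eu * ev)
    if family == "plackett":
        if abs(theta - 1.0) < 1e-10:
            return v.copy()
        s = 1.0 + (theta - 1.0) * (u + v)
        d = np.sqrt(s * s - 4.0 * theta * (theta - 1.0) * u * v)
        return 0.5 * (1.0 - (s - 2.0 * theta * v) / d)
    # gauss
    if abs(theta) < 1e-12:
        return v.copy()
    x = stats.norm.ppf(u)
    y = stats.norm.ppf(v)
    return stats.norm.cdf((y - theta * x) / np.sqrt(1.0 - theta * theta))


def copula_conditional_sample(u, family: str, theta: float, seed) -> np.ndarray:
    """Sample V from the conditional law ``V | U = u``.

    Marginally V is uniform when u is uniform.  Frank and Gauss use closed
    forms; Plackett inverts the conditional CDF by vectorized bisection.
    """
    from .signature_model import as_rng

    theta = _check_theta(family, theta)
    u = np.atleast_1d(np.asarray(u, dtype=float))
    rng = as_rng(seed)
    t = rng.uniform(size=u.shape)
    uc = np.clip(u, 1e-12, 1 - 1e-12)
    if family == "gauss":
        x = stats.norm.ppf(uc)
        z = stats.norm.ppf(np.clip(t, 1e-15, 1 - 1e-15))
        return stats.norm.cdf(theta * x + np.sqrt(1.0 - theta * theta) * z)
    if family == "frank":
        if abs(theta) < 1e-10:
            return t
        eu = np.expm1(-theta * uc)
        ev = t * np.expm1(-theta) / (1.0 + eu * (1.0 - t))
        v = -np.log1p(ev) / theta
        return np.clip(v, 0.0, 1.0)
    # plackett: bisection on the monotone conditional CDF
    lo = np.zeros_like(uc)
    hi = np.ones_like(uc)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        below = conditional_cdf(family, theta, uc, mid) < t
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(96)
_GL_X = 0.5 * (_GL_NODES + 1.0)
_GL_W = 0.5 * _GL_WEIGHTS


def rho_uniform(family: str, theta: float) -> float:
    """Pearson correlation of (U, V) under the copula (= Spearman's rho).

    Gauss uses the closed form (6/pi) asin(theta/2); Frank and Plackett use
    Hoeffding's identity rho = 12 * integral(C) - 3 with Gauss-Legendre
    quadrature.
    """
    theta = _check_theta(family, theta)
    if family == "gauss":
        return float(6.0 / np.pi * np.arcsin(theta / 2.0))
    uu, vv = np.meshgrid(_GL_X, _GL_X)
    c = copula_cdf(family, theta, uu, vv)
    integral = float(np.einsum("i,j,ij->", _GL_W, _GL_W, c))
    return 12.0 * integral - 3.0


def fit_copula_theta(family: str, target_correlation: float, tol: float = 1e-6) -> float:
    """Parameter theta whose uniform-margin Pearson correlation hits target."""
    target = float(target_correlation)
    if not -1 < target < 1:
        raise ValueError("target correlation must lie in (-1, 1)")
    if family == "gauss":
        return float(2.0 * np.sin(np.pi * target / 6.0))
    if abs(target) < 1e-12:
        return 0.0 if family == "frank" else 1.0
    if family == "frank":
        lo, hi = -_FRANK_MAX, _FRANK_MAX
        to_theta = lambda x: x
    elif family == "plackett":
        lo, hi = -_PLACKETT_LOG_MAX, _PLACKETT_LOG_MAX
        to_theta = np.exp
    else:
        raise ValueError(f"unknown copula family {family!r}")
    rho_lo = rho_uniform(family, to_theta(lo))
    rho_hi = rho_uniform(family, to_theta(hi))
    if target <= rho_lo:
        warnings.warn(
            f"target correlation {target} below attainable range for {family}; "
            "clamped to the bound",
            stacklevel=2,
        )
        return float(to_theta(lo))
    if target >= rho_hi:
        warnings.warn(
            f"target correlation {target} above attainable range for {family}; "
            "clamped to the bound",
            stacklevel=2,
        )
        return float(to_theta(hi))
    x = optimize.brentq(
        lambda x: rho_uniform(family, to_theta(x)) - target, lo, hi, xtol=tol
    )
    return float(to_theta(x))


@dataclass(frozen=True)
class DiscreteCopulaJoint:
    """Joint pmf over two rank margins built from a fitted copula.

    ``joint[a-1, b-1] = P(rank1 = a, rank2 = b)``; rectangle differences of
    the copula CDF at the cumulative margins reproduce both margins exactly.
    """

    joint: np.ndarray
    fitted_theta: float
    achieved_correlation: float
    family: str

    def __post_init__(self):
        j = np.asarray(self.joint, dtype=float)
        if j.ndim != 2 or (j < -1e-12).any():
            raise ValueError("joint must be a nonnegative matrix")
        if abs(j.sum() - 1.0) > 1e-9:
            raise ValueError("joint probabilities must sum to 1")
        object.__setattr__(self, "joint", np.clip(j, 0.0, None))

    @property
    def margin1(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def margin2(self) -> np.ndarray:
        return self.joint.sum(axis=0)

    def conditional_row(self, rank1: int) -> np.ndarray:
        """pmf of rank2 given rank1 (1-based)."""
        row = self.joint[rank1 - 1]
        total = row.sum()
        if total <= 0:
            raise ValueError(f"rank {rank1} has zero marginal probability")
        return row / total


def _rank_correlation(joint: np.ndarray) -> float:
    """Exact Pearson correlation of the two rank variables under ``joint``."""
    n1, n2 = joint.shape
    r1 = np.arange(1, n1 + 1, dtype=float)
    r2 = np.arange(1, n2 + 1, dtype=float)
    p1 = joint.sum(axis=1)
    p2 = joint.sum(axis=0)
    m1 = float(r1 @ p1)
    m2 = float(r2 @ p2)
    v1 = float((r1 - m1) ** 2 @ p1)
    v2 = float((r2 - m2) ** 2 @ p2)
    if v1 <= 1e-15 or v2 <= 1e-15:
        return 0.0
    cov = float((r1 - m1) @ joint @ (r2 - m2))
    return cov / np.sqrt(v1 * v2)


def _joint_from_theta(
    family: str, theta: float, cum1: np.ndarray, cum2: np.ndarray
) -> np.ndarray:
    grid = copula_cdf(family, theta, cum1[:, None], cum2[None, :])
    joint = np.diff(np.diff(grid, axis=0), axis=1)
    return np.clip(joint, 0.0, None)


def fit_discrete_copula(
    margin1,
    margin2,
    family: str,
    target_correlation: float,
    tol: float = 1e-4,
) -> DiscreteCopulaJoint:
    """Couple two rank pmfs with a copula matched to a Pearson correlation.

    The joint pmf is built from rectangle differences of the copula CDF
    evaluated at the cumulative margins; theta is optimized so that the
    exact Pearson correlation of the coupled ranks is as close as possible
    to ``target_correlation``.  Targets beyond the attainable (Frechet)
    range for these margins are clamped to the bound with a warning.
    """
    p1 = np.asarray(margin1, dtype=float)
    p2 = np.asarray(margin2, dtype=float)
    for p in (p1, p2):
        if p.ndim != 1 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("margins must be valid pmfs over ranks 1..N")
    target = float(target_correlation)
    if not -1 <= target <= 1:
        raise ValueError("target correlation must lie in [-1, 1]")
    if family not in COPULA_FAMILIES:
        raise ValueError(f"unknown copula family {family!r}")

    independence = {"frank": 0.0, "plackett": 1.0, "gauss": 0.0}[family]
    outer = np.outer(p1, p2)
    degenerate = len(p1) == 1 or len(p2) == 1
    # zero-variance margins cannot carry correlation: independence coupling
    r1 = np.arange(1, len(p1) + 1, dtype=float)
    r2 = np.arange(1, len(p2) + 1, dtype=float)
    v1 = float((r1 - r1 @ p1) ** 2 @ p1)
    v2 = float((r2 - r2 @ p2) ** 2 @ p2)
    if degenerate or v1 <= 1e-15 or v2 <= 1e-15 or abs(target) < 1e-12:
        return DiscreteCopulaJoint(
            joint=outer,
            fitted_theta=independence,
            achieved_correlation=0.0 if (v1 <= 1e-15 or v2 <= 1e-15) else _rank_correlation(outer),
            family=family,
        )

    cum1 = np.concatenate([[0.0], np.cumsum(p1)])
    cum2 = np.concatenate([[0.0], np.cumsum(p2)])
    cum1[-1] = 1.0
    cum2[-1] = 1.0

    if family == "frank":
        lo, hi = -_FRANK_MAX, _FRANK_MAX
        to_theta = lambda x: x
    elif family == "plackett":
        lo, hi = -_PLACKETT_LOG_MAX, _PLACKETT_LOG_MAX
        to_theta = np.exp
    else:
        lo, hi = -_GAUSS_MAX, _GAUSS_MAX
        to_theta = lambda x: x

    def achieved(x: float) -> float:
        return _rank_correlation(_joint_from_theta(family, to_theta(x), cum1, cum2))

    rho_lo, rho_hi = achieved(lo), achieved(hi)
    if target <= rho_lo or target >= rho_hi:
        x = lo if target <= rho_lo else hi
        warnings.warn(
            f"target correlation {target} outside the attainable range "
            f"[{rho_lo:.4f}, {rho_hi:.4f}] for these margins ({family}); "
            "clamped to the bound",
            stacklevel=2,
        )
    else:
        x = optimize.brentq(lambda x: achieved(x) - target, lo, hi, xtol=tol)
    theta = float(to_theta(x))
    joint = _joint_from_theta(family, theta, cum1, cum2)
    joint = joint / joint.sum()
    return DiscreteCopulaJoint(
        joint=joint,
        fitted_theta=theta,
        achieved_correlation=_rank_correlation(joint),
        family=family,
    )
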