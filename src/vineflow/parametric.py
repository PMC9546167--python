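"""Closed-form bivariate copulas (Clayton, Frank, Gaussian, independence).

These families provide the ground truth for the simulation benchmark and the
analytic oracles (CDF, density, conditional h-function and its inverse,
Kendall's tau) against which the non-parametric spline-flow estimators are
validated.  All functions are vectorized over ``u``/``v``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, stats
from scipy.special import expm1, log1p, ndtr, ndtri

__all__ = [
    "ParametricCopulaSpec",
    "copula_cdf",
    "copula_pdf",
    "copula_hfunc",
    "copula_hinv",
    "copula_sample",
    "copula_kendall_tau",
]

FAMILIES = ("clayton", "frank", "gaussian", "independence")


class InvalidSpecError(ValueError):
    """Copula parameter outside the family's domain."""


@dataclass(frozen=True)
class ParametricCopulaSpec:
    """A bivariate copula family together with its dependence parameter.

    Clayton and Frank use ``theta``; Gaussian uses the off-diagonal
    correlation ``rho``; the independence copula takes no parameter.
    """

    family: str
    theta: Optional[float] = None
    rho: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidSpecError(f"unknown copula family {self.family!r}")
        if self.family == "clayton":
            if self.theta is None or self.theta <= 0 or self.rho is not None:
                raise InvalidSpecError("clayton requires theta > 0 (and no rho)")
        elif self.family == "frank":
            if self.theta is None or self.theta == 0 or self.rho is not None:
                raise InvalidSpecError("frank requires theta != 0 (and no rho)")
        elif self.family == "gaussian":
            if self.rho is None or not -1 < self.rho < 1 or self.theta is not None:
                raise InvalidSpecError("gaussian requires -1 < rho < 1 (and no theta)")
        elif self.family == "independence":
            if self.theta is not None or self.rho is not None:
                raise InvalidSpecError("independence takes no parameter")

    def to_json(self) -> str:
        d = {"family": self.family}
        if self.theta is not None:
            d["theta"] = self.theta
        if self.rho is not None:
            d["rho"] = self.rho
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ParametricCopulaSpec":
        d = json.loads(s)
        return cls(d["family"], d.get("theta"), d.get("rho"))


def _as_arrays(u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return np.broadcast_arrays(u, v)


def copula_cdf(spec: ParametricCopulaSpec, u, v):
    """Copula CDF C(u, v) on the unit square."""
    u, v = _as_arrays(u, v)
    if np.any((u < 0) | (u > 1) | (v < 0) | (v > 1)):
        raise ValueError("u, v must lie in [0, 1]")
    if spec.family == "independence":
        return u * v
    if spec.family == "clayton":
        th = spec.theta
        # boundary-safe: C -> 0 as u or v -> 0
        with np.errstate(divide="ignore", over="ignore"):
            s = np.power(u, -th) + np.power(v, -th) - 1.0
            out = np.power(s, -1.0 / th)
        out = np.where((u <= 0) | (v <= 0), 0.0, out)
        return np.minimum(out, np.minimum(u, v))
    if spec.family == "frank":
        th = spec.theta
        gu, gv, g1 = expm1(-th * u), expm1(-th * v), expm1(-th)
        return -log1p(gu * gv / g1) / th
    # gaussian
    rho = spec.rho
    a, b = ndtri(np.clip(u, 1e-300, 1.0)), ndtri(np.clip(v, 1e-300, 1.0))
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    pts = np.stack([a, b], axis=-1)
    out = mvn.cdf(pts)
    out = np.asarray(out, dtype=float)
    zero = (u <= 0) | (v <= 0)
    out = np.where(zero, 0.0, out)
    out = np.where((u >= 1), v, out)
    out = np.where((v >= 1), np.where(u >= 1, 1.0, u), out)
    return out


def copula_pdf(spec: ParametricCopulaSpec, u, v):
    """Copula density c(u, v) on the open unit square."""
    u, v = _as_arrays(u, v)
    if np.any((u <= 0) | (u >= 1) | (v <= 0) | (v >= 1)):
        raise ValueError("u, v must lie strictly inside (0, 1)")
    if spec.family == "independence":
        return np.ones_like(u)
    if spec.family == "clayton":
        th = spec.theta
        s = np.power(u, -th) + np.power(v, -th) - 1.0
        return (1 + th) * np.power(u * v, -th - 1) * np.power(s, -2.0 - 1.0 / th)
    if spec.family == "frank":
        th = spec.theta
        g1 = expm1(-th)
        num = -th * g1 * np.exp(-th * (u + v))
        den = (g1 + expm1(-th * u) * expm1(-th * v)) ** 2
        return num / den
    rho = spec.rho
    a, b = ndtri(u), ndtri(v)
    r2 = 1.0 - rho * rho
    expo = -(rho * rho * (a * a + b * b) - 2 * rho * a * b) / (2 * r2)
    return np.exp(expo) / np.sqrt(r2)


def copula_hfunc(spec: ParametricCopulaSpec, u, v):
    """Conditional CDF h(u | v) = dC(u, v)/dv."""
    u, v = _as_arrays(u, v)
    if np.any((v <= 0) | (v >= 1)):
        raise ValueError("conditioning value v must lie strictly inside (0, 1)")
    u = np.clip(u, 0.0, 1.0)
    if spec.family == "independence":
        return u.copy()
    if spec.family == "clayton":
        th = spec.theta
        with np.errstate(divide="ignore", over="ignore"):
            s = np.power(u, -th) + np.power(v, -th) - 1.0
            out = np.power(v, -th - 1) * np.power(s, -1.0 / th - 1.0)
        return np.where(u <= 0, 0.0, np.where(u >= 1, 1.0, out))
    if spec.family == "frank":
        th = spec.theta
        gu, gv, g1 = expm1(-th * u), expm1(-th * v), expm1(-th)
        return np.exp(-th * v) * gu / (g1 + gu * gv)
    rho = spec.rho
    a = ndtri(np.clip(u, 1e-300, 1 - 1e-16))
    b = ndtri(v)
    out = ndtr((a - rho * b) / np.sqrt(1 - rho * rho))
    return np.where(u <= 0, 0.0, np.where(u >= 1, 1.0, out))


def copula_hinv(spec: ParametricCopulaSpec, p, v):
    """Inverse of the h-function in its first argument: u with h(u|v) = p."""
    p, v = _as_arrays(p, v)
    if np.any((p < 0) | (p > 1)) or np.any((v <= 0) | (v >= 1)):
        raise ValueError("require 0 <= p <= 1 and 0 < v < 1")
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    if spec.family == "independence":
        return p.copy()
    if spec.family == "clayton":
        th = spec.theta
        t = np.power(p * np.power(v, th + 1), -th / (th + 1.0))
        return np.power(t - np.power(v, -th) + 1.0, -1.0 / th)
    if spec.family == "frank":
        th = spec.theta
        gv, g1 = expm1(-th * v), expm1(-th)
        gu = p * g1 / (np.exp(-th * v) - p * gv)
        return -log1p(gu) / th
    rho = spec.rho
    b = ndtri(v)
    return ndtr(np.sqrt(1 - rho * rho) * ndtri(p) + rho * b)


def copula_sample(spec: ParametricCopulaSpec, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` points from the copula by conditional inversion.

    Uses v ~ U(0,1), p ~ U(0,1), u = h^{-1}(p | v), which is exact for all
    supported families.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    eps = 1e-12
    v = rng.uniform(eps, 1 - eps, size=n)
    p = rng.uniform(eps, 1 - eps, size=n)
    u = copula_hinv(spec, p, v)
    return np.column_stack([np.clip(u, eps, 1 - eps), v])


def _debye1(theta: float) -> float:
    val, _ = integrate.quad(lambda t: t / np.expm1(t), 0.0, theta)
    return val / theta


def copula_kendall_tau(spec: ParametricCopulaSpec) -> float:
    """Population Kendall's tau of the copula (closed form; Frank via Debye)."""
    if spec.family == "independence":
        return 0.0
    if spec.family == "clayton":
        return spec.theta / (spec.theta + 2.0)
    if spec.family == "frank":
        th = spec.theta
        return 1.0 - 4.0 / th * (1.0 - _debye1(th))
    return 2.0 / np.pi * np.arcsin(spec.rho)
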