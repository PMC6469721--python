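"""Degree distributions and their probability generating functions.

Everything downstream — deterministic dynamics, final-size roots, asymptotic
variances and branching approximations — is expressed through the degree PGF

    f_D(s) = sum_k p_k s^k

and its first three derivatives.  Two named families are supported with
analytic closed forms valid on their full (unbounded) support,

    Poisson(lam):    f^(i)(s) = lam^i exp(-lam (1 - s)),
    Geometric(p):    f^(i)(s) = i! p (1-p)^i / (1 - (1-p) s)^(i+1)
                     (pmf p_k = p (1-p)^k on k = 0, 1, ...),

alongside arbitrary finite-support pmfs for which derivatives are computed by
direct summation.  Truncation of a named family to a finite maximum degree
renormalizes the pmf so that it remains a proper distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegreeDistribution",
    "FinitePMF",
    "PoissonDegree",
    "GeometricDegree",
    "DeficitPGFSpec",
    "pgf_derivative",
    "size_biased_minus_one",
    "truncate",
]


def _check_s(s: float) -> None:
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"PGF argument s={s!r} outside [0, 1]")


class DegreeDistribution:
    """Base class; concrete distributions implement ``pgf_derivative``."""

    family_tag: str = "custom"

    @property
    def mean(self) -> float:
        raise NotImplementedError

    @property
    def var(self) -> float:
        raise NotImplementedError

    def pgf_derivative(self, s: float, order: int = 0) -> float:
        raise NotImplementedError

    # mean of the size-biased distribution minus one: E[D~ - 1]
    @property
    def mean_excess_degree(self) -> float:
        mu = self.mean
        if mu <= 0:
            raise ValueError("degenerate distribution with mean 0")
        return mu + self.var / mu - 1.0

    @property
    def kappa(self) -> float:
        """E[D(D-2)] = sigma_D^2 + mu_D^2 - 2 mu_D; giant component exists iff > 0."""
        return self.var + self.mean**2 - 2.0 * self.mean


@dataclass
class FinitePMF(DegreeDistribution):
    """Finite-support degree distribution given by an explicit pmf.

    ``pmf[k]`` is P(D = k) for k = 0 .. support_max.  The pmf must be a
    probability vector to within 1e-12.
    """

    pmf: np.ndarray
    family_tag: str = "custom"
    family_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        if self.pmf.ndim != 1 or self.pmf.size == 0:
            raise ValueError("pmf must be a non-empty 1-d array")
        if np.any(self.pmf < -1e-15):
            raise ValueError("pmf entries must be non-negative")
        if abs(self.pmf.sum() - 1.0) > 1e-12:
            raise ValueError(f"pmf sums to {self.pmf.sum()}, not 1")
        self._k = np.arange(self.pmf.size, dtype=float)

    @property
    def support_max(self) -> int:
        return self.pmf.size - 1

    @property
    def mean(self) -> float:
        return float(self._k @ self.pmf)

    @property
    def var(self) -> float:
        mu = self.mean
        return float((self._k - mu) ** 2 @ self.pmf)

    def pgf_derivative(self, s: float, order: int = 0) -> float:
        _check_s(s)
        if order < 0:
            raise ValueError("order must be >= 0")
        k = self._k
        if order == 0:
            return float(self.pmf @ s**k)
        # falling factorial k!/(k-order)!; zero for k < order
        ff = np.ones_like(k)
        for r in range(order):
            ff = ff * np.clip(k - r, 0.0, None)
        with np.errstate(invalid="ignore"):
            powers = np.where(k >= order, s ** np.clip(k - order, 0, None), 0.0)
        if s == 0.0:
            powers = np.where(k == order, 1.0, np.where(k > order, 0.0, powers))
        return float((self.pmf * ff) @ powers)


@dataclass
class PoissonDegree(DegreeDistribution):
    """Poisson(lam) degrees with analytic PGF derivatives of every order."""

    lam: float
    family_tag: str = "poisson"

    @property
    def mean(self) -> float:
        return self.lam

    @property
    def var(self) -> float:
        return self.lam

    def pmf_vector(self, m: int) -> np.ndarray:
        k = np.arange(m + 1)
        logp = -self.lam + k * math.log(self.lam) - np.array(
            [math.lgamma(j + 1) for j in k]
        )
        return np.exp(logp)

    def tail_mass(self, m: int) -> float:
        return float(1.0 - self.pmf_vector(m).sum())

    def pgf_derivative(self, s: float, order: int = 0) -> float:
        _check_s(s)
        return self.lam**order * math.exp(-self.lam * (1.0 - s))


@dataclass
class GeometricDegree(DegreeDistribution):
    """Geometric(p) degrees, pmf p_k = p (1-p)^k for k >= 0."""

    p: float
    family_tag: str = "geometric"

    @property
    def mean(self) -> float:
        return (1.0 - self.p) / self.p

    @property
    def var(self) -> float:
        return (1.0 - self.p) / self.p**2

    def pmf_vector(self, m: int) -> np.ndarray:
        k = np.arange(m + 1)
        return self.p * (1.0 - self.p) ** k

    def tail_mass(self, m: int) -> float:
        return float((1.0 - self.p) ** (m + 1))

    def pgf_derivative(self, s: float, order: int = 0) -> float:
        _check_s(s)
        q = 1.0 - self.p
        return (
            math.factorial(order) * self.p * q**order / (1.0 - q * s) ** (order + 1)
        )


@dataclass
class DeficitPGFSpec:
    """PGF of the deficit distribution D_eps.

    f_{D_eps}(s) = sum_k (p_k - eps_k) s^k, where eps_k is the limiting
    fraction of the population that is initially an infective of degree k.
    An all-zero eps vector encodes the eps_E -> 0 limit, in which the deficit
    PGF coincides with f_D.
    """

    base: DegreeDistribution
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if np.any(self.epsilon < -1e-15):
            raise ValueError("epsilon entries must be non-negative")
        if isinstance(self.base, FinitePMF):
            if self.epsilon.size > self.base.pmf.size:
                raise ValueError("epsilon vector longer than pmf support")
            if np.any(self.epsilon > self.base.pmf[: self.epsilon.size] + 1e-12):
                raise ValueError("epsilon_k may not exceed p_k")
        self._k = np.arange(self.epsilon.size, dtype=float)

    @classmethod
    def proportional(cls, base: DegreeDistribution, eps: float, support_max: int | None = None) -> "DeficitPGFSpec":
        """eps_k = eps * p_k: initial infectives in population proportions."""
        if isinstance(base, FinitePMF):
            pvec = base.pmf
        else:
            if support_max is None:
                raise ValueError("support_max required for analytic families")
            pvec = base.pmf_vector(support_max)
        return cls(base, eps * pvec)

    @property
    def eps_total(self) -> float:
        """eps = sum_k eps_k: the initially infective fraction."""
        return float(self.epsilon.sum())

    @property
    def eps_edges(self) -> float:
        """eps_E = sum_k k eps_k: the initially infective stub fraction."""
        return float(self._k @ self.epsilon)

    @property
    def mean(self) -> float:
        # mu_D of the *base* distribution, which is what the theory uses
        return self.base.mean

    def pgf_derivative(self, s: float, order: int = 0) -> float:
        _check_s(s)
        base_val = self.base.pgf_derivative(s, order)
        if self.epsilon.size == 0 or not self.epsilon.any():
            return base_val
        k = self._k
        ff = np.ones_like(k)
        for r in range(order):
            ff = ff * np.clip(k - r, 0.0, None)
        powers = np.where(k >= order, s ** np.clip(k - order, 0, None), 0.0)
        if s == 0.0:
            powers = np.where(k == order, 1.0, np.where(k > order, 0.0, powers))
        return base_val - float((self.epsilon * ff) @ powers)


def pgf_derivative(dist, s: float, order: int = 0) -> float:
    """Evaluate f^(order)(s) for a degree distribution or deficit spec."""
    return dist.pgf_derivative(s, order)


def size_biased_minus_one(dist: DegreeDistribution) -> DegreeDistribution:
    """Distribution of D~ - 1, where D~ is size biased: P(D~=k) = k p_k / mu.

    D~ - 1 is the number of stubs, other than the one along which it was
    reached, of a randomly-reached neighbour.  For Poisson(lam) degrees
    D~ - 1 is again Poisson(lam).
    """
    if isinstance(dist, PoissonDegree):
        return PoissonDegree(dist.lam)
    if not isinstance(dist, FinitePMF):
        raise TypeError("size_biased_minus_one needs a FinitePMF or PoissonDegree")
    mu = dist.mean
    if mu <= 0:
        raise ValueError("size biasing undefined for a distribution with mean 0")
    k = np.arange(1, dist.pmf.size)
    pmf = k * dist.pmf[1:] / mu
    return FinitePMF(pmf / pmf.sum(), family_tag="custom")


_FAMILIES = {"poisson": PoissonDegree, "geometric": GeometricDegree}


def truncate(family, M: int, tail_tol: float = 1e-8) -> FinitePMF:
    """Truncate a named family at maximum degree M and renormalize.

    ``family`` is a PoissonDegree/GeometricDegree instance.  A warning (not an
    error) is raised when the discarded tail mass exceeds ``tail_tol``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    pvec = family.pmf_vector(M)
    tail = family.tail_mass(M)
    if tail > tail_tol:
        warnings.warn(
            f"truncating {family.family_tag} at M={M} discards tail mass "
            f"{tail:.3g} > tail_tol={tail_tol:.3g}",
            stacklevel=2,
        )
    if isinstance(family, PoissonDegree):
        params = {"lambda": family.lam}
    elif isinstance(family, GeometricDegree):
        params = {"p": family.p}
    else:
        params = {}
    return FinitePMF(pvec / pvec.sum(), family_tag=family.family_tag, family_params=params)
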