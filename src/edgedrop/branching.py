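"""Branching-process approximation of the early epidemic.

During the early stages of an outbreak in a large population the epidemic is
well approximated by a Galton-Watson process.  An infective with k
susceptible neighbours infects

    Y_k^(gamma,omega) ~ MixBin(k, (beta/(beta+omega)) (1 - e^{-(beta+omega) I})),
        I ~ Exp(gamma)                         (dropping model)

    Y_k^(gamma+omega,0) ~ MixBin(k, 1 - e^{-beta I*}),  I* ~ Exp(gamma+omega)
                                               (modified model: no dropping,
                                                recovery rate gamma+omega)

of them.  Both offspring laws have mean k beta/(beta+gamma+omega), so the two
models share

    R_0 = beta/(beta+gamma+omega) * (mu_D + sigma_D^2/mu_D - 1)

and the Malthusian parameter r = beta (mu_D - 2 + sigma_D^2/mu_D) - gamma -
omega, but the dropping model has the smaller offspring variance and hence
the *larger* probability of a major outbreak.

The number of susceptible neighbours is D for the initial infective
(uniformly chosen) and D~ - 1 (size-biased minus the infector) afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.optimize import brentq

from .degree_models import DegreeDistribution, FinitePMF, size_biased_minus_one
from .params import EpidemicParams

__all__ = [
    "R0",
    "malthusian_r",
    "OffspringLaw",
    "offspring_pgf",
    "offspring_pmf",
    "offspring_moments",
    "BranchingResult",
    "p_major",
]


def R0(params: EpidemicParams, dist: DegreeDistribution) -> float:
    """Basic reproduction number; identical for dropping and modified models."""
    mu = dist.mean
    if mu <= 0:
        raise ValueError("R0 undefined for mean degree 0")
    b, g, w = params.beta, params.gamma, params.omega
    return b / (b + g + w) * (mu + dist.var / mu - 1.0)


def malthusian_r(params: EpidemicParams, dist: DegreeDistribution) -> float:
    """Early exponential growth rate (real root of the Euler-Lotka equation)."""
    mu = dist.mean
    if mu <= 0:
        raise ValueError("Malthusian parameter undefined for mean degree 0")
    b, g, w = params.beta, params.gamma, params.omega
    return b * (mu - 2.0 + dist.var / mu) - g - w


@dataclass(frozen=True)
class OffspringLaw:
    """Number of neighbours infected by an infective with k susceptible ones."""

    k: int
    model: str  # "dropping" | "modified"
    params: EpidemicParams

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.model not in ("dropping", "modified"):
            raise ValueError("model must be 'dropping' or 'modified'")

    def _mixture(self):
        """(a, c, g): per-edge success a(1 - e^{-c I}) with I ~ Exp(g).

        Dropping: a = beta/(beta+omega), c = beta+omega, g = gamma.
        Modified: a = 1, c = beta, g = gamma+omega.
        """
        p = self.params
        if self.model == "dropping":
            if p.beta + p.omega == 0:
                return 0.0, 1.0, p.gamma
            return p.beta / (p.beta + p.omega), p.beta + p.omega, p.gamma
        return 1.0, p.beta, p.gamma + p.omega

    def pgf(self, s: float) -> float:
        """E[s^Y] via the exact finite-sum reduction of the Exp mixture.

        Conditioning on I, the PGF is (1 - b(1 - e^{-cI}))^k with
        b = a(1-s); expanding binomially in u = e^{-cI} and using
        E[u^m] = g/(g + c m) gives a k+1 term sum.
        """
        if not (0.0 <= s <= 1.0):
            raise ValueError("s must lie in [0, 1]")
        if self.k == 0:
            return 1.0
        a, c, g = self._mixture()
        b = a * (1.0 - s)
        total = 0.0
        for m in range(self.k + 1):
            total += comb(self.k, m) * (1.0 - b) ** (self.k - m) * b**m * g / (g + c * m)
        return total

    def pmf(self) -> np.ndarray:
        """Exact pmf over 0..k.

        P(Y=m) = C(k,m) E[q^m (1-q)^{k-m}] with q = a(1 - u), u = e^{-cI};
        expanding in u and using E[u^n] = g/(g + c n).
        """
        a, c, g = self._mixture()
        k = self.k
        out = np.zeros(k + 1)
        for m in range(k + 1):
            tot = 0.0
            for r in range(m + 1):
                for s_ in range(k - m + 1):
                    tot += (
                        comb(m, r)
                        * (-1.0) ** r
                        * comb(k - m, s_)
                        * (1.0 - a) ** (k - m - s_)
                        * a ** s_
                        * g / (g + c * (r + s_))
                    )
            out[m] = comb(k, m) * a**m * tot
        out = np.clip(out, 0.0, None)
        return out / out.sum()

    def mean_variance(self) -> tuple[float, float]:
        pm = self.pmf()
        m = np.arange(self.k + 1)
        mean = float(m @ pm)
        return mean, float((m - mean) ** 2 @ pm)


def offspring_pgf(law: OffspringLaw, s: float) -> float:
    return law.pgf(s)


def offspring_pmf(law: OffspringLaw) -> np.ndarray:
    return law.pmf()


def offspring_moments(law: OffspringLaw) -> tuple[float, float]:
    return law.mean_variance()


@dataclass
class BranchingResult:
    model: str
    R0: float
    r: float
    sigma_fp: float    # extinction prob. of a non-initial line (PGF fixed point)
    p_major: float


def _mixture_pgf(pmf: np.ndarray, model: str, params: EpidemicParams, s: float) -> float:
    return sum(
        pk * OffspringLaw(k, model, params).pgf(s)
        for k, pk in enumerate(pmf)
        if pk > 0
    )


def p_major(
    params: EpidemicParams,
    dist: FinitePMF,
    model: str = "dropping",
    initial: str | int = "uniform-single",
    n_initial: int = 1,
) -> BranchingResult:
    """Major-outbreak probability from the branching approximation.

    sigma is the unique fixed point in [0, 1) of f~(s) = sum_k p~_k f_k(s),
    the offspring PGF of non-initial generations (p~ the pmf of D~ - 1).
    The initial infective has k susceptible neighbours with law

      * ``"uniform-single"``: k ~ D (uniformly chosen individual); with
        ``n_initial`` > 1 independent such initials, extinction requires all
        lines to die, so p_major = 1 - f(sigma)^n_initial;
      * an integer d: an initial infective of specified degree d.

    Subcritical (R_0 <= 1) gives p_major = 0.
    """
    if not isinstance(dist, FinitePMF):
        raise TypeError("p_major requires a finite-support degree distribution")
    r0 = R0(params, dist)
    r = malthusian_r(params, dist)
    if r0 <= 1.0:
        return BranchingResult(model, r0, r, 1.0, 0.0)
    ptilde = size_biased_minus_one(dist).pmf
    g = lambda s: _mixture_pgf(ptilde, model, params, s) - s
    hi = 1.0 - 1e-12
    while g(hi) >= 0.0:
        hi = 1.0 - 2.0 * (1.0 - hi)
        if hi < 0.25:
            raise RuntimeError("failed to bracket the PGF fixed point")
    sigma = brentq(g, 0.0, hi, xtol=1e-14) if g(0.0) > 0 else 0.0
    if isinstance(initial, int) and not isinstance(initial, bool):
        q = OffspringLaw(initial, model, params).pgf(sigma)
    elif initial == "uniform-single":
        q = _mixture_pgf(dist.pmf, model, params, sigma)
    else:
        raise ValueError(f"unknown initial specification {initial!r}")
    return BranchingResult(model, r0, r, sigma, 1.0 - q**n_initial)
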