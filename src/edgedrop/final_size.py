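"""Deterministic final size of the epidemic (law-of-large-numbers limit).

In the large-population limit the fraction rho of the population ultimately
infected in a major outbreak is rho = 1 - f(s), where f is the PGF of the
degree distribution (or of the deficit distribution D_eps when a
non-vanishing fraction is initially infective) and s is the unique root in
[0, 1) of

    (beta + omega + gamma) s - (omega + gamma) = beta mu_D^{-1} f'(s).

Equivalently, with s = psi~(z) = p_omega + (1 - p_omega) z, the variable
z = exp(-(beta+omega) tau~) solves

    [((beta+omega+gamma) z - gamma) / (beta+omega)] mu_D = f'(psi~(z)),

where tau~ is the duration of the time-transformed deterministic epidemic.
Because gamma and omega enter the s-equation only through their sum, the
final size is invariant under (gamma, omega) -> (gamma + omega, 0): dropping
an edge and recovery are interchangeable as far as the susceptibles are
concerned.

Setting gamma = omega = 0 and starting from a trace of infection reduces the
root equation to mu_D z = f'(z), whose solution gives the relative size
1 - f(z) of the giant component of the configuration-model graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .degree_models import DeficitPGFSpec, DegreeDistribution
from .params import EpidemicParams
from .branching import R0

__all__ = ["FinalSizeResult", "final_size", "final_size_residual", "giant_component_size"]

_ROOT_TOL = 1e-12


@dataclass
class FinalSizeResult:
    s_root: float          # root of the s-equation; 1.0 by convention if subcritical
    z: float               # e^{-(beta+omega) tau~}; equals psi~^{-1}(s)
    rho: float             # deterministic attack rate, 1 - f(s_root)
    tau_tilde: float       # -ln(z)/(beta+omega); inf if z == 0
    regime: str            # "supercritical" | "subcritical"


def _dist_and_spec(dist, epsilon_vec):
    """Normalize (dist, epsilon) into the PGF object the root equation uses."""
    if isinstance(dist, DeficitPGFSpec):
        return dist, dist.base
    if epsilon_vec is None:
        return dist, dist
    spec = DeficitPGFSpec(dist, np.asarray(epsilon_vec, dtype=float))
    return spec, dist


def final_size_residual(params: EpidemicParams, dist, s: float,
                        epsilon_vec=None) -> float:
    """Signed residual of the final-size root equation at s.

    Positive residual means the left side (beta+omega+gamma)s - (omega+gamma)
    exceeds beta mu_D^{-1} f'(s).  s = 1 is always a root when eps_E = 0.
    """
    if not (0.0 <= s <= 1.0):
        raise ValueError("s must lie in [0, 1]")
    f, base = _dist_and_spec(dist, epsilon_vec)
    b, g, w = params.beta, params.gamma, params.omega
    mu = base.mean
    return (b + w + g) * s - (w + g) - b * f.pgf_derivative(s, 1) / mu


def final_size(params: EpidemicParams, dist, epsilon_vec=None) -> FinalSizeResult:
    """Solve the deterministic final-size equation.

    With eps_E > 0 (epidemic started by a positive fraction of infectives)
    the root in [0, 1) always exists and is unique.  With eps_E = 0 the
    trivial root s = 1 is excluded; a non-trivial root exists iff R_0 > 1,
    otherwise rho = 0 is returned with regime = "subcritical".
    """
    f, base = _dist_and_spec(dist, epsilon_vec)
    b, g, w = params.beta, params.gamma, params.omega
    eps_E = f.eps_edges if isinstance(f, DeficitPGFSpec) else 0.0

    resid = lambda s: final_size_residual(params, f, s)

    if eps_E > 0:
        hi = 1.0
    else:
        if R0(params, base) <= 1.0:
            return FinalSizeResult(1.0, 1.0, 0.0, 0.0, "subcritical")
        # s = 1 solves the equation identically; shrink the right bracket
        # until the residual is positive (guaranteed since R0 > 1 makes the
        # residual positive just below 1).
        hi = 1.0 - 1e-12
        while resid(hi) <= 0.0:
            hi = 1.0 - 2.0 * (1.0 - hi)
            if hi < 0.5:
                raise RuntimeError("failed to bracket the non-trivial root")
    lo = 0.0
    if resid(lo) > 0.0:
        # can only happen when omega = gamma = 0 and f'(0) = 0: root at s=0
        s = 0.0
    else:
        s = brentq(resid, lo, hi, xtol=_ROOT_TOL, rtol=8.9e-16)
    rho = 1.0 - f.pgf_derivative(s, 0)
    if b + w > 0:
        z = ((b + w) * s - w) / b if b > 0 else 0.0
        z = min(max(z, 0.0), 1.0)
    else:
        z = s
    tau = math.inf if z <= 0 else -math.log(z) / (b + w)
    return FinalSizeResult(s, z, rho, tau, "supercritical")


def giant_component_size(dist: DegreeDistribution) -> FinalSizeResult:
    """Relative size of the giant component: rho = 1 - f_D(z), mu_D z = f'_D(z).

    No giant component exists when kappa = E[D(D-2)] <= 0, in which case
    rho = 0 is returned.
    """
    if dist.kappa <= 0:
        return FinalSizeResult(1.0, 1.0, 0.0, 0.0, "subcritical")
    mu = dist.mean
    resid = lambda z: mu * z - dist.pgf_derivative(z, 1)
    hi = 1.0 - 1e-12
    while resid(hi) <= 0.0:
        hi = 1.0 - 2.0 * (1.0 - hi)
        if hi < 0.5:
            raise RuntimeError("failed to bracket the giant-component root")
    if resid(0.0) >= 0.0:
        z = 0.0
    else:
        z = brentq(resid, 0.0, hi, xtol=_ROOT_TOL, rtol=8.9e-16)
    rho = 1.0 - dist.pgf_derivative(z, 0)
    return FinalSizeResult(z, z, rho, math.inf if z <= 0 else -math.log(z), "supercritical")
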