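"""Asymptotic variance of the final size of a major outbreak.

For the epidemic on a Molloy-Reed (prescribed-degree) graph the scaled final
size T_N / sqrt(N) is asymptotically Gaussian with variance

    sigma^2_MR = [four explicit terms in z, b~(z)] + I_A + I_B + I_C + I_D,

where z in (0, 1) solves the final-size equation, b~(z) is an explicit
ratio, and I_A..I_D are one-dimensional integrals over v in [z, 1] of smooth
functions built from the first three derivatives of the degree PGF.  On a
Newman-Strogatz-Watts graph (iid degrees) the extra randomness of the
empirical degree distribution contributes an additive, fully closed-form
term sigma_0^2, so

    sigma^2_NSW = sigma^2_MR + sigma_0^2.

With no dropping (omega = 0) the NSW variance collapses to a fully explicit
closed form in z, and with gamma = omega = 0 both variances reduce to the
giant-component CLT variances of the configuration model.  An approximation
of the final-size standard deviation in a population of size N is
sqrt(N) * sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .degree_models import DeficitPGFSpec, DegreeDistribution
from .final_size import FinalSizeResult, final_size, giant_component_size
from .params import EpidemicParams

__all__ = [
    "VarianceResult",
    "sigma2_mr",
    "sigma2_0",
    "sigma2_nsw",
    "sigma2_nodropping",
    "giant_component_variance",
    "b_tilde",
]

_QUAD_KW = dict(epsabs=1e-10, epsrel=1e-10, limit=200)


@dataclass
class VarianceResult:
    sigma2_mr: float
    sigma2_0: float | None
    sigma2_nsw: float | None
    components: dict
    fs: FinalSizeResult
    params: EpidemicParams

    def scaled_sd(self, N: int, graph: str = "nsw") -> float:
        s2 = self.sigma2_nsw if graph.lower() == "nsw" else self.sigma2_mr
        if s2 is None:
            raise ValueError(f"sigma^2 for graph {graph!r} not available")
        return float(np.sqrt(N * s2))


def _resolve(params, dist, epsilon_vec):
    """Return (pgf-like object f, base dist, FinalSizeResult)."""
    if isinstance(dist, DeficitPGFSpec):
        spec, base = dist, dist.base
    elif epsilon_vec is not None:
        spec = DeficitPGFSpec(dist, np.asarray(epsilon_vec, float))
        base = dist
    else:
        spec, base = dist, dist
    fs = final_size(params, spec)
    eps_E = spec.eps_edges if isinstance(spec, DeficitPGFSpec) else 0.0
    # In the trace-of-infection limit the deficit distribution is replaced by
    # D itself everywhere in the variance formulae.
    f = spec if eps_E > 0 else base
    return f, base, fs


def b_tilde(params: EpidemicParams, f, mu: float, z: float) -> float:
    """The coefficient b~(z) entering every variance formula."""
    b, g, w = params.beta, params.gamma, params.omega
    pw = params.p_omega
    psi_z = pw + (1.0 - pw) * z
    num = b * (((b + w + g) * z - g) / (b + w)) * mu
    den = z * (b * f.pgf_derivative(psi_z, 2) - (b + w + g) * mu)
    return num / den


def sigma2_mr(params: EpidemicParams, dist, epsilon_vec=None) -> VarianceResult:
    """Asymptotic final-size variance on a Molloy-Reed graph.

    Evaluates the four explicit leading terms plus the quadratures I_A..I_D.
    Requires z > 0 (equivalently tau~ < infinity), which fails only when
    gamma = omega = 0 and the degree-1 mass vanishes.
    """
    f, base, fs = _resolve(params, dist, epsilon_vec)
    b, g, w = params.beta, params.gamma, params.omega
    if fs.regime == "subcritical":
        raise ValueError("variance undefined in the subcritical regime")
    z = fs.z
    if z <= 0.0:
        raise ValueError(
            "z = 0 (infinite time-transformed duration): the final-size CLT "
            "variance formula does not apply; requires gamma, omega or "
            "degree-1 mass positive"
        )
    mu = base.mean
    sig2D = base.var
    pw = params.p_omega
    bw = b + w
    bt = b_tilde(params, f, mu, z)

    def psi1(v):
        return pw + (1.0 - pw) * z / v

    def psi2(v):
        return v * psi1(v) ** 2 + pw * (1.0 - v)

    def psi3(v):
        return psi1(v) - bt * z / v

    t1 = (
        2.0 * (bw + g) * (g - b - w - (bw + g) * z) / bw**2
        * mu * bt**2 * z**2 * (1.0 - z)
    )
    t2 = g / (b * bw) * mu * bt**2 * z * (b - (2.0 * b + w) * z) if g > 0 else 0.0
    t3 = (
        g / (b * (2.0 * bw + g)) * bt**2 * z**2 * (b * (sig2D + mu**2) + w * mu)
        if g > 0 else 0.0
    )
    t4 = (
        -g * ((bw + g) * z - g) * z / ((2.0 * bw + g) * bw) * mu * bt
        if g > 0 else 0.0
    )

    IA = quad(
        lambda v: (w * (psi3(v) - 1.0) ** 2 + b * psi3(v) ** 2)
        * f.pgf_derivative(psi2(v), 1),
        z, 1.0, **_QUAD_KW,
    )[0] / bw
    IB = (
        2.0 * w * z * bt / bw
        * quad(
            lambda v: psi1(v) * (psi1(v) - 1.0) * (1.0 - psi3(v))
            * f.pgf_derivative(psi2(v), 2),
            z, 1.0, **_QUAD_KW,
        )[0]
        if w > 0 else 0.0
    )
    IC = (
        b * z * bt / bw
        * quad(
            lambda v: psi1(v) ** 2 * (bt * z / v - 2.0 * psi3(v))
            * f.pgf_derivative(psi2(v), 2),
            z, 1.0, **_QUAD_KW,
        )[0]
    )
    ID = (
        z**2 * bt**2 / bw
        * quad(
            lambda v: (w * (psi1(v) - 1.0) ** 2 + b * psi1(v) ** 2)
            * psi1(v) ** 2 * f.pgf_derivative(psi2(v), 3),
            z, 1.0, **_QUAD_KW,
        )[0]
    )

    s2 = t1 + t2 + t3 + t4 + IA + IB + IC + ID
    comps = dict(t1=t1, t2=t2, t3=t3, t4=t4, I_A=IA, I_B=IB, I_C=IC, I_D=ID,
                 b_tilde=bt)
    return VarianceResult(s2, None, None, comps, fs, params)


def sigma2_0(params: EpidemicParams, dist: DegreeDistribution) -> float:
    """Extra variance from iid (NSW) degrees, trace-of-infection regime.

    Fully closed form in z, from the CLT for the empirical degree
    distribution propagated through the final-size functionals.
    """
    fs = final_size(params, dist)
    if fs.regime == "subcritical" or fs.z <= 0:
        raise ValueError("sigma_0^2 requires a supercritical outbreak with z > 0")
    z, rho = fs.z, fs.rho
    b, g, w = params.beta, params.gamma, params.omega
    bw = b + w
    mu, sig2D = dist.mean, dist.var
    pw = params.p_omega
    psi_z = pw + (1.0 - pw) * z
    bt = b_tilde(params, dist, mu, z)
    A = ((bw + g) * z - g) / bw
    f = dist.pgf_derivative
    return (
        f(psi_z**2, 0) - (1.0 - rho) ** 2
        + bt**2 * psi_z**2 * z**2 * f(psi_z**2, 2)
        + bt * f(psi_z**2, 1) * z * (z * bt - 2.0 * psi_z)
        + bt**2 * z**2 * A**2 * (sig2D + mu**2)
        - 2.0 * bt**2 * z**2 * mu * A * (A + (bw + g) / b * psi_z)
    )


def sigma2_nsw(params: EpidemicParams, dist: DegreeDistribution) -> VarianceResult:
    """sigma^2_NSW = sigma^2_MR + sigma_0^2 (trace-of-infection regime)."""
    res = sigma2_mr(params, dist)
    s0 = sigma2_0(params, dist)
    return VarianceResult(res.sigma2_mr, s0, res.sigma2_mr + s0,
                          res.components, res.fs, params)


def sigma2_nodropping(beta: float, gamma: float, dist, epsilon_vec=None,
                      graph: str = "nsw") -> float:
    """Closed-form final-size variance for the no-dropping (omega = 0) model.

    The NSW form is fully explicit in z and h(beta, gamma, z); the MR form is
    obtained from it by subtracting the degree-randomness term sigma_0^2.
    """
    params = EpidemicParams(beta, gamma, 0.0)
    f, base, fs = _resolve(params, dist, epsilon_vec)
    if fs.regime == "subcritical" or fs.z <= 0:
        raise ValueError("closed forms require a supercritical outbreak with z > 0")
    z, rho = fs.z, fs.rho
    mu, sig2D = base.mean, base.var
    h = (gamma - (beta + gamma) * z) / (
        beta + gamma - beta * f.pgf_derivative(z, 2) / mu
    )
    u = (gamma - (beta + gamma) * z) / beta
    s2_nsw = (
        rho * (1.0 - rho)
        + 2.0 * h * u * (beta + gamma) / (2.0 * beta + gamma) * mu
        + h**2 * (gamma / (2.0 * beta + gamma) + u**2) * (sig2D + mu**2)
        + 2.0 * h**2 * (beta + gamma) * (gamma - (beta + gamma) * z) / beta**2 * z * mu
    )
    if graph.lower() == "nsw":
        return s2_nsw
    if graph.lower() == "mr":
        return s2_nsw - sigma2_0(params, base)
    raise ValueError("graph must be 'mr' or 'nsw'")


def giant_component_variance(dist: DegreeDistribution, graph: str = "mr") -> float:
    """CLT variance of the giant-component size of a configuration model.

    Requires kappa = E[D(D-2)] > 0 (a giant component), p_1 > 0 and finite
    maximum degree.
    """
    if dist.kappa <= 0:
        raise ValueError("no giant component: kappa = E[D(D-2)] <= 0")
    if dist.pgf_derivative(0.0, 1) <= 0:
        raise ValueError("giant-component CLT requires p_1 > 0")
    gc = giant_component_size(dist)
    z, rho = gc.z, gc.rho
    mu, sig2D = dist.mean, dist.var
    f = dist.pgf_derivative
    denom = 1.0 - f(z, 2) / mu
    if graph.lower() == "mr":
        return (
            1.0 - rho - f(z**2, 0)
            - z**2 / denom * (2.0 * f(z**2, 1) - mu)
            - z**2 / denom**2 * (f(z**2, 1) + z**2 * f(z**2, 2) - 2.0 * mu * z**2)
        )
    if graph.lower() == "nsw":
        return (
            rho * (1.0 - rho)
            + z**2 / denom * mu
            + z**4 / denom**2 * (sig2D + mu**2 - 2.0 * mu)
        )
    raise ValueError("graph must be 'mr' or 'nsw'")
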