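"""Gaussian fluctuation machinery for the effective-degree Markov chain.

The scaled chain is a density dependent population process: from state
fractions w = (x_0..x_M, y_0..y_M, z_E) it jumps by l with intensity
N beta_l(w), for l in a finite jump set Delta.  Five jump families exist
(infection of a susceptible, edge formation between infectives, dropping of
a susceptible's edge, edge formation with a recovered stub, recovery), and

    F(w)  = sum_l l beta_l(w)            (drift),
    G(w)  = sum_l l^T l beta_l(w)        (local covariance),

give the LLN ODE dw/dt = F(w) and the fluctuation covariance ODE

    dSigma/dt = G(w) + dF(w) Sigma + Sigma dF(w)^T,

with Sigma(0) = 0 for prescribed (MR) initial conditions and Sigma(0) =
Sigma_0 (a multinomial covariance) for iid (NSW) degrees.  The same
machinery applies to the time-transformed chain, whose intensities are the
real-time ones multiplied by eta_E / y_E.  The covariance of the chain
stopped when the infective stub fraction y_E first hits delta is obtained
from Sigma~(tau~_delta) by the oblique projection

    B_delta = I - (F~ (x) grad phi) / (grad phi . F~),   phi(w) = y_E,

valid while grad phi . F~ < 0 (a proper crossing).

State ordering is (x_0..x_M, y_0..y_M, z_E) throughout; dimension 2M + 3.
Self-pairing corrections to the intensities are O(1/N) and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .degree_models import FinitePMF
from .deterministic import (
    drift_real_time,
    drift_transformed,
    initial_state,
)
from .params import EpidemicParams

__all__ = [
    "JumpModel",
    "CovarianceSolution",
    "drift",
    "diffusion_G",
    "jacobian_dF",
    "solve_covariance",
    "nsw_initial_covariance",
    "hitting_projection",
    "prevalence_moments",
]


@dataclass
class JumpModel:
    """Enumerated jump vectors and intensity evaluators for support 0..M."""

    M: int
    params: EpidemicParams
    variant: str = "real"   # "real" | "transformed"

    def __post_init__(self) -> None:
        if self.variant not in ("real", "transformed"):
            raise ValueError("variant must be 'real' or 'transformed'")
        M = self.M
        dim = 2 * M + 3
        jumps = []   # (vector, kind, i, j)
        for i in range(1, M + 1):
            for j in range(1, M + 1):
                # infection: type-i infective infects type-j susceptible
                v = np.zeros(dim)
                v[M + 1 + i] -= 1; v[M + 1 + i - 1] += 1
                v[j] -= 1; v[M + 1 + j - 1] += 1
                jumps.append((v, 1, i, j))
                # edge formed between infectives ('infection'/'warning' of an
                # infective; the two transitions coincide)
                v = np.zeros(dim)
                v[M + 1 + i] -= 1; v[M + 1 + i - 1] += 1
                v[M + 1 + j] -= 1; v[M + 1 + j - 1] += 1
                jumps.append((v, 2, i, j))
                # warning: type-j susceptible drops its edge
                v = np.zeros(dim)
                v[M + 1 + i] -= 1; v[M + 1 + i - 1] += 1
                v[j] -= 1; v[j - 1] += 1
                jumps.append((v, 3, i, j))
            # edge formed with a recovered stub
            v = np.zeros(dim)
            v[M + 1 + i] -= 1; v[M + 1 + i - 1] += 1
            v[2 * M + 2] -= 1
            jumps.append((v, 4, i, 0))
        for i in range(0, M + 1):
            # recovery of a type-i infective: its i stubs move to the
            # recovered pool
            v = np.zeros(dim)
            v[M + 1 + i] -= 1
            v[2 * M + 2] += i
            jumps.append((v, 5, i, 0))
        self.vectors = np.array([v for v, *_ in jumps])
        self.kinds = np.array([k for _, k, *_ in jumps])
        self.ii = np.array([i for _, _, i, _ in jumps])
        self.jj = np.array([j for _, _, _, j in jumps])

    def intensities(self, wv: np.ndarray) -> np.ndarray:
        """beta_l(w) for every enumerated jump, in enumeration order."""
        M = self.M
        b, g, w_ = self.params.beta, self.params.gamma, self.params.omega
        x = wv[: M + 1]
        y = wv[M + 1 : 2 * M + 2]
        z = wv[2 * M + 2]
        idx = np.arange(M + 1)
        yE = float(idx @ y)
        eta = float(idx @ x) + yE + z
        denom = eta if self.variant == "real" else yE
        if denom <= 0:
            raise ZeroDivisionError("intensities undefined at this state")
        out = np.empty(self.vectors.shape[0])
        i, j, k = self.ii, self.jj, self.kinds
        iy = np.where(k <= 4, i * y[np.clip(i, 0, M)], 0.0)
        out[k == 1] = b * (iy[k == 1] * (j[k == 1] * x[j[k == 1]])) / denom
        out[k == 2] = (b + w_) * (iy[k == 2] * (j[k == 2] * y[j[k == 2]])) / denom
        out[k == 3] = w_ * (iy[k == 3] * (j[k == 3] * x[j[k == 3]])) / denom
        out[k == 4] = (b + w_) * iy[k == 4] * z / denom
        if self.variant == "real":
            out[k == 5] = g * y[i[k == 5]]
        else:
            out[k == 5] = g * y[i[k == 5]] * eta / yE
        return out

    def drift_from_jumps(self, wv: np.ndarray) -> np.ndarray:
        return self.intensities(wv) @ self.vectors

    def diffusion_from_jumps(self, wv: np.ndarray) -> np.ndarray:
        beta = self.intensities(wv)
        return (self.vectors * beta[:, None]).T @ self.vectors


def drift(wv: np.ndarray, params: EpidemicParams, M: int,
          variant: str = "real") -> np.ndarray:
    """Closed-form drift F(w) (real) or F~(w) (transformed)."""
    if variant == "real":
        return drift_real_time(wv, params, M)
    return drift_transformed(wv, params, M)


def diffusion_G(wv: np.ndarray, params: EpidemicParams, M: int,
                variant: str = "real", model: JumpModel | None = None) -> np.ndarray:
    """Local covariance G(w) = sum_l l^T l beta_l(w)."""
    if model is None:
        model = JumpModel(M, params, variant)
    return model.diffusion_from_jumps(wv)


def jacobian_dF(wv: np.ndarray, params: EpidemicParams, M: int,
                variant: str = "real") -> np.ndarray:
    """Analytic Jacobian of the drift with respect to (x, y, z_E)."""
    b, g, w_ = params.beta, params.gamma, params.omega
    dim = 2 * M + 3
    x = wv[: M + 1]
    y = wv[M + 1 : 2 * M + 2]
    z = wv[2 * M + 2]
    idx = np.arange(M + 1, dtype=float)
    xE = float(idx @ x)
    yE = float(idx @ y)
    eta = xE + yE + z
    x_up = np.append(x[1:], 0.0)
    y_up = np.append(y[1:], 0.0)
    ip1 = idx + 1
    m = -(b + w_) * idx * x + w_ * ip1 * x_up       # x-drift / rho (or plain)
    L = ip1 * y_up - idx * y
    J = np.zeros((dim, dim))
    sx, sy, sz = slice(0, M + 1), slice(M + 1, 2 * M + 2), 2 * M + 2

    # dm_i/dx_j matrix (banded): diag -(b+w)i, super-diag w(i+1)
    dm = np.zeros((M + 1, M + 1))
    np.fill_diagonal(dm, -(b + w_) * idx)
    for i in range(M):
        dm[i, i + 1] = w_ * (i + 1)
    # dL_i/dy_j: diag -i, super-diag (i+1)
    dL = np.zeros((M + 1, M + 1))
    np.fill_diagonal(dL, -idx)
    for i in range(M):
        dL[i, i + 1] = i + 1
    # d(b (i+1) x_{i+1})/dx_j: super-diag b(i+1)
    dbx = np.zeros((M + 1, M + 1))
    for i in range(M):
        dbx[i, i + 1] = b * (i + 1)

    if variant == "real":
        rho = yE / eta
        drho_dx = -rho * idx / eta
        drho_dy = idx * (1.0 - rho) / eta
        drho_dz = -rho / eta
        # x rows: F_x = m * rho
        J[sx, sx] = rho * dm + np.outer(m, drho_dx)
        J[sx, sy] = np.outer(m, drho_dy)
        J[np.arange(M + 1), sz] = m * drho_dz
        # y rows: F_y = (b+w) L (1+rho) + b(i+1)x_{i+1} rho - g y
        coef = (b + w_) * L + b * ip1 * x_up
        J[sy, sx] = rho * dbx + np.outer(coef, drho_dx)
        J[sy, sy] = (b + w_) * (1.0 + rho) * dL + np.outer(coef, drho_dy)
        np.fill_diagonal(J[sy, sy], np.diag(J[sy, sy]) - g)
        J[M + 1 + np.arange(M + 1), sz] = coef * drho_dz
        # z row: F_z = g yE - (b+w) rho z
        J[sz, sx] = -(b + w_) * z * drho_dx
        J[sz, sy] = g * idx - (b + w_) * z * drho_dy
        J[sz, sz] = -(b + w_) * (rho + z * drho_dz)
        return J

    if yE <= 0:
        raise ZeroDivisionError("transformed Jacobian undefined at y_E = 0")
    phi = eta / yE
    dphi_dx = idx / yE
    dphi_dy = idx * (1.0 - phi) / yE
    dphi_dz = 1.0 / yE
    # x rows: F~_x = m (no rho factor)
    J[sx, sx] = dm
    # y rows: F~_y = (b+w) L (1+phi) + b(i+1)x_{i+1} - g y phi
    coef = (b + w_) * L - g * y
    J[sy, sx] = dbx + np.outer(coef, dphi_dx)
    J[sy, sy] = (b + w_) * (1.0 + phi) * dL + np.outer(coef, dphi_dy)
    np.fill_diagonal(J[sy, sy], np.diag(J[sy, sy]) - g * phi)
    J[M + 1 + np.arange(M + 1), sz] = coef * dphi_dz
    # z row: F~_z = g eta - (b+w) z
    J[sz, sx] = g * idx
    J[sz, sy] = g * idx
    J[sz, sz] = g - (b + w_)
    return J


@dataclass
class CovarianceSolution:
    t: np.ndarray
    w: np.ndarray            # states, shape (len(t), 2M+3)
    sigma: np.ndarray        # covariance matrices, shape (len(t), 2M+3, 2M+3)
    M: int
    variant: str
    tau_delta: float | None = None

    def block(self, which: str, k: int = -1) -> np.ndarray:
        """Covariance block at time index k: 'xx', 'yy', 'xy', 'zz'."""
        M = self.M
        sl = dict(x=slice(0, M + 1), y=slice(M + 1, 2 * M + 2),
                  z=slice(2 * M + 2, 2 * M + 3))
        a, b = which[0], which[1]
        return self.sigma[k][sl[a], sl[b]]


def _tril_pack(S, dim, idx):
    return S[idx]


def solve_covariance(params: EpidemicParams, dist: FinitePMF, epsilon_vec,
                     t_end: float, variant: str = "real",
                     sigma0: np.ndarray | None = None,
                     stop_at: float | None = None,
                     t_eval=None, rtol: float = 1e-7, atol: float = 1e-9,
                     homogeneous: bool = False) -> CovarianceSolution:
    """Jointly integrate the state ODEs and the covariance matrix ODE.

    ``sigma0`` is the initial covariance (zero for MR, multinomial for NSW).
    For the transformed variant, ``stop_at`` = delta stops integration when
    y~_E = delta (event detection).  ``homogeneous`` drops the G term, which
    solves the homogeneous part of the Sigma ODE (used to verify the
    additivity of initial-condition covariance).
    """
    M = dist.support_max
    dim = 2 * M + 3
    w0 = initial_state(dist, epsilon_vec)
    if sigma0 is None:
        S0 = np.zeros((dim, dim))
    else:
        S0 = np.asarray(sigma0, float)
        if S0.shape != (dim, dim):
            raise ValueError(f"sigma0 must have shape {(dim, dim)}")
        if not np.allclose(S0, S0.T, atol=1e-10):
            raise ValueError("sigma0 must be symmetric")
    tril = np.tril_indices(dim)
    model = JumpModel(M, params, variant)
    i_w = np.arange(M + 1)

    def unpack(u):
        wv = u[:dim]
        S = np.zeros((dim, dim))
        S[tril] = u[dim:]
        S = S + S.T - np.diag(np.diag(S))
        return wv, S

    def rhs(t, u):
        wv, S = unpack(u)
        Fw = drift(wv, params, M, variant)
        A = jacobian_dF(wv, params, M, variant)
        dS = A @ S + S @ A.T
        if not homogeneous:
            dS = dS + model.diffusion_from_jumps(wv)
        return np.concatenate([Fw, dS[tril]])

    events = None
    if variant == "transformed":
        delta = stop_at if stop_at is not None else 0.0

        def hit(t, u):
            return float(i_w @ u[M + 1 : 2 * M + 2]) - delta

        hit.terminal = True
        hit.direction = -1
        events = [hit]

    u0 = np.concatenate([w0, S0[tril]])
    res = solve_ivp(rhs, (0.0, t_end), u0, method="RK45", events=events,
                    rtol=rtol, atol=atol, t_eval=t_eval)
    if not res.success:
        raise RuntimeError(f"covariance integration failed: {res.message}")
    tau = None
    if events and res.t_events[0].size:
        tau = float(res.t_events[0][0])
    W = res.y[:dim].T
    Sflat = res.y[dim:].T
    sig = np.zeros((len(res.t), dim, dim))
    for k in range(len(res.t)):
        S = np.zeros((dim, dim))
        S[tril] = Sflat[k]
        sig[k] = S + S.T - np.diag(np.diag(S))
    return CovarianceSolution(res.t, W, sig, M, variant, tau)


def nsw_initial_covariance(dist: FinitePMF, epsilon: float) -> np.ndarray:
    """Sigma_0 for iid degrees and uniformly-chosen initial infectives.

    The degree counts of initial susceptibles/infectives are multinomial, so
    the x-block has diagonal p_i(1-p_i)(1-eps) and off-diagonal
    -p_i p_j (1-eps); the y-block is the same with eps; cross blocks and the
    z_E row/column vanish.
    """
    if not (0.0 <= epsilon < 1.0):
        raise ValueError("epsilon must lie in [0, 1)")
    p = dist.pmf
    M = dist.support_max
    dim = 2 * M + 3
    S = np.zeros((dim, dim))
    blk = np.diag(p) - np.outer(p, p)
    S[: M + 1, : M + 1] = blk * (1.0 - epsilon)
    S[M + 1 : 2 * M + 2, M + 1 : 2 * M + 2] = blk * epsilon
    return S


def hitting_projection(sigma: np.ndarray, w_at_stop: np.ndarray,
                       params: EpidemicParams, M: int) -> np.ndarray:
    """Project the transformed-time covariance onto the hitting surface.

    phi(w) = y_E; requires grad phi . F~ < 0 at the stopping state.  Returns
    B Sigma B^T with B = I - (F~ outer grad phi)/(grad phi . F~).
    """
    dim = 2 * M + 3
    grad = np.zeros(dim)
    grad[M + 1 : 2 * M + 2] = np.arange(M + 1)
    Fw = drift(w_at_stop, params, M, "transformed")
    a = float(grad @ Fw)
    if a >= 0:
        raise ValueError("crossing condition grad(phi).F~ < 0 violated")
    B = np.eye(dim) - np.outer(Fw, grad) / a
    return B @ sigma @ B.T


def final_size_variance_ode_route(params: EpidemicParams, dist: FinitePMF,
                                  epsilon_vec, deltas=(0.02, 0.01, 0.005),
                                  sigma0: np.ndarray | None = None,
                                  rtol: float = 1e-7) -> float:
    """sigma^2 of the final size via the covariance-ODE + projection route.

    Integrates the transformed-time covariance to y~_E = delta, projects with
    B_delta, extracts the (1, 0, 0)-weighted scalar (total susceptibles) and
    extrapolates linearly in delta to delta = 0.  Serves as an independent
    numerical check of the explicit variance formulas.
    """
    dim = 2 * dist.support_max + 3
    M = dist.support_max
    vals = []
    ones = np.zeros(dim)
    ones[: M + 1] = 1.0
    for d in deltas:
        cs = solve_covariance(params, dist, epsilon_vec, t_end=60.0,
                              variant="transformed", stop_at=d, sigma0=sigma0,
                              rtol=rtol)
        if cs.tau_delta is None:
            raise RuntimeError(f"y~_E never reached delta={d}")
        proj = hitting_projection(cs.sigma[-1], cs.w[-1], params, M)
        vals.append(float(ones @ proj @ ones))
    if len(vals) == 1:
        return vals[0]
    coef = np.polyfit(np.asarray(deltas, float), np.asarray(vals), 1)
    return float(coef[-1])


def prevalence_moments(cs: CovarianceSolution):
    """Mean and sd curves (per-N fractions) of the number of infectives."""
    M = cs.M
    mean = cs.w[:, M + 1 : 2 * M + 2].sum(axis=1)
    var = cs.sigma[:, M + 1 : 2 * M + 2, M + 1 : 2 * M + 2].sum(axis=(1, 2))
    return mean, np.sqrt(np.clip(var, 0.0, None))
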