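"""Law-of-large-numbers (deterministic) dynamics of the effective-degree model.

State fractions: x_i(t), y_i(t) are the fractions of the population that are
susceptible / infective with effective degree i (i = 0..M), and z_E(t) is the
fraction (per individual) of unpaired stubs attached to recovered
individuals.  Aggregates: x_E = sum i x_i, y_E = sum i y_i,
eta_E = x_E + y_E + z_E and rho_E = y_E / eta_E (the fraction of unpaired
stubs that belong to infectives).

Two time scales are used:

* real time: the limit of the scaled Markov chain itself;
* transformed time: the clock is sped up by eta_E / y_E, which decouples the
  susceptible block and makes the system explicitly solvable.  Real time t
  corresponds to transformed time xi(t) = int_0^t rho_E(u) du, and
  w(t) = w~(xi(t)).

In transformed time the closed forms are (psi(t) = p_w + (1-p_w) e^{-(b+w)t},
f the deficit PGF, c = beta + omega):

    x~_i(t)  = e^{-c i t} / i! * f^(i)(p_w (1 - e^{-c t}))
    x~_E(t)  = e^{-c t} f'(psi(t))
    x~(t)    = f(psi(t))
    eta~_E(t)= mu_D e^{-2 c t}
    z~_E(t)  = (gamma/c) mu_D e^{-c t} (1 - e^{-c t})
    y~_E(t)  = eta~_E - x~_E - z~_E

The epidemic ends at tau~ = inf{t : y~_E(t) = 0}.  theta(t), the probability
that a given stub has not transmitted infection to its owner by real time t,
satisfies d theta/dt = beta f'(theta)/mu_D - (beta+gamma+omega) theta +
gamma + omega with theta(0) = 1, and theta(t) = psi(xi(t)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .degree_models import DeficitPGFSpec, FinitePMF
from .params import EpidemicParams

__all__ = [
    "DeterministicSolution",
    "TimeChange",
    "initial_state",
    "drift_real_time",
    "drift_transformed",
    "solve_real_time",
    "solve_time_transformed",
    "closed_form_tilde",
    "solve_xi_and_theta",
    "infective_fraction_tilde",
]

_IVP_KW = dict(rtol=1e-8, atol=1e-10, dense_output=True)


@dataclass
class DeterministicSolution:
    """ODE solution on a time grid; state ordering (x_0..x_M, y_0..y_M, z_E)."""

    t: np.ndarray
    x: np.ndarray          # shape (len(t), M+1)
    y: np.ndarray          # shape (len(t), M+1)
    z_E: np.ndarray
    variant: str           # "real" | "transformed"
    status: str = "ok"
    tau_delta: float | None = None   # stop time when event detection fired
    sol = None             # dense-output callable (scipy OdeSolution)

    @property
    def M(self) -> int:
        return self.x.shape[1] - 1

    @property
    def x_E(self) -> np.ndarray:
        return self.x @ np.arange(self.x.shape[1])

    @property
    def y_E(self) -> np.ndarray:
        return self.y @ np.arange(self.y.shape[1])

    @property
    def eta_E(self) -> np.ndarray:
        return self.x_E + self.y_E + self.z_E

    @property
    def rho_E(self) -> np.ndarray:
        return self.y_E / self.eta_E

    @property
    def x_total(self) -> np.ndarray:
        return self.x.sum(axis=1)

    @property
    def y_total(self) -> np.ndarray:
        return self.y.sum(axis=1)


@dataclass
class TimeChange:
    """xi (real -> transformed time), theta, and psi."""

    params: EpidemicParams
    t: np.ndarray
    xi_values: np.ndarray
    theta_values: np.ndarray
    _xi_sol: object = None
    _theta_sol: object = None

    def xi(self, t):
        return self._xi_sol(np.asarray(t))[0]

    def theta(self, t):
        return self._theta_sol(np.asarray(t))[0]

    def psi(self, u):
        pw = self.params.p_omega
        c = self.params.beta + self.params.omega
        return pw + (1.0 - pw) * np.exp(-c * np.asarray(u))


def initial_state(dist: FinitePMF, epsilon_vec) -> np.ndarray:
    """w(0) = (p_i - eps_i, eps_i, 0)."""
    eps = np.zeros(dist.pmf.size)
    ev = np.asarray(epsilon_vec, float)
    eps[: ev.size] = ev
    if np.any(eps > dist.pmf + 1e-12):
        raise ValueError("epsilon_k may not exceed p_k")
    return np.concatenate([dist.pmf - eps, eps, [0.0]])


def _split(wv: np.ndarray, M: int):
    return wv[: M + 1], wv[M + 1 : 2 * M + 2], wv[2 * M + 2]


def drift_real_time(wv: np.ndarray, params: EpidemicParams, M: int) -> np.ndarray:
    """Closed-form drift F(w) of the real-time limit."""
    b, g, w_ = params.beta, params.gamma, params.omega
    x, y, z = _split(wv, M)
    i = np.arange(M + 1)
    xE = float(i @ x)
    yE = float(i @ y)
    eta = xE + yE + z
    rho = yE / eta if eta > 0 else 0.0
    x_up = np.append(x[1:], 0.0)
    y_up = np.append(y[1:], 0.0)
    ip1 = i + 1
    dx = (-(b + w_) * i * x + w_ * ip1 * x_up) * rho
    L = ip1 * y_up - i * y
    dy = (b + w_) * L * (1.0 + rho) + b * ip1 * x_up * rho - g * y
    dz = g * yE - (b + w_) * rho * z
    return np.concatenate([dx, dy, [dz]])


def drift_transformed(wv: np.ndarray, params: EpidemicParams, M: int,
                      yE_floor: float | None = None) -> np.ndarray:
    """Closed-form drift F~(w) of the time-transformed limit (needs y_E > 0).

    ``yE_floor`` clamps y_E from below; used by the ODE driver so that the
    right-hand side stays finite while event detection locates y~_E = delta
    (the solver may evaluate slightly past the crossing).
    """
    b, g, w_ = params.beta, params.gamma, params.omega
    x, y, z = _split(wv, M)
    i = np.arange(M + 1)
    xE = float(i @ x)
    yE = float(i @ y)
    eta = xE + yE + z
    if yE <= 0:
        if yE_floor is None:
            raise ZeroDivisionError("transformed drift undefined at y_E = 0")
        yE = yE_floor
    phi = eta / yE      # 1/rho_E
    x_up = np.append(x[1:], 0.0)
    y_up = np.append(y[1:], 0.0)
    ip1 = i + 1
    dx = -(b + w_) * i * x + w_ * ip1 * x_up
    L = ip1 * y_up - i * y
    dy = (b + w_) * L * (1.0 + phi) + b * ip1 * x_up - g * y * phi
    dz = g * eta - (b + w_) * z
    return np.concatenate([dx, dy, [dz]])


def _solve(params, dist, epsilon_vec, t_end, variant, stop_at_yE, rtol, atol,
           t_eval=None):
    M = dist.support_max
    w0 = initial_state(dist, epsilon_vec)
    i = np.arange(M + 1)
    if float(i @ w0[M + 1 : 2 * M + 2]) <= 0:
        raise ValueError("eps_E > 0 required for the ODE limits")
    rhs = (
        (lambda t, wv: drift_real_time(wv, params, M))
        if variant == "real"
        else (lambda t, wv: drift_transformed(wv, params, M, yE_floor=1e-9))
    )
    events = []
    if variant == "transformed":
        delta = stop_at_yE if stop_at_yE is not None else 0.0
        # y~_E = 0 is a singular boundary (the drift carries 1/rho~_E); the
        # event is placed at a tiny positive level instead.  The crossing
        # slope is finite and O(1), so the error in tau~ is O(1e-8).
        delta = max(delta, 1e-7)

        def hit(t, wv):
            return float(i @ wv[M + 1 : 2 * M + 2]) - delta

        hit.terminal = True
        hit.direction = -1
        events.append(hit)
    res = solve_ivp(rhs, (0.0, t_end), w0, method="LSODA", events=events or None,
                    rtol=rtol, atol=atol, dense_output=True, t_eval=t_eval)
    if not res.success:
        raise RuntimeError(f"ODE integration failed: {res.message}")
    t = res.t
    Y = res.y.T
    tau = None
    status = "ok"
    if events and res.t_events[0].size:
        tau = float(res.t_events[0][0])
        status = "hit"
    sol = DeterministicSolution(
        t=t, x=Y[:, : M + 1], y=Y[:, M + 1 : 2 * M + 2], z_E=Y[:, 2 * M + 2],
        variant=variant, status=status, tau_delta=tau,
    )
    sol.sol = res.sol
    return sol


def solve_real_time(params: EpidemicParams, dist: FinitePMF, epsilon_vec,
                    t_end: float, rtol: float = 1e-8, atol: float = 1e-10,
                    t_eval=None) -> DeterministicSolution:
    """Solve the (2M+3)-dimensional real-time ODE limit on [0, t_end]."""
    return _solve(params, dist, epsilon_vec, t_end, "real", None, rtol, atol,
                  t_eval)


def solve_time_transformed(params: EpidemicParams, dist: FinitePMF, epsilon_vec,
                           stop_at_yE: float = 0.0, t_max: float = 50.0,
                           rtol: float = 1e-8, atol: float = 1e-10,
                           t_eval=None) -> DeterministicSolution:
    """Solve the transformed-time ODEs until y~_E(t) = stop_at_yE.

    The right-hand side carries a 1/rho~_E factor, so integration with
    stop_at_yE = 0 relies on event detection stopping exactly at the root
    (beyond it y~_E would go negative and the system is singular).
    """
    return _solve(params, dist, epsilon_vec, t_max, "transformed", stop_at_yE,
                  rtol, atol, t_eval)


def closed_form_tilde(params: EpidemicParams, spec: DeficitPGFSpec, t):
    """Explicit transformed-time solution at time(s) t.

    Returns a dict with x_i (matrix), x_E, eta_E, z_E, y_E and x (the
    susceptible fraction).  Valid for any t >= 0, also beyond tau~ (where
    y_E goes negative).
    """
    t = np.atleast_1d(np.asarray(t, float))
    b, g, w_ = params.beta, params.gamma, params.omega
    c = b + w_
    pw = params.p_omega
    mu = spec.mean
    base = spec.base
    M = base.support_max if isinstance(base, FinitePMF) else spec.epsilon.size - 1
    ect = np.exp(-c * t)
    psi = pw + (1.0 - pw) * ect
    arg = pw * (1.0 - ect)
    x_i = np.empty((t.size, M + 1))
    for j, (a, e) in enumerate(zip(arg, ect)):
        for i in range(M + 1):
            x_i[j, i] = e**i / math.factorial(i) * spec.pgf_derivative(a, i)
    fp = np.array([spec.pgf_derivative(p, 1) for p in psi])
    x_E = ect * fp
    eta_E = mu * ect**2
    z_E = (g / c) * mu * ect * (1.0 - ect)
    y_E = eta_E - x_E - z_E
    x_tot = np.array([spec.pgf_derivative(p, 0) for p in psi])
    return dict(t=t, x_i=x_i, x_E=x_E, eta_E=eta_E, z_E=z_E, y_E=y_E, x=x_tot,
                psi=psi)


def solve_xi_and_theta(params: EpidemicParams, spec: DeficitPGFSpec,
                       t_end: float, rtol: float = 1e-10,
                       atol: float = 1e-12) -> TimeChange:
    """Solve the time-change ODE for xi(t) and the theta ODE jointly.

    xi requires eps_E > 0 (rho_E(0) > 0); theta is solvable for eps_E >= 0
    and satisfies theta(t) = psi(xi(t)).
    """
    b, g, w_ = params.beta, params.gamma, params.omega
    c = b + w_
    pw = params.p_omega
    mu = spec.mean

    def xi_rhs(t, u):
        e = math.exp(c * u[0])
        psi_xi = pw + (1.0 - pw) / e
        return [1.0 + (g / c) * (1.0 - e) - e * spec.pgf_derivative(psi_xi, 1) / mu]

    def theta_rhs(t, u):
        th = min(max(u[0], 0.0), 1.0)
        return [b * spec.pgf_derivative(th, 1) / mu - (b + g + w_) * th + g + w_]

    r1 = solve_ivp(xi_rhs, (0.0, t_end), [0.0], method="LSODA", rtol=rtol,
                   atol=atol, dense_output=True)
    r2 = solve_ivp(theta_rhs, (0.0, t_end), [1.0], method="LSODA", rtol=rtol,
                   atol=atol, dense_output=True)
    if not (r1.success and r2.success):
        raise RuntimeError("time-change integration failed")
    return TimeChange(params, r1.t, r1.y[0], r2.y[0], r1.sol, r2.sol)


def infective_fraction_tilde(params: EpidemicParams, spec: DeficitPGFSpec,
                             t_grid) -> np.ndarray:
    """Transformed-time infective fraction y~(t) on a grid.

    Solves d y~/dt = -(gamma/rho~_E) y~ + beta e^{-(beta+omega) t} f'(psi(t))
    with y~(0) = eps, using the closed forms for rho~_E.  The grid must stay
    below tau~ (rho~_E > 0).
    """
    t_grid = np.asarray(t_grid, float)
    b, g, w_ = params.beta, params.gamma, params.omega
    c = b + w_
    pw = params.p_omega
    mu = spec.mean

    def rho_tilde(t):
        cf = closed_form_tilde(params, spec, [t])
        return cf["y_E"][0] / cf["eta_E"][0]

    def rhs(t, u):
        psi = pw + (1.0 - pw) * math.exp(-c * t)
        infl = b * math.exp(-c * t) * spec.pgf_derivative(psi, 1)
        if g == 0:
            return [infl]
        return [-(g / rho_tilde(t)) * u[0] + infl]

    res = solve_ivp(rhs, (0.0, float(t_grid[-1])), [spec.eps_total],
                    method="LSODA", t_eval=t_grid, **_IVP_KW)
    if not res.success:
        raise RuntimeError(f"y~ integration failed: {res.message}")
    return res.y[0]
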