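"""Exact stochastic simulation of the epidemic.

Three routes to the same law:

* :func:`simulate` — Gillespie simulation of the effective-degree Markov
  chain, in which the network is constructed while the epidemic spreads:
  each unpaired stub of an infective fires at rate beta (infection attempt)
  plus omega (warning); the firing stub pairs with a uniformly chosen other
  unpaired stub.  Pairing with a susceptible's stub infects (or, for a
  warning, silently drops the edge); pairing with an infective's or
  recovered's stub just forms an edge; pairing with another stub of the same
  infective forms a self-loop.  Infectives recover at rate gamma, keeping
  their unpaired stubs.

* :func:`simulate_graph_backend` — build the configuration multigraph first
  (uniform stub pairing, self-loops and multi-edges retained, odd leftover
  stub ignored), then run the per-edge dynamics: infection at rate beta and
  dropping at rate omega on each susceptible-infective edge, recovery at
  rate gamma.  Distributionally equivalent to the effective-degree chain.

* :func:`exact_ctmc_final_size` — exact final-size pmf for tiny
  configurations by enumerating the continuous-time Markov chain.  Because
  every pairing removes two stubs and every recovery removes an infective,
  the embedded jump chain is acyclic and absorption probabilities follow by
  forward propagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .degree_models import FinitePMF
from .params import EpidemicParams

__all__ = [
    "InitSpec",
    "EpidemicOutcome",
    "mr_degree_sequence",
    "largest_remainder",
    "simulate",
    "trajectory_at",
    "simulate_graph_backend",
    "exact_ctmc_final_size",
    "estimate_major_outbreak",
    "MajorOutbreakEstimate",
]


@dataclass(frozen=True)
class InitSpec:
    """Initial conditions: graph mode and number of initial infectives.

    mode "MR": deterministic degree sequence from the target pmf (largest
    remainder) and initial infectives spread over degrees in population
    proportions.  mode "NSW": iid degrees and uniformly chosen infectives.
    ``n_infectives`` may be an int (count) or a float in (0, 1) (fraction).
    """

    mode: str = "NSW"
    n_infectives: float = 1
    def __post_init__(self):
        if self.mode not in ("MR", "NSW"):
            raise ValueError("mode must be 'MR' or 'NSW'")

    def count(self, N: int) -> int:
        n = self.n_infectives
        i0 = int(round(n * N)) if isinstance(n, float) and 0 < n < 1 else int(n)
        if not (0 < i0 < N):
            raise ValueError(f"need 0 < i0 < N, got i0={i0}, N={N}")
        return i0


@dataclass
class EpidemicOutcome:
    final_size: int                 # number ever infected (incl. initials)
    extinction_time: float
    n: int                          # population size
    final_susceptibles_by_effective_degree: np.ndarray | None = None
    trajectory: list = field(default_factory=list)   # (t, prevalence, susceptibles, y_E)


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, float)
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def mr_degree_sequence(dist: FinitePMF, N: int) -> np.ndarray:
    """Molloy-Reed degree counts: largest-remainder rounding of N p_k."""
    return largest_remainder(dist.pmf, N)


def _initial_counts(dist: FinitePMF, N: int, init: InitSpec, rng):
    """Return (X counts, Y counts) per degree 0..M."""
    i0 = init.count(N)
    if init.mode == "MR":
        counts = mr_degree_sequence(dist, N)
        inf = largest_remainder(dist.pmf, i0)
        over = inf - counts
        if np.any(over > 0):  # cap at availability, put surplus anywhere free
            inf = np.minimum(inf, counts)
            deficit = i0 - inf.sum()
            free = counts - inf
            k = 0
            while deficit > 0:
                if free[k] > 0:
                    take = min(free[k], deficit)
                    inf[k] += take
                    deficit -= take
                k += 1
    else:
        degs = rng.choice(dist.pmf.size, size=N, p=dist.pmf)
        counts = np.bincount(degs, minlength=dist.pmf.size)
        chosen = rng.choice(N, size=i0, replace=False)
        inf = np.bincount(degs[chosen], minlength=dist.pmf.size)
    return counts - inf, inf


def simulate(params: EpidemicParams, dist: FinitePMF, N: int, init: InitSpec,
             seed: int | np.random.Generator = 0,
             record: str = "final_only") -> EpidemicOutcome:
    """One realization of the effective-degree Markov chain.

    ``record="trajectory"`` stores (t, prevalence, #susceptibles, y_E stubs)
    at every event.  Terminates when no infective remains.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X0, Y0 = _initial_counts(dist, N, init, rng)
    M = dist.pmf.size - 1
    X = [int(v) for v in X0]
    Y = [int(v) for v in Y0]
    Z = 0
    ks = list(range(M + 1))
    nEX = sum(k * X[k] for k in ks)
    nEY = sum(k * Y[k] for k in ks)
    nI = sum(Y)
    nS = sum(X)
    # odd total stub: one stub is ignored.  Remove it from a uniformly chosen
    # stub owner (susceptible or infective) by decrementing its degree class.
    if (nEX + nEY) % 2 == 1:
        u = rng.random() * (nEX + nEY)
        acc = 0.0
        done = False
        for k in range(1, M + 1):
            acc += k * X[k]
            if u < acc:
                X[k] -= 1; X[k - 1] += 1; nEX -= 1; done = True
                break
        if not done:
            for k in range(1, M + 1):
                acc += k * Y[k]
                if u < acc:
                    Y[k] -= 1; Y[k - 1] += 1; nEY -= 1
                    break
    beta, gamma, omega = params.beta, params.gamma, params.omega
    bw = beta + omega
    p_infect = beta / bw if bw > 0 else 0.0
    t = 0.0
    infected = nI
    traj = []
    rand = rng.random
    exp = rng.exponential
    if record == "trajectory":
        traj.append((0.0, nI, nS, nEY))
    while nI > 0:
        ntot = nEX + nEY + Z
        act = bw * nEY if ntot >= 2 else 0.0
        rec = gamma * nI
        total = act + rec
        if total <= 0.0:
            break
        t += exp(1.0 / total)
        if rand() * total < rec:
            # recovery: pick type i with prob Y_i / nI
            u = rand() * nI
            acc = 0.0
            for k in ks:
                acc += Y[k]
                if u < acc:
                    Y[k] -= 1; Z += k; nEY -= k; nI -= 1
                    break
        else:
            # stub activation: actor type i with prob i Y_i / nEY
            u = rand() * nEY
            acc = 0.0
            i = 0
            for k in range(1, M + 1):
                acc += k * Y[k]
                if u < acc:
                    i = k
                    break
            # partner stub uniform among the other ntot - 1 stubs
            u = rand() * (ntot - 1)
            acc = 0.0
            partner = None
            for k in range(1, M + 1):
                acc += k * X[k]
                if u < acc:
                    partner = ("S", k)
                    break
            if partner is None:
                for k in range(1, M + 1):
                    cnt = k * Y[k] - (1 if k == i else 0)
                    acc += cnt
                    if u < acc:
                        partner = ("I", k)
                        break
            if partner is None:
                partner = ("R", 0)
            kind, j = partner
            if kind == "S":
                if rand() < p_infect:
                    X[j] -= 1; nS -= 1; nEX -= j
                    Y[i] -= 1; Y[i - 1] += 1
                    Y[j - 1] += 1
                    nEY += j - 2
                    nI += 1
                    infected += 1
                else:   # warning: edge dropped, both stubs consumed
                    X[j] -= 1; X[j - 1] += 1; nEX -= 1
                    Y[i] -= 1; Y[i - 1] += 1; nEY -= 1
            elif kind == "R":
                Z -= 1
                Y[i] -= 1; Y[i - 1] += 1; nEY -= 1
            else:
                # infective partner; possibly the actor itself (self-loop)
                if j == i and i >= 2 and rand() * (i * Y[i] - 1) < (i - 1):
                    Y[i] -= 1; Y[i - 2] += 1; nEY -= 2
                else:
                    Y[i] -= 1; Y[i - 1] += 1
                    Y[j] -= 1; Y[j - 1] += 1
                    nEY -= 2
        if record == "trajectory":
            traj.append((t, nI, nS, nEY))
    final_sus = np.array(X, dtype=int)
    return EpidemicOutcome(infected, t, N, final_sus, traj)


def trajectory_at(outcome: EpidemicOutcome, times) -> np.ndarray:
    """Sample a recorded trajectory at given times (piecewise-constant).

    Returns an array of shape (len(times), 3): prevalence, #susceptibles,
    infective stub count y_E at each requested time.
    """
    if not outcome.trajectory:
        raise ValueError("outcome was not recorded with record='trajectory'")
    arr = np.asarray(outcome.trajectory, dtype=float)
    idx = np.searchsorted(arr[:, 0], np.asarray(times, float), side="right") - 1
    idx = np.clip(idx, 0, arr.shape[0] - 1)
    return arr[idx, 1:]


# ---------------------------------------------------------------------------
# explicit-graph backend


def _pair_stubs(degrees: np.ndarray, rng):
    """Uniform stub pairing; returns edge list (u, v).  Odd stub ignored."""
    stubs = np.repeat(np.arange(degrees.size), degrees)
    rng.shuffle(stubs)
    if stubs.size % 2 == 1:
        stubs = stubs[:-1]
    return stubs.reshape(-1, 2)


def simulate_graph_backend(params: EpidemicParams, degree_sequence,
                           i0: int, seed: int | np.random.Generator = 0,
                           infective_ids=None) -> EpidemicOutcome:
    """Build the multigraph first, then run per-edge Markov dynamics."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    degrees = np.asarray(degree_sequence, int)
    N = degrees.size
    edges = _pair_stubs(degrees, rng)
    incident = [[] for _ in range(N)]
    for e, (u, v) in enumerate(edges):
        incident[u].append(e)
        if v != u:
            incident[v].append(e)
    status = np.zeros(N, dtype=np.int8)   # 0 S, 1 I, 2 R
    if infective_ids is None:
        infective_ids = rng.choice(N, size=i0, replace=False)
    status[list(infective_ids)] = 1
    alive = np.ones(len(edges), dtype=bool)

    def is_si(e):
        u, v = edges[e]
        return alive[e] and u != v and status[u] + status[v] == 1

    si = [e for e in range(len(edges)) if is_si(e)]
    si_pos = {e: k for k, e in enumerate(si)}
    infectives = list(np.flatnonzero(status == 1))
    inf_pos = {v: k for k, v in enumerate(infectives)}

    def si_remove(e):
        k = si_pos.pop(e)
        last = si.pop()
        if last != e:
            si[k] = last
            si_pos[last] = k

    def si_add(e):
        si_pos[e] = len(si)
        si.append(e)

    beta, gamma, omega = params.beta, params.gamma, params.omega
    t = 0.0
    infected = len(infectives)
    while infectives:
        r_edge = (beta + omega) * len(si)
        r_rec = gamma * len(infectives)
        total = r_edge + r_rec
        if total <= 0.0:   # no SI edges and no recovery: epidemic frozen
            break
        t += rng.exponential(1.0 / total)
        if rng.random() * total < r_rec:
            w = infectives[int(rng.random() * len(infectives))]
            k = inf_pos.pop(w)
            last = infectives.pop()
            if last != w:
                infectives[k] = last
                inf_pos[last] = k
            status[w] = 2
            for e in incident[w]:
                if e in si_pos:
                    si_remove(e)
            continue
        e = si[int(rng.random() * len(si))]
        u, v = edges[e]
        s_node = u if status[u] == 0 else v
        if rng.random() * (beta + omega) < omega:
            alive[e] = False          # dropped
            si_remove(e)
            continue
        # infection of s_node
        status[s_node] = 1
        infected += 1
        inf_pos[s_node] = len(infectives)
        infectives.append(s_node)
        for e2 in incident[s_node]:
            if not alive[e2]:
                continue
            a, b = edges[e2]
            if a == b:
                continue
            other = a if b == s_node else b
            if status[other] == 0:
                if e2 not in si_pos:
                    si_add(e2)
            else:
                if e2 in si_pos:
                    si_remove(e2)
    return EpidemicOutcome(infected, t, N, None, [])


# ---------------------------------------------------------------------------
# exact CTMC enumeration (tiny state spaces)


def exact_ctmc_final_size(params: EpidemicParams, degree_sequence, i0: int,
                          max_states: int = 200_000) -> dict[int, float]:
    """Exact pmf of the final size by enumerating the jump chain.

    ``degree_sequence`` gives the degrees of all N individuals; the first
    ``i0`` (sorted descending by degree grouping is irrelevant — individuals
    are exchangeable within a degree class) are initially infective.  Total
    stubs must be small (the state space is enumerated exhaustively).

    States are (X counts, Y counts, Z); every pairing removes two stubs and
    every recovery removes an infective while keeping stubs, so states are
    ordered by (total unpaired stubs, #infectives) and the chain is acyclic.
    """
    degrees = np.asarray(degree_sequence, int)
    if degrees.sum() > 24:
        raise ValueError("exact enumeration intended for <= 24 total stubs")
    M = int(degrees.max(initial=0))
    counts = np.bincount(degrees, minlength=M + 1)
    inf0 = np.bincount(degrees[:i0], minlength=M + 1)
    # ignore one leftover stub deterministically is impossible (random owner);
    # require an even total for exactness
    if degrees.sum() % 2 == 1:
        raise ValueError("odd total stubs: the ignored-stub rule makes the "
                         "initial state random; use an even total")
    X0 = tuple(int(v) for v in counts - inf0)
    Y0 = tuple(int(v) for v in inf0)
    start = (X0, Y0, 0)
    beta, gamma, omega = params.beta, params.gamma, params.omega
    bw = beta + omega

    def transitions(state):
        X, Y, Z = state
        X = list(X); Y = list(Y)
        nEX = sum(k * v for k, v in enumerate(X))
        nEY = sum(k * v for k, v in enumerate(Y))
        ntot = nEX + nEY + Z
        out = []
        for i in range(1, M + 1):
            if Y[i] == 0:
                continue
            base = i * Y[i]
            if ntot >= 2:
                den = ntot - 1
                for j in range(1, M + 1):
                    if X[j] > 0:
                        # infection
                        if beta > 0:
                            Xn = X.copy(); Yn = Y.copy()
                            Xn[j] -= 1
                            Yn[i] -= 1; Yn[i - 1] += 1; Yn[j - 1] += 1
                            out.append((beta * base * j * X[j] / den,
                                        (tuple(Xn), tuple(Yn), Z)))
                        # warning drops the edge
                        if omega > 0:
                            Xn = X.copy(); Yn = Y.copy()
                            Xn[j] -= 1; Xn[j - 1] += 1
                            Yn[i] -= 1; Yn[i - 1] += 1
                            out.append((omega * base * j * X[j] / den,
                                        (tuple(Xn), tuple(Yn), Z)))
                    cnt = j * Y[j] - (1 if j == i else 0)
                    cnt -= (i - 1) if j == i else 0   # self stubs handled below
                    if cnt > 0 and bw > 0:
                        Yn = Y.copy()
                        Yn[i] -= 1; Yn[i - 1] += 1
                        Yn[j] -= 1; Yn[j - 1] += 1
                        out.append((bw * base * cnt / den,
                                    (tuple(X), tuple(Yn), Z)))
                if i >= 2 and bw > 0:
                    # self-pairing: the actor pairs two of its own stubs
                    Yn = Y.copy()
                    Yn[i] -= 1; Yn[i - 2] += 1
                    out.append((bw * base * (i - 1) / den,
                                (tuple(X), tuple(Yn), Z)))
                if Z > 0 and bw > 0:
                    Yn = Y.copy()
                    Yn[i] -= 1; Yn[i - 1] += 1
                    out.append((bw * base * Z / den,
                                (tuple(X), tuple(Yn), Z - 1)))
        if gamma > 0:
            for i in range(M + 1):
                if Y[i] > 0:
                    Yn = list(Y)
                    Yn[i] -= 1
                    out.append((gamma * Y[i], (tuple(X), tuple(Yn), Z + i)))
        return out

    # forward propagation in topological order (stubs, infectives) decreasing
    from collections import defaultdict

    prob = defaultdict(float)
    prob[start] = 1.0
    N = int(degrees.size)
    S0 = int(sum(X0))

    def level(state):
        X, Y, Z = state
        stubs = sum(k * v for k, v in enumerate(X)) + sum(
            k * v for k, v in enumerate(Y)) + Z
        return (stubs, sum(Y))

    final_pmf = defaultdict(float)
    frontier = {start: 1.0}
    seen_states = 1
    while frontier:
        # process the state with the maximal level first
        state = max(frontier, key=level)
        p = frontier.pop(state)
        X, Y, Z = state
        if sum(Y) == 0:
            final_pmf[i0 + (S0 - sum(X))] += p
            continue
        trs = transitions(state)
        tot = sum(r for r, _ in trs)
        if tot <= 0:   # no events possible but infectives remain (gamma=0, isolated)
            final_pmf[i0 + (S0 - sum(X))] += p
            continue
        for r, ns in trs:
            frontier[ns] = frontier.get(ns, 0.0) + p * r / tot
            seen_states += 1
            if seen_states > max_states:
                raise ValueError("state space too large for exact enumeration")
    return dict(sorted(final_pmf.items()))


# ---------------------------------------------------------------------------
# ensemble estimation


@dataclass
class MajorOutbreakEstimate:
    p_hat: float
    ci: tuple[float, float]
    n_major: int
    n_reps: int
    mean_major: float | None
    mean_ci: tuple[float, float] | None
    sd_major: float | None
    sd_ci: tuple[float, float] | None
    final_sizes: np.ndarray


def estimate_major_outbreak(params: EpidemicParams, dist: FinitePMF, N: int,
                            init: InitSpec, n_reps: int,
                            threshold_frac: float = 0.15,
                            seed: int = 0) -> MajorOutbreakEstimate:
    """Monte-Carlo estimate of the major-outbreak probability and the
    mean/sd of major-outbreak final sizes, with 95% CIs.

    A run is major when final_size >= threshold_frac * N.  The sd CI
    endpoints are the square roots of the chi-square variance CI endpoints.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    sizes = np.empty(n_reps, dtype=int)
    for k, child in enumerate(ss.spawn(n_reps)):
        rng = np.random.default_rng(child)
        sizes[k] = simulate(params, dist, N, init, seed=rng).final_size
    thresh = threshold_frac * N
    major = sizes >= thresh
    m = int(major.sum())
    p_hat = m / n_reps
    half = 1.959963984540054 * math.sqrt(max(p_hat * (1 - p_hat), 0.0) / n_reps)
    ci = (max(p_hat - half, 0.0), min(p_hat + half, 1.0))
    if m >= 2:
        vals = sizes[major].astype(float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        mean_half = 1.959963984540054 * sd / math.sqrt(m)
        mean_ci = (mean - mean_half, mean + mean_half)
        from scipy.stats import chi2
        lo = (m - 1) * sd**2 / chi2.ppf(0.975, m - 1)
        hi = (m - 1) * sd**2 / chi2.ppf(0.025, m - 1)
        sd_ci = (math.sqrt(lo), math.sqrt(hi))
    else:
        mean = sd = None
        mean_ci = sd_ci = None
    return MajorOutbreakEstimate(p_hat, ci, m, n_reps, mean, mean_ci, sd, sd_ci,
                                 sizes)
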