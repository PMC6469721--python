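"""Named experiment scenarios and YAML configuration loading.

A scenario bundles rates, a degree specification, the population size,
initial conditions and replication controls.  The built-in scenarios
reproduce the numerical study settings: degree distributions Poi(5)
(truncated at 15) and Geo(1/6) (truncated at 50), beta = 3/2, gamma = 1,
with dropping rate omega = 2 against the modified no-dropping model with
recovery rate 3, at N = 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .degree_models import FinitePMF, GeometricDegree, PoissonDegree, truncate
from .effective_degree import InitSpec
from .params import EpidemicParams

__all__ = ["Scenario", "load_scenario", "builtin_scenarios", "resolve_degree"]

_DEFAULT_M = {"poisson": 15, "geometric": 50}


def resolve_degree(cfg: dict):
    """Build (analytic family or None, truncated FinitePMF) from a config dict."""
    fam = cfg.get("family")
    if fam == "poisson":
        analytic = PoissonDegree(float(cfg["lambda"]))
    elif fam == "geometric":
        analytic = GeometricDegree(float(cfg["p"]))
    elif fam == "custom":
        if "pmf_csv" in cfg:
            # two-column CSV: degree k, probability p_k
            import pandas as pd

            tab = pd.read_csv(cfg["pmf_csv"])
            k = tab.iloc[:, 0].to_numpy(int)
            pmf = np.zeros(int(k.max()) + 1)
            pmf[k] = tab.iloc[:, 1].to_numpy(float)
        else:
            pmf = np.asarray(cfg["pmf"], dtype=float)
        return None, FinitePMF(pmf / pmf.sum())
    else:
        raise ValueError(f"unknown degree family {fam!r}")
    M = int(cfg.get("truncate_at", _DEFAULT_M[fam]))
    return analytic, truncate(analytic, M, tail_tol=float(cfg.get("tail_tol", 1e-3)))


@dataclass
class Scenario:
    name: str
    params: EpidemicParams
    degree: dict
    N: int = 1000
    init: InitSpec = field(default_factory=lambda: InitSpec("NSW", 1))
    replicates: int = 2000
    seed: int = 0
    threshold_frac: float = 0.15

    @property
    def dist(self) -> FinitePMF:
        return resolve_degree(self.degree)[1]

    @property
    def analytic_dist(self):
        return resolve_degree(self.degree)[0]

    def to_dict(self) -> dict:
        return dict(
            name=self.name,
            beta=self.params.beta, gamma=self.params.gamma,
            omega=self.params.omega,
            degree=self.degree, N=self.N,
            init=dict(mode=self.init.mode, n_infectives=self.init.n_infectives),
            replicates=self.replicates, seed=self.seed,
            threshold_frac=self.threshold_frac,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        for key in ("beta", "gamma", "degree"):
            if key not in d:
                raise ValueError(f"scenario is missing required field {key!r}")
        init = d.get("init", {})
        return cls(
            name=d.get("name", "unnamed"),
            params=EpidemicParams(float(d["beta"]), float(d["gamma"]),
                                  float(d.get("omega", 0.0))),
            degree=d["degree"],
            N=int(d.get("N", 1000)),
            init=InitSpec(init.get("mode", "NSW"),
                          init.get("n_infectives", 1)),
            replicates=int(d.get("replicates", 2000)),
            seed=int(d.get("seed", 0)),
            threshold_frac=float(d.get("threshold_frac", 0.15)),
        )


def builtin_scenarios() -> dict[str, Scenario]:
    poi = dict(family="poisson", **{"lambda": 5.0}, truncate_at=15)
    geo = dict(family="geometric", p=1.0 / 6.0, truncate_at=50)
    sc = {}
    for tag, deg in (("poisson", poi), ("geometric", geo)):
        sc[f"table1_{tag}_dropping"] = Scenario(
            f"table1_{tag}_dropping", EpidemicParams(1.5, 1.0, 2.0), deg,
            N=1000, init=InitSpec("NSW", 1), replicates=2000)
        sc[f"table1_{tag}_modified"] = Scenario(
            f"table1_{tag}_modified", EpidemicParams(1.5, 3.0, 0.0), deg,
            N=1000, init=InitSpec("NSW", 1), replicates=2000)
        sc[f"fig1_{tag}"] = Scenario(
            f"fig1_{tag}", EpidemicParams(1.5, 1.0, 1.0), deg,
            N=1000, init=InitSpec("NSW", 0.05), replicates=1000)
    return sc


def load_scenario(path_or_name) -> Scenario:
    """Load a scenario by built-in name or from a YAML file."""
    builtins = builtin_scenarios()
    name = str(path_or_name)
    if name in builtins:
        return builtins[name]
    with open(name) as fh:
        data = yaml.safe_load(fh)
    return Scenario.from_dict(data)
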