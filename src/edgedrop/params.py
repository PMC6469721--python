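"""Model rate parameters."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class EpidemicParams:
    """Rates of the SIR epidemic with preventive dropping.

    beta   per-edge infection rate of an infective towards a neighbour,
    gamma  recovery rate of an infective,
    omega  per-edge dropping ('warning') rate.

    ``p_omega = omega / (beta + omega)`` is the probability that a given
    susceptible-infective edge is dropped rather than transmitting, given
    that one of the two happens before recovery intervenes.
    """

    beta: float
    gamma: float
    omega: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0 or self.gamma < 0 or self.omega < 0:
            raise ValueError("rates must be non-negative")
        if self.beta + self.gamma + self.omega <= 0:
            raise ValueError("at least one rate must be positive")

    @property
    def p_omega(self) -> float:
        if self.beta + self.omega == 0:
            return 0.0
        return self.omega / (self.beta + self.omega)

    def modified(self) -> "EpidemicParams":
        """The no-dropping model with recovery rate increased to gamma+omega."""
        return EpidemicParams(self.beta, self.gamma + self.omega, 0.0)
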