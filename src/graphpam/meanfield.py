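"""Closed-form mean-field results and phase classification.

On the fully connected graph (per-pair weight 1/N) the normalized field
M_i = m_i / sum_j m_j has the exact stationary density

    P_eq(M) = A exp(-(mu-1)/M) / M^mu,   A = (mu-1)^mu / Gamma(mu),

with the single dimensionless parameter mu = 1 + 2J/sigma^2 controlling the
Pareto tail.  Two critical values structure the phase diagram: mu = 1
(localization: a few nodes carry everything) and mu = 3, where the
stationary second moment (mu-1)/(mu-3) diverges — equivalently
sigma_c2^2 = J, i.e. J/sigma^2 = 1.  For general topologies the phase count
is set by the spectral dimension: d~ <= 2 is always intermittent, d~ > 2
has a transition at a finite sigma_c^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MeanFieldParams",
    "PhaseReport",
    "mu_param",
    "normalization_constant",
    "equilibrium_density",
    "stationary_second_moment",
    "classify_phase_meanfield",
    "classify_phase_topology",
    "phase_report",
]

#: half-width treated as exactly critical at the mu = 1, 3 boundaries
CRITICAL_EPS = 1e-12


def mu_param(J: float, sigma_sq: float) -> float:
    """Mean-field tail exponent ``mu = 1 + 2 J / sigma^2``."""
    if sigma_sq <= 0:
        raise ValueError("sigma^2 must be positive (mu is infinite at zero noise)")
    return 1.0 + 2.0 * J / sigma_sq


def normalization_constant(mu: float) -> float:
    """``A = (mu-1)^mu / Gamma(mu)``; requires mu > 1."""
    if mu <= 1:
        raise ValueError("P_eq is normalizable only for mu > 1")
    return math.exp(mu * math.log(mu - 1.0) - math.lgamma(mu))


def equilibrium_density(M: np.ndarray | float, mu: float) -> np.ndarray | float:
    """Stationary density ``A exp(-(mu-1)/M) / M^mu`` of the normalized field.

    Normalized to 1 on (0, inf); mode at ``(mu-1)/mu``; Pareto tail
    ``M^{-mu}``.
    """
    if mu <= 1:
        raise ValueError("P_eq is normalizable only for mu > 1")
    M = np.asarray(M, dtype=float)
    if np.any(M <= 0):
        raise ValueError("M must be positive")
    A = normalization_constant(mu)
    return A * np.exp(-(mu - 1.0) / M) / M**mu


def stationary_second_moment(mu: float) -> float:
    """Stationary normalized second moment ``(mu-1)/(mu-3)``.

    Returns ``inf`` for mu <= 3 (no finite stationary second moment — the
    divergence is reported, not raised).
    """
    if mu <= 3.0:
        return math.inf
    return (mu - 1.0) / (mu - 3.0)


def classify_phase_meanfield(mu: float) -> str:
    """Phase label of the mean-field model as a function of mu."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if abs(mu - 1.0) <= CRITICAL_EPS or abs(mu - 3.0) <= CRITICAL_EPS:
        return "critical"
    if mu < 1.0:
        return "localized"
    if mu < 3.0:
        return "intermittent-heavy-tail"
    return "finite-fluctuations"


def classify_phase_topology(
    d_tilde: float, sigma_sq: float | None = None, sigma_c_sq: float | None = None
) -> str:
    """Phase label for a general topology from its spectral dimension.

    Recurrent families (d~ <= 2) are intermittent at every noise level; a
    transient family (d~ > 2) needs its critical variance to place the
    point on either side of the transition.
    """
    if d_tilde < 0:
        raise ValueError("spectral dimension must be nonnegative")
    if d_tilde <= 2.0:
        return "always-intermittent"
    if sigma_c_sq is None:
        raise ValueError("sigma_c_sq is required for d_tilde > 2")
    if sigma_sq is None:
        return "transition-at-sigma-c"
    return "intermittent" if sigma_sq <= sigma_c_sq else "finite-correlation"


@dataclass(frozen=True)
class MeanFieldParams:
    J: float
    sigma_sq: float

    @property
    def mu(self) -> float:
        return mu_param(self.J, self.sigma_sq)

    @property
    def A(self) -> float:
        return normalization_constant(self.mu)


@dataclass(frozen=True)
class PhaseReport:
    mu: float
    phase_label: str
    sigma_c2_sq: float  # second-moment critical variance (= J in mean field)
    sigma_cH_sq: float | str  # high-noise critical point
    d_tilde: float | None = None

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "phase": self.phase_label,
            "sigma_c2_sq": self.sigma_c2_sq,
            "sigma_cH_sq": self.sigma_cH_sq
            if isinstance(self.sigma_cH_sq, str)
            else float(self.sigma_cH_sq),
            "d_tilde": self.d_tilde,
        }


def phase_report(
    J: float, sigma_sq: float, d_tilde: float | None = None, sigma_c_sq: float | None = None
) -> PhaseReport:
    """Assemble the phase report for a parameter point.

    Without a topology, the mean-field classification applies and the
    high-noise critical point is infinite; with a spectral dimension the
    topological classification is used instead and the high-noise point is
    recorded as not computable perturbatively.
    """
    mu = mu_param(J, sigma_sq)
    if d_tilde is None:
        label = classify_phase_meanfield(mu)
        sigma_cH: float | str = math.inf
    else:
        label = classify_phase_topology(d_tilde, sigma_sq, sigma_c_sq)
        sigma_cH = "not-computable-perturbatively"
    return PhaseReport(
        mu=mu,
        phase_label=label,
        sigma_c2_sq=J,
        sigma_cH_sq=sigma_cH,
        d_tilde=d_tilde,
    )
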