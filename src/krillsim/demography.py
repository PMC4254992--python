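"""Per-individual demographic processes for the krill population model.

The simulated population is a set of individuals, each carrying a body
length (mm) and an age (months).  Three processes act on it every month:

* **Mortality** — each individual survives a month with probability
  ``1 - M/100`` where ``M`` is a proportional monthly mortality rate (%).
  ``M`` is related to the exponential decay rate ``m`` (yr^-1) familiar
  from aggregate population models by ``M = 100 * (1 - exp(-m/12))``;
  a natural mortality of 1.0 yr^-1 converts to about 8% month^-1, and the
  default model input is exactly 8.0% month^-1.

* **Growth** — a von Bertalanffy increment whose monthly coefficient is
  modulated by a sinusoidal seasonal factor SV(t) in [-1, +1] (peaking in
  late austral summer, flat growth in winter at full amplitude).  The
  modulation is normalised so that the monthly coefficients sum to the
  annual coefficient K over any 12-month window: length-at-age at annual
  boundaries is identical to the aseasonal von Bertalanffy curve.

* **Recruit initialisation** — new one-year-olds receive a length drawn
  from a normal distribution (default mean 21.742 mm = von Bertalanffy
  length at age 1 with L_inf = 60 mm, K = 0.45 yr^-1; sd 2 mm), truncated
  to (0, L_inf) so growth monotonicity is never violated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

__all__ = [
    "MortalityParams",
    "GrowthParams",
    "PopulationState",
    "monthly_mortality_percent",
    "survive",
    "initial_length",
    "seasonal_modulator",
    "monthly_growth_coefficient",
    "grow",
]

_TWO_PI = 2.0 * np.pi


def monthly_mortality_percent(m_annual: float) -> float:
    """Convert an exponential decay rate (yr^-1) to a proportional monthly rate (%).

    ``M = 100 * (1 - exp(-m/12))``.  For ``m = 1.0`` this is 7.9945...%,
    conventionally rounded to 8% month^-1 for presentation; the exact value
    is returned and rounding is left to the caller.
    """
    if m_annual < 0:
        raise ValueError(f"annual mortality rate must be >= 0, got {m_annual}")
    return 100.0 * (1.0 - np.exp(-m_annual / 12.0))


@dataclass(frozen=True)
class MortalityParams:
    """Proportional monthly mortality rate, optionally tied to an annual rate.

    The model input is ``M_monthly`` (% month^-1, default 8.0 — the
    conventional rounding of a 1.0 yr^-1 natural mortality).  When
    ``m_annual`` is also supplied the two must be consistent under
    :func:`monthly_mortality_percent`.
    """

    M_monthly: float = 8.0
    m_annual: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.M_monthly < 100.0:
            raise ValueError(f"M_monthly must be in [0, 100), got {self.M_monthly}")
        if self.m_annual is not None:
            expected = monthly_mortality_percent(self.m_annual)
            if abs(expected - self.M_monthly) > 1e-6:
                raise ValueError(
                    f"inconsistent rates: m_annual={self.m_annual} implies "
                    f"M_monthly={expected:.6f}, got {self.M_monthly}"
                )

    @classmethod
    def from_annual_rate(cls, m_annual: float) -> "MortalityParams":
        """Build from an exponential annual rate using the exact conversion."""
        return cls(M_monthly=monthly_mortality_percent(m_annual), m_annual=m_annual)


@dataclass(frozen=True)
class GrowthParams:
    """Seasonal von Bertalanffy growth and recruit-initialisation parameters.

    Parameters
    ----------
    l_inf : asymptotic length (mm).
    k_annual : von Bertalanffy growth coefficient (yr^-1).
    init_mean, init_sd : normal distribution of recruit initial lengths (mm).
        The default mean 21.742 mm is the length-at-age-1 of the default
        curve: ``60 * (1 - exp(-0.45)) = 21.742``.
    sv_phase : calendar month (1-12) at which the seasonal modulator peaks
        (default 2 = February, the austral sea-surface-temperature maximum).
    sv_amplitude : seasonal amplitude in [0, 1]; 1 means growth stops
        entirely at the winter trough.
    """

    l_inf: float = 60.0
    k_annual: float = 0.45
    init_mean: float = 21.742
    init_sd: float = 2.0
    sv_phase: int = 2
    sv_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (self.l_inf > self.init_mean > 0):
            raise ValueError(
                f"need l_inf > init_mean > 0, got l_inf={self.l_inf}, "
                f"init_mean={self.init_mean}"
            )
        if self.k_annual <= 0:
            raise ValueError(f"k_annual must be > 0, got {self.k_annual}")
        if self.init_sd < 0:
            raise ValueError(f"init_sd must be >= 0, got {self.init_sd}")
        if not 1 <= int(self.sv_phase) <= 12:
            raise ValueError(f"sv_phase must be a month 1-12, got {self.sv_phase}")
        if not 0.0 <= self.sv_amplitude <= 1.0:
            raise ValueError(f"sv_amplitude must be in [0, 1], got {self.sv_amplitude}")


@dataclass
class PopulationState:
    """Parallel per-individual arrays plus the current absolute month (0-based).

    ``month_index = 0`` is January of the first simulated year; recruits
    enter as one-year-olds (age 12 months).
    """

    lengths: np.ndarray = field(default_factory=lambda: np.empty(0))
    ages: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    month_index: int = 0

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        self.ages = np.asarray(self.ages, dtype=np.int32)
        if self.lengths.shape != self.ages.shape:
            raise ValueError("lengths and ages must have equal size")

    @property
    def n(self) -> int:
        return self.lengths.size

    @property
    def month_of_year(self) -> int:
        """Calendar month 1-12 of the month currently being processed."""
        return self.month_index % 12 + 1

    @classmethod
    def empty(cls, month_index: int = 0) -> "PopulationState":
        return cls(np.empty(0), np.empty(0, dtype=np.int32), month_index)


def survive(
    state: PopulationState, M: float, rng: np.random.Generator
) -> PopulationState:
    """Apply one month of Bernoulli mortality; survivors age by one month.

    Each individual independently draws a uniform probability on [0, 100)%
    and survives when the draw exceeds ``M``, i.e. with probability
    ``1 - M/100``.  Order of survivors is preserved.
    """
    if not 0.0 <= M < 100.0:
        raise ValueError(f"M must be in [0, 100), got {M}")
    keep = rng.random(state.n) * 100.0 > M
    return replace(
        state, lengths=state.lengths[keep], ages=state.ages[keep] + 1
    )


def initial_length(
    n: int, g: GrowthParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` recruit initial lengths ~ Normal(init_mean, init_sd), truncated to (0, l_inf)."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if n == 0:
        return np.empty(0)
    if g.init_sd == 0.0:
        return np.full(n, g.init_mean)
    a = (0.0 - g.init_mean) / g.init_sd
    b = (g.l_inf - g.init_mean) / g.init_sd
    return truncnorm.rvs(a, b, loc=g.init_mean, scale=g.init_sd, size=n, random_state=rng)


def seasonal_modulator(month_of_year, g: GrowthParams):
    """Sinusoidal seasonal growth modulator SV(t), amplitude-scaled.

    A cosine with a 12-month period: ``+sv_amplitude`` at ``sv_phase`` and
    ``-sv_amplitude`` six months later; sums to zero over any 12 consecutive
    months, which is what keeps annual length-at-age on the aseasonal curve.
    """
    m = np.asarray(month_of_year)
    if np.any((m < 1) | (m > 12)):
        raise ValueError(f"month_of_year must be in 1..12, got {month_of_year}")
    out = g.sv_amplitude * np.cos(_TWO_PI * (m - g.sv_phase) / 12.0)
    return out if out.ndim else float(out)


def monthly_growth_coefficient(month_of_year, g: GrowthParams):
    """Seasonally modulated monthly vB coefficient ``k_t = K/12 * (1 + SV(t))``."""
    return g.k_annual / 12.0 * (1.0 + seasonal_modulator(month_of_year, g))


def grow(state: PopulationState, g: GrowthParams) -> PopulationState:
    """One month of seasonal von Bertalanffy growth.

    ``L <- L + (l_inf - L) * (1 - exp(-k_t))`` with ``k_t`` from
    :func:`monthly_growth_coefficient` at the state's current calendar month.
    Lengths are non-decreasing and bounded by ``l_inf``.
    """
    k_t = monthly_growth_coefficient(state.month_of_year, g)
    new_lengths = g.l_inf - (g.l_inf - state.lengths) * np.exp(-k_t)
    return replace(state, lengths=new_lengths)
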