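"""Yearly mean-temperature scenarios over a plantation rotation.

A scenario is a linear warming trend ``T_t = T0 + k t`` for planting years
``t = 1..H``, optionally with independent Gaussian interannual fluctuations
around the trend.  Selection on the planted cohort acts in years 1..H; the
planting-year temperature (t = 0) enters no computation.

Named presets follow common usage: total warming realised over a 60-year
rotation under four emission scenarios, and three interannual-fluctuation
strengths bracketing the observed global average of local interannual
standard deviations (~0.45 degC).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InvalidScenarioError

#: Total warming (degC) realised over a 60-year rotation, per named scenario.
WARMING_OVER_60Y = {
    "control": 0.0,
    "intermediate": 1.7,
    "high": 2.6,
    "very-high": 3.3,
}

#: Interannual fluctuation standard deviations (degC), per named preset.
FLUCTUATION_SD = {
    "weak": 0.35,
    "moderate": 0.5,
    "strong": 0.65,
}


def rate_from_endpoints(total_warming: float, H: int) -> float:
    """Warming rate k (degC/year) from total warming over the rotation.

    ``k = (T_H - T0) / H``.

    Parameters
    ----------
    total_warming : float
        Temperature change realised between planting and harvest (degC).
    H : int
        Rotation length in years; must be >= 1.
    """
    if H < 1:
        raise InvalidScenarioError(f"rotation length must be >= 1, got {H}")
    return total_warming / H


@dataclass(frozen=True)
class ClimateScenario:
    """Linear warming trend with optional Gaussian interannual fluctuations.

    Attributes
    ----------
    T0 : float
        Baseline mean annual temperature at planting (degC).
    k : float
        Warming rate (degC per year).
    H : int
        Rotation length (years between planting and harvest), >= 1.
    sigma_f : float
        Standard deviation of interannual fluctuations around the trend
        (degC, >= 0).  Zero means a deterministic scenario.
    seed : int, optional
        Seed for the fluctuation draws.  Required whenever ``sigma_f > 0``
        and a reproducible series is generated without an explicit RNG.
    """

    T0: float
    k: float
    H: int
    sigma_f: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if int(self.H) != self.H or self.H < 1:
            raise InvalidScenarioError(f"rotation length must be a positive integer, got {self.H}")
        if self.sigma_f < 0:
            raise InvalidScenarioError(f"sigma_f must be >= 0, got {self.sigma_f}")

    @classmethod
    def from_total_warming(
        cls,
        T0: float,
        total_warming: float,
        H: int,
        sigma_f: float = 0.0,
        seed: Optional[int] = None,
    ) -> "ClimateScenario":
        """Scenario from the warming realised over the whole rotation."""
        return cls(T0=T0, k=rate_from_endpoints(total_warming, H), H=H, sigma_f=sigma_f, seed=seed)

    @classmethod
    def preset(
        cls,
        T0: float = 0.0,
        warming: str | float = "intermediate",
        H: int = 60,
        fluctuation: str | float | None = None,
        seed: Optional[int] = None,
    ) -> "ClimateScenario":
        """Scenario from named presets.

        ``warming`` is a preset name (total warming over 60 years is rescaled
        to the requested ``H`` at the same per-year rate) or a numeric total
        warming over ``H`` years.  ``fluctuation`` is a preset name, a numeric
        standard deviation, or None (deterministic).
        """
        if isinstance(warming, str):
            try:
                total_60 = WARMING_OVER_60Y[warming]
            except KeyError:
                raise InvalidScenarioError(
                    f"unknown warming preset {warming!r}; options: {sorted(WARMING_OVER_60Y)}"
                ) from None
            k = rate_from_endpoints(total_60, 60)
        else:
            k = rate_from_endpoints(float(warming), H)
        if fluctuation is None:
            sigma_f = 0.0
        elif isinstance(fluctuation, str):
            try:
                sigma_f = FLUCTUATION_SD[fluctuation]
            except KeyError:
                raise InvalidScenarioError(
                    f"unknown fluctuation preset {fluctuation!r}; options: {sorted(FLUCTUATION_SD)}"
                ) from None
        else:
            sigma_f = float(fluctuation)
        return cls(T0=T0, k=k, H=H, sigma_f=sigma_f, seed=seed)

    def with_seed(self, seed: Optional[int]) -> "ClimateScenario":
        return replace(self, seed=seed)

    def deterministic(self) -> "ClimateScenario":
        """The same warming trend with fluctuations switched off."""
        return replace(self, sigma_f=0.0, seed=None)

    def control(self) -> "ClimateScenario":
        """The matching no-warming, no-fluctuation scenario (same T0, H)."""
        return replace(self, k=0.0, sigma_f=0.0, seed=None)

    def trend(self) -> np.ndarray:
        """Deterministic trend ``T0 + k t`` for t = 1..H."""
        return self.T0 + self.k * np.arange(1, self.H + 1, dtype=float)

    @property
    def total_warming(self) -> float:
        return self.k * self.H

    @property
    def mean_trend_temperature(self) -> float:
        """Mean of the trend over t = 1..H, i.e. ``T0 + k (H+1)/2``.

        Under constant thermal tolerance this is the thermal optimum of the
        best provenance.
        """
        return self.T0 + self.k * (self.H + 1) / 2.0


def temperature_series(
    scenario: ClimateScenario, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Generate the yearly temperature series ``T_1..T_H`` for a scenario.

    With ``sigma_f = 0`` the series is exactly the trend.  With
    ``sigma_f > 0`` each year's temperature is drawn independently from a
    normal distribution centred on the trend value with standard deviation
    ``sigma_f``.  The same seed always yields the identical series.
    """
    trend = scenario.trend()
    if scenario.sigma_f == 0:
        return trend
    if rng is None:
        if scenario.seed is None:
            raise ConfigurationError(
                "sigma_f > 0 requires a seed (or an explicit rng) for a reproducible series"
            )
        rng = np.random.default_rng(scenario.seed)
    return trend + rng.normal(0.0, scenario.sigma_f, size=scenario.H)
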