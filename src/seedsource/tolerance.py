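"""Thermal-tolerance ontogeny and cumulative (lifetime) tolerance.

Stage i survival declines as a Gaussian of the mismatch between the
provenance's thermal optimum and the yearly temperature, with width omega_i.
Across a whole life history the repeated Gaussian filters compose into a
single Gaussian whose squared width is the inverse of the sum of stage
durations over squared stage widths:

    omega_tot^2 = ( sum_i d_i / omega_i^2 )^-1

i.e. the harmonic mean of the squared yearly widths divided by the horizon.
With constant width omega this gives omega_tot = omega / sqrt(H).

Ontogeny is modelled as a linear trend in squared width,
``omega_i^2 = omega_1^2 (1 + b (i - 1))``; b > 0 makes older stages more
tolerant.  Holding the cumulative tolerance fixed while varying b requires
recalibrating omega_1 against a reference (typical) life history, which
:func:`calibrate_omega1` does in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InvalidScenarioError
from .life_cycle import LifeHistory, VitalRates

#: Cumulative-tolerance presets (degC) spanning narrow to wide climatic niches.
OMEGA_TOT_PRESETS = (2.0, 3.5, 5.0)


def ontogeny_b_from_ratio(ratio_last_first: float, n: int) -> float:
    """Slope b giving a last/first tolerance ratio ``omega_n/omega_1``.

    From ``omega_n^2 = omega_1^2 (1 + b (n - 1))``:
    ``b = (ratio^2 - 1) / (n - 1)``.  E.g. n = 5 and a ratio of 9 give b = 20.
    """
    if n < 2:
        raise InvalidScenarioError("ontogeny ratio needs at least two stages")
    if ratio_last_first <= 0:
        raise InvalidScenarioError("tolerance ratio must be positive")
    return (ratio_last_first**2 - 1.0) / (n - 1)


def _check_b(b: float, n: int) -> None:
    if n > 1 and b <= -1.0 / (n - 1):
        raise InvalidScenarioError(
            f"ontogeny slope b={b} makes stage-{n} squared tolerance non-positive"
        )


@dataclass(frozen=True)
class ToleranceProfile:
    """Per-stage tolerance widths with the linear ontogeny that generates them."""

    omega: np.ndarray
    omega1: float
    b: float

    def __post_init__(self) -> None:
        om = np.atleast_1d(np.asarray(self.omega, dtype=float))
        object.__setattr__(self, "omega", om)
        if np.any(om <= 0):
            raise InvalidScenarioError("tolerance widths must be positive")

    @property
    def n(self) -> int:
        return len(self.omega)

    @property
    def ratio_last_first(self) -> float:
        return float(self.omega[-1] / self.omega[0])

    @classmethod
    def from_b(cls, omega1: float, b: float, n: int) -> "ToleranceProfile":
        """Profile ``omega_i^2 = omega_1^2 (1 + b (i - 1))`` for i = 1..n."""
        if omega1 <= 0:
            raise InvalidScenarioError("omega1 must be positive")
        _check_b(b, n)
        i = np.arange(n)
        return cls(omega=omega1 * np.sqrt(1.0 + b * i), omega1=omega1, b=b)

    @classmethod
    def calibrated(
        cls,
        omega_tot: float,
        b: float,
        a: "LifeHistory | Sequence[int]",
        H: int,
    ) -> "ToleranceProfile":
        """Profile with slope b whose cumulative tolerance over the reference
        life history ``a`` equals ``omega_tot`` exactly."""
        ages = a.a if isinstance(a, LifeHistory) else tuple(a)
        n = len(ages) + 1
        omega1 = calibrate_omega1(omega_tot, b, LifeHistory(a=ages, H=H), H)
        return cls.from_b(omega1, b, n)

    @classmethod
    def calibrated_from_ratio(
        cls,
        omega_tot: float,
        ratio_last_first: float,
        a: "LifeHistory | Sequence[int]",
        H: int,
    ) -> "ToleranceProfile":
        ages = a.a if isinstance(a, LifeHistory) else tuple(a)
        return cls.calibrated(omega_tot, ontogeny_b_from_ratio(ratio_last_first, len(ages) + 1), ages, H)


def stage_durations(a: LifeHistory | Sequence[int], H: int) -> np.ndarray:
    """Years spent in each stage: d_1 = a_1, d_i = a_i - a_{i-1}, d_n = H - a_{n-1}.

    Durations sum to H; the final stage may have zero duration when the last
    transition happens in the harvest year itself.
    """
    ages = np.asarray(a.a if isinstance(a, LifeHistory) else a, dtype=int)
    edges = np.concatenate(([0], ages, [H]))
    d = np.diff(edges)
    if np.any(d[:-1] < 1) or d[-1] < 0:
        raise ValueError(f"invalid life history {tuple(ages)} for horizon H={H}")
    return d


def cumulative_tolerance(d: Sequence[float], omega: Sequence[float]) -> float:
    """Lifetime tolerance width omega_tot from stage durations and widths.

    ``omega_tot^2 = (sum_i d_i / omega_i^2)^-1``.
    """
    d = np.asarray(d, dtype=float)
    om = np.asarray(omega, dtype=float)
    if d.shape != om.shape:
        raise ValueError(f"durations {d.shape} and widths {om.shape} must align")
    denom = float(np.sum(d / om**2))
    if denom <= 0:
        raise ValueError("cumulative tolerance undefined: all stage durations are zero")
    return denom**-0.5


def calibrate_omega1(
    omega_tot_target: float, b: float, a: LifeHistory | Sequence[int], H: int
) -> float:
    """First-stage width making the cumulative tolerance hit a target.

    Substituting ``omega_i^2 = omega_1^2 (1 + b (i-1))`` into the cumulative
    tolerance and solving:  ``omega_1^2 = omega_tot^2 sum_i d_i / (1 + b (i-1))``.
    The round trip through :func:`cumulative_tolerance` is exact to machine
    precision.
    """
    if omega_tot_target <= 0:
        raise InvalidScenarioError("target cumulative tolerance must be positive")
    d = stage_durations(a, H)
    n = len(d)
    _check_b(b, n)
    i = np.arange(n)
    return float(omega_tot_target * np.sqrt(np.sum(d / (1.0 + b * i))))


def effective_cumulative_tolerance(
    vital: VitalRates,
    omega: Sequence[float] | ToleranceProfile,
    H: int,
    T0: float = 0.0,
    half_width_frac: float = 0.5,
    n_points: int = 101,
    cap: int = 2_000_000,
) -> float:
    """Realised lifetime tolerance of the stochastic-growth cohort.

    With stochastic stage transitions the expected harvest is a mixture of
    Gaussians in the provenance optimum theta, one per life history, so the
    realised tolerance can differ from the theoretical cumulative tolerance
    computed on the typical life history (which ignores survivorship).  This
    diagnostic measures the width of the best local Gaussian description:
    under a constant climate at T0 it fits a quadratic to log E[N_H](theta)
    on a grid around the optimum and returns ``sqrt(-1 / (2 c2))`` where c2
    is the fitted curvature.

    With a single feasible life history (g_i = 1 everywhere) this equals the
    theoretical cumulative tolerance exactly (up to the fit's conditioning).
    """
    from .analytic import expected_harvest  # local import to avoid a cycle

    om = omega.omega if isinstance(omega, ToleranceProfile) else np.asarray(omega, dtype=float)
    series = np.full(H, float(T0))
    # under a constant climate every history's Gaussian is centred at T0
    scale = cumulative_tolerance(np.full(len(om), H / len(om)), om)
    thetas = T0 + np.linspace(-half_width_frac, half_width_frac, n_points) * scale
    vals = expected_harvest(thetas, 1.0, vital, om, series, cap=cap)
    if np.any(vals <= 0):
        raise ValueError("expected harvest vanished on the fit grid; narrow the window")
    c2 = np.polyfit(thetas - T0, np.log(vals), 2)[0]
    if c2 >= 0:
        raise ValueError("log-harvest not concave around the optimum; cannot fit a width")
    return float(np.sqrt(-1.0 / (2.0 * c2)))
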