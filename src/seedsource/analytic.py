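"""Closed-form expected harvest.

For a cohort whose members all share a life history ``a`` (fixed transition
ages), the product of yearly Gaussian survivals collapses into a single
Gaussian in the provenance optimum theta:

    E[N_H | a] = N0 s_tot,max(a) exp( -(theta - T_tot(a))^2 / (2 omega_tot(a)^2) )

where omega_tot is the cumulative tolerance (inverse-sum of stage durations
over squared widths), T_tot is the yearly temperature averaged with weights
``omega_tot^2 / omega_i(t)^2`` (which sum to one), and s_tot,max is the
survival-to-harvest probability of a perfectly tracking provenance.  With
stochastic stage transitions the expectation is the probability-weighted sum
over all life histories, which matches the year-by-year matrix projection
exactly.

A variable cohort whose optima are Gaussian around theta_bar with standard
deviation sigma_p convolves two Gaussians, widening the tolerance to
``sqrt(omega_tot^2 + sigma_p^2)`` and shrinking the peak by
``omega_tot / sqrt(omega_tot^2 + sigma_p^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .life_cycle import (
    LifeHistory,
    VitalRates,
    enumerate_life_histories,
)
from .tolerance import ToleranceProfile, cumulative_tolerance, stage_durations


def _widths(omega) -> np.ndarray:
    return omega.omega if isinstance(omega, ToleranceProfile) else np.asarray(omega, dtype=float)


def _ages(a) -> tuple[int, ...]:
    return a.a if isinstance(a, LifeHistory) else tuple(int(x) for x in a)


def year_widths(d: Sequence[int], omega) -> np.ndarray:
    """Tolerance width experienced in each year of the rotation."""
    return np.repeat(_widths(omega), np.asarray(d, dtype=int))


def weighted_lifetime_temperature(d: Sequence[int], omega, series) -> float:
    """Tolerance-weighted lifetime temperature T_tot.

    Yearly temperatures weighted by ``omega_tot^2 / omega_i(t)^2``; the
    weights sum to one exactly, so with constant widths T_tot is the plain
    arithmetic mean of the series.  T_tot is the thermal optimum of the best
    provenance for this fixed life history.
    """
    series = np.asarray(series, dtype=float)
    om_year = year_widths(d, omega)
    if len(om_year) != len(series):
        raise ValueError(
            f"durations cover {len(om_year)} years but the series has {len(series)}"
        )
    inv = 1.0 / om_year**2
    w = inv / inv.sum()
    return float(w @ series)


@dataclass(frozen=True)
class FixedHistorySummary:
    """Gaussian summary of expected harvest for one fixed life history."""

    omega_tot: float
    T_tot: float
    log_s_tot_max: float

    @property
    def s_tot_max(self) -> float:
        """Maximal survival-to-harvest probability (harvest at theta = T_tot, N0 = 1)."""
        return float(np.exp(self.log_s_tot_max))

    def harvest(self, theta, N0: float = 1.0):
        """Expected harvest E[N_H | a] as a function of the provenance optimum."""
        theta = np.asarray(theta, dtype=float)
        out = N0 * np.exp(
            self.log_s_tot_max - (theta - self.T_tot) ** 2 / (2.0 * self.omega_tot**2)
        )
        return float(out) if out.ndim == 0 else out


def fixed_history_summary(
    vital: VitalRates, a, omega, series
) -> FixedHistorySummary:
    """Compute (omega_tot, T_tot, s_tot,max) for a fixed life history.

    ``s_tot,max = prod_i s_i,max^d_i *
    exp(T_tot^2/(2 omega_tot^2) - sum_t T_t^2/(2 omega_i(t)^2))``; it equals
    the expected harvest per seedling evaluated at theta = T_tot.  Computed
    in log space for numerical safety.
    """
    series = np.asarray(series, dtype=float)
    H = len(series)
    ages = _ages(a)
    d = stage_durations(ages, H)
    om = _widths(omega)
    om_year = year_widths(d, om)
    inv = 1.0 / om_year**2
    omega_tot = float(inv.sum() ** -0.5)
    w = inv * omega_tot**2
    T_tot = float(w @ series)
    log_s = float(
        d @ np.log(vital.s_max)
        + T_tot**2 / (2.0 * omega_tot**2)
        - 0.5 * (series**2 * inv).sum()
    )
    return FixedHistorySummary(omega_tot=omega_tot, T_tot=T_tot, log_s_tot_max=log_s)


def max_total_survival(vital: VitalRates, a, omega, series) -> float:
    """Maximal survival-to-harvest probability s_tot,max for a fixed history."""
    return fixed_history_summary(vital, a, omega, series).s_tot_max


def expected_harvest_fixed(theta, N0: float, vital: VitalRates, a, omega, series):
    """Closed-form expected harvest for a cohort with one fixed life history."""
    return fixed_history_summary(vital, a, omega, series).harvest(theta, N0)


def yearly_survival_product(theta, N0: float, vital: VitalRates, a, omega, series):
    """Expected harvest as the direct product of yearly stage survivals.

    The defining product form; the closed-form Gaussian summary is its exact
    reorganisation and the two agree to machine precision.  Kept as an
    independent route for validation.
    """
    series = np.asarray(series, dtype=float)
    d = stage_durations(_ages(a), len(series))
    om_year = year_widths(d, _widths(omega))
    smax_year = np.repeat(vital.s_max, d)
    theta = np.asarray(theta, dtype=float)
    mism = (theta[..., None] - series) ** 2 / (2.0 * om_year**2)
    log_p = np.sum(np.log(smax_year) - mism, axis=-1)
    out = N0 * np.exp(log_p)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class HistoryEnsemble:
    """Per-life-history Gaussian summaries for a vital-rate/climate pairing.

    Precomputing these once makes grid searches over the provenance optimum
    cheap: the expected harvest is a probability-weighted mixture of
    Gaussians in theta.
    """

    p: np.ndarray
    omega_tot: np.ndarray
    T_tot: np.ndarray
    log_s_tot_max: np.ndarray
    ages: np.ndarray  # (histories, n-1) transition ages

    def expected_harvest(self, theta, N0: float = 1.0):
        theta = np.asarray(theta, dtype=float)
        z = (theta[..., None] - self.T_tot) ** 2 / (2.0 * self.omega_tot**2)
        out = N0 * np.sum(self.p * np.exp(self.log_s_tot_max - z), axis=-1)
        return float(out) if out.ndim == 0 else out


def history_ensemble(
    vital: VitalRates, omega, series, cap: int = 2_000_000
) -> HistoryEnsemble:
    """Summaries for every life history completing by harvest."""
    series = np.asarray(series, dtype=float)
    H = len(series)
    ps, oms, Ts, logs, ages = [], [], [], [], []
    om = _widths(omega)
    for lh, p in enumerate_life_histories(vital.g, vital.n, H, cap=cap):
        summ = fixed_history_summary(vital, lh, om, series)
        ps.append(p)
        oms.append(summ.omega_tot)
        Ts.append(summ.T_tot)
        logs.append(summ.log_s_tot_max)
        ages.append(lh.a)
    return HistoryEnsemble(
        p=np.asarray(ps),
        omega_tot=np.asarray(oms),
        T_tot=np.asarray(Ts),
        log_s_tot_max=np.asarray(logs),
        ages=np.asarray(ages, dtype=int),
    )


def expected_harvest(
    theta, N0: float, vital: VitalRates, omega, series, cap: int = 2_000_000
):
    """Expected harvest summed over all possible life histories.

    ``E[N_H] = sum_a p(a) E[N_H | a]``.  Agrees with the year-by-year matrix
    projection to numerical precision.  Raises
    :class:`~seedsource.errors.EnumerationCapError` when the number of life
    histories exceeds ``cap``; use the cohort simulator then.
    """
    if vital.n == 1:
        series = np.asarray(series, dtype=float)
        return expected_harvest_fixed(theta, N0, vital, (), omega, series)
    return history_ensemble(vital, omega, series, cap=cap).expected_harvest(theta, N0)


def mixture_expected_harvest(
    theta_mean: float,
    sigma_p: float,
    N0: float,
    vital: VitalRates,
    a,
    omega,
    series,
):
    """Expected harvest of a variable cohort (Gaussian spread of optima).

    Integrating the fixed-history Gaussian harvest over a Gaussian
    distribution of theta (mean ``theta_mean``, sd ``sigma_p``) gives

        N0 s_tot,max * omega_tot / sqrt(omega_tot^2 + sigma_p^2)
           * exp( -(theta_mean - T_tot)^2 / (2 (omega_tot^2 + sigma_p^2)) )

    With sigma_p = 0 this is the homogeneous-cohort harvest.  Spreading the
    cohort lowers the peak but fattens the tails: it costs survivors when the
    mean optimum is well chosen and saves them when it is badly wrong.
    """
    if sigma_p < 0:
        raise ValueError("sigma_p must be >= 0")
    summ = fixed_history_summary(vital, a, omega, series)
    var = summ.omega_tot**2 + sigma_p**2
    theta_mean = np.asarray(theta_mean, dtype=float)
    out = (
        N0
        * np.exp(summ.log_s_tot_max - (theta_mean - summ.T_tot) ** 2 / (2.0 * var))
        * summ.omega_tot
        / np.sqrt(var)
    )
    return float(out) if out.ndim == 0 else out
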