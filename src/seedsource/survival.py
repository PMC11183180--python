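"""Gaussian climate-dependent survival and the yearly projection matrix.

Annual survival in stage i is a Gaussian function of the mismatch between
the provenance's thermal optimum theta and the yearly mean temperature T:

    s_i(theta, T) = s_i,max exp( -(theta - T)^2 / (2 omega_i^2) )

so survival is maximal when the year matches the optimum and drops by a
factor 1 - e^(-1/2) (about 40%) at one tolerance width of mismatch.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import InvalidScenarioError
from .life_cycle import StageMatrix, VitalRates
from .tolerance import ToleranceProfile


def stage_survival(theta, T, s_max, omega):
    """Annual survival probability under thermal mismatch.

    Vectorised over any broadcastable combination of arguments.  ``omega``
    must be positive.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise InvalidScenarioError("tolerance width omega must be positive")
    theta = np.asarray(theta, dtype=float)
    T = np.asarray(T, dtype=float)
    s_max = np.asarray(s_max, dtype=float)
    out = s_max * np.exp(-((theta - T) ** 2) / (2.0 * omega**2))
    return float(out) if out.ndim == 0 else out


def _widths(omega: Sequence[float] | ToleranceProfile) -> np.ndarray:
    return omega.omega if isinstance(omega, ToleranceProfile) else np.asarray(omega, dtype=float)


def projection_matrix(
    theta: float,
    T: float,
    vital: VitalRates,
    omega: Sequence[float] | ToleranceProfile,
    growth_climate: bool = False,
) -> StageMatrix:
    """Yearly transition matrix for a provenance at temperature T.

    Entry (i, i) is survive-and-stay ``s_i(theta,T) (1 - g_i)``, entry
    (i+1, i) is survive-and-grow ``s_i(theta,T) g_i``, and the last stage is
    absorbing with survival ``s_n(theta,T)``.  At ``theta = T`` this is
    exactly the matrix rebuilt from the maximal vital rates.

    With ``growth_climate`` on, the conditional growth probability is also
    penalised by the same per-stage Gaussian factor (a model variant where
    both growth and survival respond to temperature).
    """
    om = _widths(omega)
    n = vital.n
    if len(om) != n:
        raise InvalidScenarioError(f"{n} stages need {n} tolerance widths, got {len(om)}")
    s = stage_survival(theta, T, vital.s_max, om)
    s = np.atleast_1d(s)
    g = vital.g.copy()
    if growth_climate and n > 1:
        g = g * np.exp(-((theta - T) ** 2) / (2.0 * om[:-1] ** 2))
    U = np.zeros((n, n))
    for i in range(n - 1):
        U[i, i] = s[i] * (1 - g[i])
        U[i + 1, i] = s[i] * g[i]
    U[n - 1, n - 1] = s[n - 1]
    return StageMatrix(U)
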