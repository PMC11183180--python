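"""Deterministic-expectation cohort projection.

Iterates the climate-dependent projection matrix over a yearly temperature
series, ``N_{t+1} = M(theta, T_{t+1}) N_t``, and reports the expected number
of individuals in the last stage at harvest.  Abundances are expectations
(real-valued), not individual-based realisations; with N0 normalised to one
seedling the harvest reads as a per-seedling survival-to-harvest
probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .life_cycle import VitalRates
from .survival import projection_matrix
from .tolerance import ToleranceProfile


@dataclass(frozen=True)
class CohortTrajectory:
    """Expected stage abundances year by year; row t is the census at year t."""

    N: np.ndarray  # (H+1, n)

    @property
    def H(self) -> int:
        return self.N.shape[0] - 1

    @property
    def n(self) -> int:
        return self.N.shape[1]

    @property
    def harvest(self) -> float:
        """Expected count in the last stage at harvest."""
        return float(self.N[-1, -1])

    @property
    def total(self) -> np.ndarray:
        """Total expected abundance per year (non-increasing: no reproduction)."""
        return self.N.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (year, stage, expected abundance) for export."""
        H, n = self.H, self.n
        years = np.repeat(np.arange(H + 1), n)
        stages = np.tile(np.arange(1, n + 1), H + 1)
        return pd.DataFrame(
            {"year": years, "stage": stages, "expected_abundance": self.N.ravel()}
        )


def project_cohort(
    N0: Sequence[float] | float,
    theta: float,
    vital: VitalRates,
    omega: Sequence[float] | ToleranceProfile,
    series: Sequence[float],
    growth_climate: bool = False,
) -> CohortTrajectory:
    """Project a planted cohort through the rotation.

    ``N0`` is the initial stage vector; a scalar puts all mass in stage 1
    (a planted seedling cohort).  ``series`` holds the yearly temperatures
    T_1..T_H experienced after planting.
    """
    n = vital.n
    if np.isscalar(N0):
        N = np.zeros(n)
        N[0] = float(N0)
    else:
        N = np.asarray(N0, dtype=float).copy()
        if N.shape != (n,):
            raise ValueError(f"initial vector has shape {N.shape}, expected ({n},)")
    if np.any(N < 0):
        raise ValueError("initial abundances must be non-negative")
    series = np.asarray(series, dtype=float)
    out = np.empty((len(series) + 1, n))
    out[0] = N
    for t, T in enumerate(series):
        M = projection_matrix(theta, T, vital, omega, growth_climate=growth_climate)
        N = M.U @ N
        out[t + 1] = N
    return CohortTrajectory(N=out)
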