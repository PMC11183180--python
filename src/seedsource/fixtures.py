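"""Synthetic life cycles and packaged reference parameter sets.

Everything here is generated programmatically, so every other module can be
exercised without external demographic data.  The synthetic matrices obey
the model's structural assumptions exactly (stasis plus one-step growth, no
retrogression, no stage skipping) and pass strict conformance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigurationError, SpeciesExcludedError
from .life_cycle import (
    StageMatrix,
    VitalRates,
    rebuild,
    typical_life_history_from_rates,
    write_matrix_csv,
)


def figure2_fixture() -> tuple[VitalRates, dict]:
    """Reference two-stage life cycle (juveniles and adults).

    Maximal annual survivals 0.61 (juvenile) and 0.98 (adult) with a 0.012
    conditional growth probability, a slow-maturing long-lived tree whose
    typical age of maturation is 3 years.  Defaults bundle the standard
    60-year rotation (plus a 100-year variant) and the intermediate
    cumulative-tolerance preset.
    """
    vital = VitalRates(s_max=np.array([0.61, 0.98]), g=np.array([0.012]))
    defaults = {"H": 60, "H_long": 100, "omega_tot": 3.5, "T0": 0.0}
    return vital, defaults


@dataclass(frozen=True)
class FixtureSpec:
    """Sampling recipe for random ladder life cycles."""

    n: int = 2
    H: int = 60
    survival_bounds: tuple[float, float] = (0.01, 0.99)
    growth_bounds: tuple[float, float] = (0.01, 0.99)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigurationError("life cycles need at least two stages")
        lo, hi = self.survival_bounds
        glo, ghi = self.growth_bounds
        if not (0 < lo < hi <= 1) or not (0 < glo < ghi <= 1):
            raise ConfigurationError("bounds must satisfy 0 < lo < hi <= 1")


def random_life_cycles(spec: FixtureSpec, count: int) -> list[VitalRates]:
    """Draw random vital-rate sets with uniform survivals and growths.

    For more than two stages, draws whose typical life history fails to
    reach the last stage by the horizon are rejected and redrawn, mirroring
    the species filter a harvest-time analysis requires.  Reproducible under
    the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[VitalRates] = []
    attempts = 0
    max_attempts = max(100 * count, 1000)
    while len(out) < count:
        if attempts >= max_attempts:
            raise ConfigurationError(
                f"rejection rate above 99%: only {len(out)}/{count} life cycles "
                f"reached stage {spec.n} by H={spec.H}"
            )
        attempts += 1
        s = rng.uniform(*spec.survival_bounds, size=spec.n)
        g = rng.uniform(*spec.growth_bounds, size=spec.n - 1)
        vital = VitalRates(s_max=s, g=g)
        if spec.n > 2:
            try:
                typical_life_history_from_rates(vital, spec.H)
            except SpeciesExcludedError:
                continue
        out.append(vital)
    return out


def species_like_matrix(
    n: int,
    target_first_stage_duration: float,
    seed: Optional[int] = None,
) -> StageMatrix:
    """Conformant matrix whose typical first-stage duration hits a target.

    Emulates the range of real tree life cycles, from matrices whose first
    stage (seeds/seedlings) lasts a single year to ones where trees linger
    in the first stage for a decade or more.  The first-stage stasis is set
    so the expected sojourn ``1 / (1 - s_1 (1 - g_1))`` matches the target;
    later stages get moderate seeded jitter.
    """
    if n < 2:
        raise ConfigurationError("need at least two stages")
    if target_first_stage_duration < 1:
        raise ConfigurationError("first-stage duration cannot be below one year")
    rng = np.random.default_rng(seed)
    s = rng.uniform(0.85, 0.98, size=n)
    g = rng.uniform(0.1, 0.4, size=n - 1)
    # solve s_1 (1 - g_1) = 1 - 1/target for the first-stage sojourn
    stasis1 = 1.0 - 1.0 / target_first_stage_duration
    if stasis1 >= s[0]:
        s[0] = min(0.995, (1.0 + stasis1) / 2.0)
        if stasis1 >= s[0]:
            raise ConfigurationError(
                f"first-stage duration {target_first_stage_duration} unreachable "
                "with survival below one"
            )
    g[0] = 1.0 - stasis1 / s[0]
    M = rebuild(VitalRates(s_max=s, g=g))
    return M


def write_fixture_set(
    directory: str | Path,
    n: int = 5,
    durations: tuple[int, ...] = (1, 3, 5, 10, 15),
    seed: int = 0,
) -> list[Path]:
    """Write a set of species-like matrices as header-less CSVs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, dur in enumerate(durations):
        M = species_like_matrix(n, dur, seed=seed + i)
        path = directory / f"species_like_n{n}_d{dur}.csv"
        write_matrix_csv(M, path)
        paths.append(path)
    return paths
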