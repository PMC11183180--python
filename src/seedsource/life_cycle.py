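"""Stage-structured life cycles.

The cohort model assumes a ladder life cycle: each year an individual in
stage i survives with probability s_i and, conditional on surviving, either
stays (probability 1 - g_i) or advances to stage i+1 (probability g_i).
Trees neither shrink nor skip stages, so a conformant annual transition
matrix U (columns = current stage, rows = next-year stage) has mass only on
the diagonal (stasis) and the first subdiagonal (one-step growth); the
column-sum deficit is mortality.

This module decomposes empirical matrices into maximal vital rates
(s_i,max, g_i), computes fundamental-matrix occupancy times and the typical
life history, and enumerates stochastic life histories with their
probabilities under the growth process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import (
    ConformanceError,
    EnumerationCapError,
    ImmortalLifeCycleError,
    InvalidMatrixError,
    SpeciesExcludedError,
)

_ATOL = 1e-9


@dataclass(frozen=True)
class StageMatrix:
    """Survival/growth transition matrix of a ladder life cycle.

    ``U[i, j]`` is the probability that a stage-j individual is in stage i
    next year.  Entries lie in [0, 1] and columns sum to at most 1; the
    deficit is annual mortality.  Reproduction is not part of U: the model
    tracks a single non-reproducing cohort.
    """

    U: np.ndarray

    def __post_init__(self) -> None:
        U = np.asarray(self.U, dtype=float)
        object.__setattr__(self, "U", U)
        if U.ndim != 2 or U.shape[0] != U.shape[1]:
            raise InvalidMatrixError(f"transition matrix must be square, got shape {U.shape}")
        if U.shape[0] < 1:
            raise InvalidMatrixError("transition matrix must have at least one stage")
        if np.any(U < -_ATOL) or np.any(U > 1 + _ATOL):
            raise InvalidMatrixError("transition probabilities must lie in [0, 1]")
        colsums = U.sum(axis=0)
        if np.any(colsums > 1 + _ATOL):
            bad = int(np.argmax(colsums))
            raise InvalidMatrixError(
                f"column {bad + 1} sums to {colsums[bad]:.6g} > 1 (not a survival matrix)"
            )

    @property
    def n(self) -> int:
        return self.U.shape[0]

    def is_conformant(self, tol: float = 0.0) -> bool:
        """True if mass sits only on the diagonal and first subdiagonal."""
        off = self.U.copy()
        n = self.n
        idx = np.arange(n)
        off[idx, idx] = 0.0
        off[idx[1:], idx[:-1]] = 0.0
        return bool(np.all(np.abs(off) <= tol + _ATOL))


@dataclass(frozen=True)
class VitalRates:
    """Per-stage maximal vital rates of a ladder life cycle.

    ``s_max[i]`` is the annual survival probability of stage i+1 when the
    climate matches the thermal optimum; ``g[i]`` is the probability of
    advancing to the next stage conditional on survival (the last stage is
    absorbing, g_n = 0).
    """

    s_max: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        s = np.atleast_1d(np.asarray(self.s_max, dtype=float))
        g = np.atleast_1d(np.asarray(self.g, dtype=float)) if np.size(self.g) else np.empty(0)
        object.__setattr__(self, "s_max", s)
        object.__setattr__(self, "g", g)
        if len(g) != len(s) - 1:
            raise InvalidMatrixError(
                f"need n-1 growth probabilities for n={len(s)} stages, got {len(g)}"
            )
        if np.any(s <= 0) or np.any(s > 1 + _ATOL):
            raise InvalidMatrixError("survival probabilities must lie in (0, 1]")
        if len(g) and (np.any(g < 0) or np.any(g > 1 + _ATOL)):
            raise InvalidMatrixError("growth probabilities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.s_max)


@dataclass(frozen=True)
class LifeHistory:
    """Ages of transition between successive stages.

    ``a[i]`` is the year in which the individual moves from stage i+1 to
    stage i+2; ages are strictly increasing, at least one stage per year
    (a_i >= i+1), and the last transition occurs by harvest (a_{n-1} <= H).
    """

    a: tuple[int, ...]
    H: int

    def __post_init__(self) -> None:
        a = tuple(int(x) for x in self.a)
        object.__setattr__(self, "a", a)
        for i, ai in enumerate(a):
            if ai < i + 1:
                raise InvalidMatrixError(f"transition age a_{i+1}={ai} faster than one stage/year")
            if i and ai <= a[i - 1]:
                raise InvalidMatrixError(f"transition ages must strictly increase, got {a}")
        if a and a[-1] > self.H:
            raise SpeciesExcludedError(
                f"last transition at year {a[-1]} is after harvest H={self.H}"
            )

    @property
    def n(self) -> int:
        return len(self.a) + 1


@dataclass
class ConformanceReport:
    """Mass removed from a raw matrix to make it conformant."""

    removed: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def removed_per_column(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for (_, j), v in self.removed.items():
            out[j] = out.get(j, 0.0) + v
        return out

    @property
    def total_removed(self) -> float:
        return float(sum(self.removed.values()))

    def summary(self) -> str:
        if not self.removed:
            return "conformant: no mass removed"
        lines = [f"removed {self.total_removed:.6g} total non-conforming mass:"]
        for (i, j), v in sorted(self.removed.items()):
            lines.append(f"  entry ({i + 1},{j + 1}): {v:.6g}")
        return "\n".join(lines)


def enforce_conformance(
    raw: Sequence[Sequence[float]] | np.ndarray,
    policy: str = "drop",
    tol: float = 0.0,
) -> tuple[StageMatrix, ConformanceReport]:
    """Coerce a raw square table to the stasis + one-step-growth pattern.

    Raw tables from demographic databases may carry fecundities (row 1),
    retrogression (above-diagonal mass) or stage skips.  Policy ``"drop"``
    zeroes every non-conforming entry and records the removed mass per entry;
    the dropped mass becomes additional mortality (survival is re-derived
    from what remains, never renormalised).  Policy ``"strict"`` raises if
    any non-conforming entry exceeds ``tol``.
    """
    A = np.asarray(raw, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidMatrixError(f"expected a square table, got shape {A.shape}")
    n = A.shape[0]
    mask = np.zeros_like(A, dtype=bool)
    idx = np.arange(n)
    mask[idx, idx] = True
    mask[idx[1:], idx[:-1]] = True
    offenders = (~mask) & (np.abs(A) > tol)
    report = ConformanceReport()
    if policy == "strict":
        if offenders.any():
            i, j = map(int, np.argwhere(offenders)[0])
            raise ConformanceError(
                f"non-conforming entry {A[i, j]:.6g} at ({i + 1},{j + 1}) under strict policy"
            )
        cleaned = np.where(mask, A, 0.0)
    elif policy == "drop":
        cleaned = np.where(mask, A, 0.0)
        for i, j in np.argwhere((~mask) & (A != 0)):
            report.removed[(int(i), int(j))] = float(A[i, j])
    else:
        raise ValueError(f"unknown conformance policy {policy!r}")
    return StageMatrix(cleaned), report


def decompose(M: StageMatrix) -> VitalRates:
    """Extract maximal vital rates from a conformant matrix.

    Assuming the empirical matrix was measured at the population's thermal
    optimum, ``s_i,max = U[i,i] + U[i+1,i]`` (last stage: ``U[n,n]``) and
    ``g_i = U[i+1,i] / s_i,max``.
    """
    if not M.is_conformant():
        raise ConformanceError(
            "matrix has mass outside stasis/one-step growth; run enforce_conformance first"
        )
    U = M.U
    n = M.n
    s = np.empty(n)
    g = np.empty(max(n - 1, 0))
    for i in range(n - 1):
        s[i] = U[i, i] + U[i + 1, i]
        if s[i] <= 0:
            raise InvalidMatrixError(f"stage {i + 1} has zero survival; vital rates undefined")
        g[i] = U[i + 1, i] / s[i]
    s[n - 1] = U[n - 1, n - 1]
    if s[n - 1] <= 0:
        raise InvalidMatrixError(f"stage {n} has zero survival; vital rates undefined")
    return VitalRates(s_max=s, g=g)


def rebuild(vital: VitalRates) -> StageMatrix:
    """Transition matrix at the thermal optimum from vital rates.

    Exact inverse of :func:`decompose` on conformant matrices.
    """
    n = vital.n
    U = np.zeros((n, n))
    for i in range(n - 1):
        U[i, i] = vital.s_max[i] * (1 - vital.g[i])
        U[i + 1, i] = vital.s_max[i] * vital.g[i]
    U[n - 1, n - 1] = vital.s_max[n - 1]
    return StageMatrix(U)


def fundamental_matrix(M: StageMatrix) -> np.ndarray:
    """Fundamental matrix ``F = (I - U)^-1``.

    ``F[i, j]`` is the expected number of years an individual currently in
    stage j+1 will spend in stage i+1 before dying.  Requires every stage to
    carry some mortality risk (spectral radius of U below 1).
    """
    U = M.U
    eigvals = np.linalg.eigvals(U)
    if np.max(np.abs(eigvals)) >= 1 - 1e-12:
        raise ImmortalLifeCycleError(
            "I - U is singular: some stage is immortal and occupancy times diverge"
        )
    return np.linalg.inv(np.eye(M.n) - U)


def expected_stage_durations(vital: VitalRates) -> np.ndarray:
    """Expected years spent in each stage by an individual starting in stage 1.

    Closed form for the ladder chain: the expected time in stage i is the
    probability of ever reaching stage i times the expected sojourn there,
    ``prod_{m<i} [s_m g_m / (1 - s_m (1 - g_m))] / (1 - s_i (1 - g_i))``.
    Unlike the fundamental matrix this remains defined for stages without
    mortality in the final (absorbing) stage, whose duration is reported as
    ``inf`` when s_n = 1.
    """
    n = vital.n
    s, g = vital.s_max, vital.g
    out = np.empty(n)
    reach = 1.0
    for i in range(n):
        stasis = s[i] * (1 - g[i]) if i < n - 1 else s[i]
        sojourn = math.inf if stasis >= 1 else 1.0 / (1.0 - stasis)
        out[i] = reach * sojourn
        if i < n - 1:
            advance = s[i] * g[i]
            reach *= 0.0 if sojourn == math.inf else advance * sojourn
    return out


def _ages_from_partial_sums(partial: np.ndarray, H: int) -> LifeHistory:
    ages: list[int] = []
    for i, x in enumerate(partial):
        a_i = math.ceil(x - 1e-9)
        if ages and a_i <= ages[-1]:
            a_i = ages[-1] + 1
        ages.append(a_i)
    if ages and ages[-1] > H:
        raise SpeciesExcludedError(
            f"typical life history reaches the last stage at year {ages[-1]} > H={H}; "
            "the species does not mature within the rotation"
        )
    return LifeHistory(a=tuple(ages), H=H)


def typical_life_history(F: np.ndarray, H: int) -> LifeHistory:
    """Typical ages of stage transition from the fundamental matrix.

    The expected age of transition from stage i to i+1 is the expected total
    time spent in stages 1..i by an individual starting in stage 1, i.e. the
    partial sums of the first column of F, rounded up to the next integer.
    Rounding ties that would break strict increase are bumped up by one year.
    """
    F = np.asarray(F, dtype=float)
    partial = np.cumsum(F[:, 0])[:-1]
    return _ages_from_partial_sums(partial, H)


def typical_life_history_from_rates(vital: VitalRates, H: int) -> LifeHistory:
    """Typical life history straight from vital rates (handles s_n = 1)."""
    partial = np.cumsum(expected_stage_durations(vital)[:-1])
    return _ages_from_partial_sums(partial, H)


def life_history_probability(a: LifeHistory | Sequence[int], g: Sequence[float]) -> float:
    """Probability of a life history under the growth process.

    ``p(a) = prod_i (1 - g_i)^(a_i - a_{i-1} - 1) g_i`` with a_0 = 0: in each
    stage the individual fails to advance for the first d_i - 1 years and
    advances in the last, independently across stages (survival aside).
    """
    ages = a.a if isinstance(a, LifeHistory) else tuple(int(x) for x in a)
    g = np.atleast_1d(np.asarray(g, dtype=float))
    if len(ages) != len(g):
        raise ValueError(f"life history with {len(ages)} transitions needs {len(ages)} g values")
    p = 1.0
    prev = 0
    for ai, gi in zip(ages, g):
        p *= (1.0 - gi) ** (ai - prev - 1) * gi
        prev = ai
    return float(p)


def count_life_histories(n: int, H: int) -> int:
    """Number of strictly increasing transition-age vectors: C(H, n-1)."""
    return math.comb(H, n - 1)


def enumerate_life_histories(
    g: Sequence[float],
    n: int,
    H: int,
    cap: int = 2_000_000,
    include_zero: bool = False,
) -> Iterator[tuple[LifeHistory, float]]:
    """Yield every life history completing n-1 transitions by year H.

    Yields ``(LifeHistory, probability)`` pairs; the probabilities sum to the
    probability that the growth process completes all transitions by year H
    (generally < 1).  Histories with probability zero (a forced transition
    that the rates make impossible) are skipped unless ``include_zero``.

    Raises :class:`EnumerationCapError` when C(H, n-1) exceeds ``cap``;
    callers should fall back to the cohort simulator in that case.
    """
    if n < 2:
        raise ValueError("enumeration needs at least two stages")
    if H < n - 1:
        raise SpeciesExcludedError(f"H={H} too short for {n - 1} transitions")
    total = count_life_histories(n, H)
    if total > cap:
        raise EnumerationCapError(
            f"C({H},{n - 1}) = {total} life histories exceeds cap {cap}; "
            "use the cohort simulator (seedsource.cohort.project_cohort)"
        )
    for ages in combinations(range(1, H + 1), n - 1):
        lh = LifeHistory(a=ages, H=H)
        p = life_history_probability(lh, g)
        if p > 0 or include_zero:
            yield lh, p


def read_matrix_csv(path) -> np.ndarray:
    """Read a raw square matrix from header-less CSV (one row per line)."""
    A = np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))
    if A.shape[0] != A.shape[1]:
        raise InvalidMatrixError(f"{path}: expected a square matrix, got shape {A.shape}")
    return A


def write_matrix_csv(M: StageMatrix | np.ndarray, path) -> None:
    """Write a matrix as header-less CSV, stages ordered young to old."""
    U = M.U if isinstance(M, StageMatrix) else np.asarray(M, dtype=float)
    np.savetxt(path, U, delimiter=",", fmt="%.17g")
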