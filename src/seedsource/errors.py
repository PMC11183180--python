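"""Exception hierarchy shared across the package."""


class SeedsourceError(Exception):
    """Base class for all package-specific errors."""


class InvalidScenarioError(SeedsourceError, ValueError):
    """A climate scenario violates its invariants (e.g. non-positive horizon)."""


class ConfigurationError(SeedsourceError, ValueError):
    """A run configuration is incomplete or inconsistent (e.g. stochastic
    fluctuations requested without a seed in a reproducible context)."""


class ConformanceError(SeedsourceError, ValueError):
    """A transition matrix has mass outside the stasis/one-step-growth
    pattern and the strict policy is in force."""


class InvalidMatrixError(SeedsourceError, ValueError):
    """A transition matrix violates probabilistic constraints (entries outside
    [0, 1], column sums above one, zero survival with nonzero growth...)."""


class ImmortalLifeCycleError(InvalidMatrixError):
    """(I - U) is singular: some stage has no mortality, so expected
    occupancy times diverge."""


class SpeciesExcludedError(SeedsourceError, ValueError):
    """The typical life history does not reach the last stage by harvest,
    so the life cycle is outside the model's domain for this rotation."""


class EnumerationCapError(SeedsourceError, RuntimeError):
    """Exhaustive life-history enumeration would exceed the configured cap;
    use the cohort simulator instead."""
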