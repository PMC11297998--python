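"""Exception types shared across the package."""


class GroupHawkError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GroupHawkError, ValueError):
    """A model or simulation configuration violates its invariants."""


class DegenerateDivisionError(GroupHawkError, ZeroDivisionError):
    """A sharing rule puts zero cost on one class (d_c in {0, 1}), so the
    class preference V_i/C_i is undefined."""


class UndefinedDecisionError(GroupHawkError, ZeroDivisionError):
    """Total decision influence is zero (epsilon = 0 and omega = 0)."""


class InvalidPerturbationError(GroupHawkError, ValueError):
    """An analytically derived probability left [0, 1] by more than
    round-off; indicates a mis-wired call, not legitimate input."""


class DegenerateRegimeError(GroupHawkError, ValueError):
    """Leader and follower preferences coincide; the regime thresholds and
    class equilibrium strategies are undefined (a continuum of equilibria
    shares the same collective probability)."""
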