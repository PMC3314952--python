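"""Exception hierarchy.

All package-specific failures derive from :class:`CoiltoolsError` so callers can
catch one base class at pipeline level; user-input problems are distinguished from
numerical/internal ones by the subclasses below.
"""


class CoiltoolsError(Exception):
    """Base class for all coiltools errors."""


class SequenceError(CoiltoolsError):
    """Invalid residue codes, empty records or bad numbering."""


class PropertyTableError(CoiltoolsError):
    """Missing or invalid entries in a residue property table."""


class RegionError(CoiltoolsError):
    """Overlapping, reversed or out-of-range residue intervals."""


class InsufficientDataError(CoiltoolsError):
    """Not enough observations to run the requested estimator."""


class ShiftTableError(CoiltoolsError):
    """Malformed shift tables: duplicates, unknown nuclei, empty overlap."""


class CouplingError(CoiltoolsError):
    """Unphysical HNHA intensity ratios or couplings at the tangent singularity."""


class FlotationError(CoiltoolsError):
    """Buoyancy term (1 - vbar*rho) is non-positive: the particle floats."""


class NoTransitionError(CoiltoolsError):
    """Titration data show no detectable cooperative unfolding transition."""


class FitError(CoiltoolsError):
    """A nonlinear fit failed to converge or returned an unphysical optimum."""


class ConfigError(CoiltoolsError):
    """Invalid pipeline configuration (unknown keys, missing inputs)."""
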