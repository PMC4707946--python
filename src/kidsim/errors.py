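"""Exception hierarchy for kidsim.

All package-specific failures derive from :class:`KidsimError` so callers
can catch simulator problems without masking programming errors.
"""


class KidsimError(Exception):
    """Base class for all kidsim errors."""


class ConfigurationError(KidsimError):
    """A run configuration or profile name is invalid."""


class GridRangeError(KidsimError):
    """An age falls outside the reference bundle's (age, sex) grid."""


class DomainError(KidsimError):
    """A numeric argument is outside the mathematical domain of a transform."""


class ConsistencyError(KidsimError):
    """Internal bookkeeping violated (timeline coverage, missing ledger rows)."""
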