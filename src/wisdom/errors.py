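"""Exception hierarchy.

Every user-facing failure mode raises a subclass of :class:`WisdomError` so
callers (and the CLI) can distinguish configuration mistakes from data
problems without matching on message text.
"""


class WisdomError(Exception):
    """Base class for all package errors."""


class ConfigurationError(WisdomError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class GenerationError(WisdomError, ValueError):
    """The synthetic renderer cannot honour a request (e.g. node > patch)."""


class MeasurementError(WisdomError, ValueError):
    """Feature computation on degenerate input (empty mask, shape mismatch)."""


class FeatureContractError(WisdomError, ValueError):
    """A model variant was given nodes lacking the features it requires."""


class TargetError(WisdomError, ValueError):
    """Weak-supervision targets outside their domain (e.g. rho not in [0,1])."""


class MetricError(WisdomError, ValueError):
    """A metric is undefined on the given input (e.g. single-class labels)."""


class ManifestError(WisdomError, ValueError):
    """A cohort manifest is structurally unreadable (missing columns, key)."""


class UnsupportedModelError(WisdomError, TypeError):
    """An operation needs model internals the given model does not expose."""
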