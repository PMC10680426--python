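"""Exception hierarchy for the rectdvh pipeline.

Each stage raises its own subclass so pipeline errors carry the stage name.
"""


class RectdvhError(Exception):
    """Base class for all package errors."""


class ConfigError(RectdvhError):
    """Invalid configuration value; the message names the offending field."""


class GeometryError(RectdvhError):
    """Structure-mask operation on incompatible or empty geometry."""


class DosimetryError(RectdvhError):
    """DVH computation on invalid dose/structure input."""


class DataError(RectdvhError):
    """Malformed toxicity records (e.g. duplicate visit rows)."""


class ModelError(RectdvhError):
    """Statistical model cannot be fitted (one-class outcome, too few rows)."""


class SimulationError(RectdvhError):
    """Synthetic-data generation failed (non-finite linear predictor, ...)."""
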