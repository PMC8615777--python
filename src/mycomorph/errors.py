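"""Exception types shared across the pipeline."""


class MycomorphError(Exception):
    """Base class for pipeline errors."""


class ParameterError(MycomorphError, ValueError):
    """Invalid parameter value (negative count, non-positive scale, ...)."""


class DegenerateObjectError(MycomorphError):
    """Object too small or thin for shape descriptors (e.g. a single pixel)."""


class EditError(MycomorphError):
    """Operator override record references a nonexistent label or is malformed."""


class ManifestError(MycomorphError):
    """Time-course manifest is inconsistent (duplicate keys, missing files)."""


class InsufficientDataError(MycomorphError):
    """Too few usable timepoints to call a coculture outcome."""
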