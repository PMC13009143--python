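"""Exception hierarchy for the retiflow pipeline.

Stage-specific failures subclass :class:`RetiflowError` so the pipeline
driver can abort with a stage-labeled message while library users can
catch the precise condition.
"""


class RetiflowError(Exception):
    """Base class for all retiflow errors."""


class InvalidSpecError(RetiflowError, ValueError):
    """A configuration or waveform specification violates its invariants."""


class SceneError(RetiflowError, ValueError):
    """Synthetic scene geometry is invalid (e.g. overlapping branches)."""


class AliasingError(RetiflowError, ValueError):
    """Requested spectral content cannot be represented below Nyquist."""


class DegenerateInputError(RetiflowError, ValueError):
    """Input has no usable structure (constant map, zero-variance series)."""


class NoVesselFoundError(RetiflowError, RuntimeError):
    """Segmentation produced an empty arterial mask."""


class NoCyclesError(RetiflowError, RuntimeError):
    """No dominant cardiac periodicity could be detected in a waveform.

    Mirrors the acquisition-time exclusion rule: measurements that do not
    span several cardiac cycles (e.g. interrupted by a blink) are removed
    from repeatability analysis rather than analyzed.
    """


class SchemaError(RetiflowError, ValueError):
    """A file is missing required datasets or attributes."""
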