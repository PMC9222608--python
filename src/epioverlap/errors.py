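"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`InfeasibleError` -> 3.
"""


class EpiOverlapError(Exception):
    """Base class for all package errors."""


class InputError(EpiOverlapError):
    """A file or value supplied by the user is malformed or missing."""


class InfeasibleError(EpiOverlapError):
    """A configuration is internally inconsistent (e.g. a background smaller
    than the union of the lists drawn from it, or more genes than fit on a
    chromosome)."""
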