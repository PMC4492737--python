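"""Exception hierarchy.

``InputError`` covers unreadable/ill-formed inputs and contract violations
on user-supplied data; ``ComputationError`` covers failures arising during
analysis of otherwise valid inputs. The CLI maps them to distinct exit
codes (2 and 3).
"""


class MotionTreeError(Exception):
    """Base class for all package errors."""


class InputError(MotionTreeError):
    """Unreadable, inconsistent or contract-violating input."""


class SelectionError(InputError):
    """An atom/residue selection matched nothing or was ill-formed."""


class ComputationError(MotionTreeError):
    """A computation on valid inputs could not be completed."""


class UnsupportedMotionError(ComputationError):
    """A closed-form/Monte-Carlo oracle does not support this motion model."""
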