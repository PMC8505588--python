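"""Error taxonomy shared by the pipeline stages.

Plain ``ValueError`` is raised for invalid arguments; the subclasses below
distinguish the data-dependent failure modes so callers can react per stage.
"""


class EmptyInputError(ValueError):
    """An operation received a recording or trial set with nothing to process."""


class EmptyOutputError(ValueError):
    """An operation would return an empty result (e.g. every trial rejected)."""


class InsufficientDataError(ValueError):
    """A class/fold has too few samples for the requested operation."""
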