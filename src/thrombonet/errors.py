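"""Exception hierarchy for thrombonet."""


class ThrombonetError(Exception):
    """Base class for all thrombonet errors."""


class ConfigurationError(ThrombonetError, ValueError):
    """A configuration object violates one of its invariants.

    The message names the violated invariant.
    """


class ReactionParseError(ThrombonetError, ValueError):
    """A reaction record is malformed; carries the offending reaction id."""

    def __init__(self, reaction_id: str, message: str):
        self.reaction_id = reaction_id
        super().__init__(f"reaction {reaction_id!r}: {message}")


class FixtureLookupError(ThrombonetError, KeyError):
    """Unknown fixture-network name; message lists the valid names."""


class FitError(ThrombonetError, ValueError):
    """Too few usable points (or otherwise degenerate input) for a fit."""


class SummaryError(ThrombonetError, ValueError):
    """Summary statistics requested for an empty network."""


class PartitionError(ThrombonetError, ValueError):
    """A module assignment does not cover the network's nodes."""
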