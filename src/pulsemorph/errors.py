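"""Exception hierarchy.

``ValidationError`` marks bad user input (files, configs, parameters) and maps
to CLI exit code 1; anything else escaping the pipeline maps to exit code 2.
"""


class PulseMorphError(Exception):
    """Base class for all package errors."""


class ValidationError(PulseMorphError):
    """Invalid user-supplied input: malformed file, bad config, bad parameter."""


class FormatError(ValidationError):
    """A list-mode or config file does not conform to its documented dialect."""


class MissingChannelError(FormatError):
    """A particle lacks a mandatory channel (FWS or SWS)."""

    def __init__(self, particle_id, channel):
        self.particle_id = particle_id
        self.channel = channel
        super().__init__(
            f"particle {particle_id!r} is missing mandatory channel {channel}"
        )


class ConfigError(ValidationError):
    """Gating or simulation configuration is malformed or inconsistent."""
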