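"""Exception hierarchy for the integration pipeline.

Errors are split by pipeline stage so that callers can distinguish a
transient source problem (:class:`PollError`, retriable on the next
scheduled run) from a configuration defect (:class:`ConfigError`, which no
amount of retrying will fix).
"""


class FeedwireError(Exception):
    """Base class for all framework errors."""


class ConfigError(FeedwireError):
    """Invalid agent/seed/template/integration configuration."""


class PollError(FeedwireError):
    """A source resource could not be read (unreachable, HTTP error, ...).

    Retriable: the next scheduled run will try again.
    """


class ExtractError(FeedwireError):
    """Source content could not be parsed in the agent's declared format."""


class DetectionError(FeedwireError):
    """The change-detection cache backend failed."""


class RenderError(FeedwireError):
    """Template rendering failed (unknown variable/function, code error)."""


class DeliveryError(FeedwireError):
    """A destination resource rejected or failed a delivery."""


class ValidationError(FeedwireError):
    """A pushed payload does not match the agent's declared selectors."""


class AuthError(FeedwireError):
    """Missing, malformed or revoked access token."""


class NotFoundError(FeedwireError):
    """Referenced entity (agent, integration, template) does not exist."""
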