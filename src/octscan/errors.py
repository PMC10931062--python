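"""Package-wide error types.

``ValidationError`` marks inputs that violate a documented contract
(shape/geometry mismatches, unknown label codes, empty cohorts);
``ConfigurationError`` marks missing or malformed configuration such as an
absent geometry sidecar. Both derive from ``ValueError`` so generic callers
may catch them together.
"""


class ValidationError(ValueError):
    """Input violates a documented invariant or precondition."""


class ConfigurationError(ValueError):
    """Required configuration (sidecar, manifest, config file) is missing or malformed."""
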