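"""Package-wide error taxonomy (mapped to CLI exit codes 2 and 3)."""


class ConfigError(ValueError):
    """Invalid configuration or parameters."""


class DataError(ValueError):
    """Malformed or inconsistent data."""
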