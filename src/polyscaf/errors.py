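"""Exception hierarchy.

CLI exit codes: 0 success, 2 usage/parameter error, 3 data/format error.
"""


class PolyscafError(Exception):
    """Base class for all package errors."""


class ParameterError(PolyscafError):
    """Invalid parameter or configuration value."""


class FormatError(PolyscafError):
    """Malformed or inconsistent input data."""


class ContractError(PolyscafError):
    """Inconsistent objects passed between pipeline stages."""
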