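"""Shared error types and logging for circprio."""

from __future__ import annotations

import logging

logger = logging.getLogger("circprio")
if not logger.handlers:  # library default: quiet unless the host app configures logging
    logger.addHandler(logging.NullHandler())


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition or invariant."""


class ConfigurationError(ValueError):
    """Raised when parameter combinations are internally inconsistent."""
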