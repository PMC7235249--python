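"""Exception hierarchy.

Three failure classes are distinguished throughout the package:

* :class:`InputError` — the data handed to an operation is malformed
  (empty sequence, ragged table, out-of-range position).
* :class:`ConfigError` — a parameter choice is invalid or unusable
  (unknown substitution matrix, even logo window, invalid IUPAC letter).
* :class:`ValidationError` — a declared expectation about the data failed
  a runtime check (expected residue missing, junction falls in a gap).
"""


class PamProspectorError(ValueError):
    """Base class for all package-specific errors."""


class InputError(PamProspectorError):
    """Malformed or degenerate input data."""


class ConfigError(PamProspectorError):
    """Invalid parameter or configuration value."""


class ValidationError(PamProspectorError):
    """A declared expectation failed verification against the data."""
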