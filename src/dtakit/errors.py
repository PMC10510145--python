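"""Exception types used across the toolkit."""


class DtakitError(Exception):
    """Base class for all toolkit errors."""


class SmilesParseError(DtakitError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, reason: str = "could not be parsed"):
        self.smiles = smiles
        super().__init__(f"invalid SMILES {smiles!r}: {reason}")


class ConfigError(DtakitError):
    """Inconsistent or invalid configuration / parameter shapes."""


class DataError(DtakitError):
    """Malformed or empty input data."""


class StateError(DtakitError):
    """An operation was applied to an object in the wrong state."""


class NumericError(DtakitError):
    """Non-finite values where finite numbers are required."""


class UndefinedMetricError(DtakitError):
    """A metric is undefined for the given inputs (e.g. CI with no ordered pairs)."""
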