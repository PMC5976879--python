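"""Exception hierarchy shared by all pipeline stages."""


class BshScanError(Exception):
    """Base class for every error raised by bshscan."""


class ParseError(BshScanError):
    """A file could not be parsed (malformed FASTA/Stockholm/Newick/TSV)."""


class ValidationError(BshScanError):
    """Parsed content violates a domain invariant (bad residue, ragged MSA...)."""


class SchemaError(BshScanError):
    """A tabular input is missing a required column."""


class ConfigError(BshScanError):
    """Inconsistent or out-of-range configuration."""


class ConstructionError(BshScanError):
    """A model could not be built from the given input (e.g. all-gap MSA)."""


class CalibrationError(BshScanError):
    """E-value calibration failed (degenerate decoy score distribution)."""
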