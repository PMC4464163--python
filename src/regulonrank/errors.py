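"""Exception hierarchy shared across the pipeline stages."""


class RegulonRankError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RegulonRankError, ValueError):
    """A file does not conform to the expected tabular layout."""


class ConsistencyError(RegulonRankError, ValueError):
    """Inputs that are individually valid but mutually inconsistent."""


class InsufficientReplicatesError(RegulonRankError, ValueError):
    """Fewer than two replicates per group; the test statistic is undefined."""


class PairingError(RegulonRankError, ValueError):
    """Replicate vectors cannot be paired (unequal lengths or missing indices)."""


class DegenerateInputError(RegulonRankError, ValueError):
    """An axis with fewer than two items cannot be clustered."""
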