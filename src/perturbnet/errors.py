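"""Exception hierarchy for perturbnet."""


class PerturbnetError(Exception):
    """Base class for all perturbnet errors."""


class DataError(PerturbnetError):
    """Malformed, inconsistent or empty input data."""


class DegenerateDistributionError(PerturbnetError):
    """A distribution fit collapsed (e.g. zero spread in the ΔPCC matrix)."""
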