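"""Exception hierarchy shared across the package.

Exit-code mapping (used by the command-line front end):
usage errors -> 1, data/format errors -> 2, runtime failures -> 3.
"""


class SurvScanError(Exception):
    """Base class for all fatal errors raised by this package."""

    exit_code = 3


class UsageError(SurvScanError):
    """Bad command line: unknown flag, missing required flag, bad enum value."""

    exit_code = 1


class DataError(SurvScanError):
    """Malformed or inconsistent input data (genotype, sample or VCF files)."""

    exit_code = 2


class FitError(SurvScanError):
    """A model fit cannot proceed for one SNP (e.g. no events, no complete cases).

    Caught by the scan loop and turned into a per-SNP NA row; never fatal.
    """
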