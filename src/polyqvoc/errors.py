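"""Exception hierarchy shared across the package."""


class PolyqvocError(Exception):
    """Base class for all package errors."""


class FormatError(PolyqvocError):
    """Malformed input (FASTA, phenotype table, config, assay table)."""


class NoHingeError(PolyqvocError):
    """No window of the sequence matches the hinge anchor within tolerance.

    Carries ``best_mismatches``, the smallest Hamming distance found, so the
    caller can report how far the closest window was.
    """

    def __init__(self, message: str, best_mismatches: int | None = None):
        super().__init__(message)
        self.best_mismatches = best_mismatches


class BinningError(PolyqvocError):
    """Invalid binning request (e.g. rank groups that do not divide n)."""


class DegenerateDataError(PolyqvocError):
    """Data admit no meaningful statistic (zero variance, too few groups)."""


class FitError(PolyqvocError):
    """A model fit failed to converge."""
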