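"""Exception hierarchy shared across the toolkit."""


class PlastomarkerError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PlastomarkerError):
    """Malformed input file (FASTA, GenBank, GFF3, genotype CSV, ...)."""


class StructureNotFoundError(PlastomarkerError):
    """No quadripartite structure (inverted-repeat pair) could be located."""


class PlacementError(PlastomarkerError):
    """A synthetic event does not fit at the requested location."""


class NoDataError(PlastomarkerError):
    """A statistic was requested on an empty / all-missing input."""


class InvalidMotifError(PlastomarkerError):
    """A motif that is itself a tandem repetition of a shorter unit."""


class DesignError(PlastomarkerError):
    """Primer design cannot proceed (insufficient flank, no candidates)."""
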