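"""Exception hierarchy for the paralog-aware MLPA toolkit."""


class ParalogMLPAError(Exception):
    """Base class for all package errors."""


class LocusConfigError(ParalogMLPAError):
    """A locus configuration file failed validation.

    The message names the offending field(s).
    """


class UnsupportedCoordinatesError(ParalogMLPAError):
    """Two HGVS positions cannot be compared (different unanchored introns)."""


class HaplotypeInvariantError(ParalogMLPAError):
    """A haplotype violates the segment-tiling or origin rules."""


class ParameterError(ParalogMLPAError):
    """A numeric parameter is out of its admissible range."""


class SchemaError(ParalogMLPAError):
    """Tabular input does not match the locus probe set."""


class DegenerateSampleError(ParalogMLPAError):
    """A sample cannot be normalized (zero scaling median)."""


class PanelConstructionError(ParalogMLPAError):
    """Too few candidates qualified as reference samples."""


class RangeError(ParalogMLPAError):
    """A requested region lies outside the locus map."""
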