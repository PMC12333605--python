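"""Exception hierarchy for input validation and configuration problems."""


class CnnBrfError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CnnBrfError, ValueError):
    """An option or hyperparameter is out of its legal range or missing."""


class DataFormatError(CnnBrfError, ValueError):
    """An input file does not follow its documented layout."""


class RangeError(DataFormatError):
    """A similarity value lies outside [0, 1] beyond tolerance."""


class SymmetryError(DataFormatError):
    """A similarity matrix is asymmetric beyond tolerance."""


class AlignmentError(CnnBrfError, ValueError):
    """Two containers that must share an entity catalog do not."""


class SamplingError(CnnBrfError, ValueError):
    """A negative-sampling request cannot be satisfied (pool too small)."""


class EmptyDatasetError(DataFormatError):
    """An input file contains no usable records."""
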