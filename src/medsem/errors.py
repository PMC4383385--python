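"""Exception hierarchy for medsem."""


class MedSEMError(Exception):
    """Base class for all medsem errors."""


class InvalidInputError(MedSEMError):
    """Malformed data, specification, or configuration."""


class MissingDataError(InvalidInputError):
    """Missing values in a column used by the model.

    The fitter never drops rows silently: the caller must perform
    complete-case filtering explicitly so that the analysis n is always known.
    """


class CollinearityError(InvalidInputError):
    """Rank-deficient design matrix; the message names the offending columns."""


class IdentificationError(MedSEMError):
    """A requested estimand is not identified under the declared assumption."""


class SettingsError(MedSEMError):
    """Invalid Monte Carlo or bootstrap settings."""
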