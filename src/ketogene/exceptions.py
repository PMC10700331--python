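"""Exception hierarchy shared across the pipeline stages."""


class KetogeneError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(KetogeneError, ValueError):
    """An argument is outside its valid domain (probability, gap, alpha...)."""


class EmptyInputError(KetogeneError, ValueError):
    """An operation that requires at least one record received none."""


class NoAmplificationError(KetogeneError):
    """A primer has no exact match on the template: the PCR yields nothing."""


class AmbiguousPrimingError(KetogeneError):
    """A primer matches the template more than once: the product is undefined."""


class UncallableGenotypeError(KetogeneError):
    """An observed band pattern matches neither homozygote nor the heterozygote."""


class MissingDataError(KetogeneError, ValueError):
    """A required measurement (e.g. blood BHB) is absent from a record."""


class IncompleteRecordError(KetogeneError, ValueError):
    """Records lack genotype or status; carries the offending animal IDs."""

    def __init__(self, message: str, animal_ids=()):
        super().__init__(message)
        self.animal_ids = list(animal_ids)


class EmptyTableError(KetogeneError, ValueError):
    """A contingency table with zero grand total cannot yield frequencies."""


class DegenerateMarginError(KetogeneError, ValueError):
    """A zero row or column margin makes the chi-square test undefined."""


class DegenerateOutcomeError(KetogeneError, ValueError):
    """All animals share one outcome; WoE needs both goods and bads."""


class ZeroCellError(KetogeneError, ValueError):
    """A WoE category has an empty cell and the policy forbids continuity."""


class UnknownCategoryError(KetogeneError, KeyError):
    """A genotype label is not present in (any merged category of) a WoE table."""


class DegenerateLabelsError(KetogeneError, ValueError):
    """ROC analysis needs both positive and negative labels present."""


class ConfigurationError(KetogeneError, ValueError):
    """A pipeline or predictor configuration is internally inconsistent."""
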