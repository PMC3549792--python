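"""Exception hierarchy for epistasim."""


class EpistasimError(Exception):
    """Base class for all epistasim errors."""


class InvalidParameterError(EpistasimError, ValueError):
    """A parameter lies outside its valid domain (e.g. MAF not in (0, 0.5])."""


class DegenerateModelError(EpistasimError):
    """The model has prevalence 0 or 1, so variance-normalized quantities
    (heritability, EDM, the class-conditional distributions) are undefined."""


class UndefinedCORError(EpistasimError):
    """All multi-locus genotypes fall into a single risk class, so the
    2x2 expected table has a zero margin and the odds ratio is undefined.

    Carries the degenerate expected table as ``table`` = (a, b, c, d).
    """

    def __init__(self, message: str, table: tuple[float, float, float, float]):
        super().__init__(message)
        self.table = table


class EmptySelectionError(EpistasimError):
    """Quantile selection was requested from an empty model population."""


class SamplingFailureError(EpistasimError):
    """Quota rejection sampling exceeded its attempt cap before filling a
    class quota. Carries the name of the starved class."""

    def __init__(self, message: str, starved_class: str):
        super().__init__(message)
        self.starved_class = starved_class


class ModelFileError(EpistasimError):
    """A penetrance-model file failed to parse or validate."""
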