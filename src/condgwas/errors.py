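"""Exception hierarchy for condgwas."""


class CondgwasError(Exception):
    """Base class for all condgwas errors."""


class ConfigurationError(CondgwasError):
    """A column mapping or option is missing or inconsistent."""


class InputError(CondgwasError):
    """Input data are unusable (e.g. zero valid rows, duplicated variant)."""


class HarmonizationError(CondgwasError):
    """Alleles of the two records can be neither matched nor swapped."""

    def __init__(self, variant_id: str, message: str):
        self.variant_id = variant_id
        super().__init__(f"{variant_id}: {message}")


class DomainError(CondgwasError):
    """An argument is outside the mathematical domain of a formula."""


class DegenerateTraitError(CondgwasError):
    """A binary trait has zero cases or zero controls."""


class InfeasibleFrequencyError(CondgwasError):
    """No stratified allele frequencies satisfy the stated constraints."""


class CollinearityError(CondgwasError):
    """The cross-product matrix V is singular or near-singular."""


class SeparationError(CondgwasError):
    """Perfect separation in a logistic fit."""


class ConvergenceError(CondgwasError):
    """Iteratively reweighted least squares failed to converge."""
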