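"""Read, write and harmonize GWAS summary-statistics tables.

A summary-statistics table carries, per variant: identifier, effect and other
allele, effect allele frequency (EAF), the marginal effect estimate with its
standard error, and sample counts (total n; for binary traits also cases and
controls).  Records store EAF; formulas that require MAF use
``min(eaf, 1 - eaf)``.

Two tables analysed jointly (outcome and adjustment covariate) must refer to
the same effect allele per variant; :func:`harmonize` flips swapped alleles and
:func:`af_discrepancy_filter` removes variants whose allele frequencies differ
significantly between the two datasets (two-proportion z-test, Bonferroni
corrected), a known failure mode when mixing consortium results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, HarmonizationError, InputError

__all__ = [
    "SummaryRecord",
    "HarmonizedPair",
    "ReadReport",
    "DEFAULT_COLUMNS",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "af_discrepancy_filter",
    "af_discrepancy_test",
    "significance_threshold",
]

_ALLELES = frozenset("ACGT")
_PALINDROMIC = {frozenset("AT"), frozenset("CG")}

#: default column names for delimited summary-statistics files
DEFAULT_COLUMNS: dict[str, str] = {
    "variant_id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "n": "n",
    "n_cases": "n_cases",
    "n_controls": "n_controls",
}


@dataclass(frozen=True)
class SummaryRecord:
    """Marginal GWAS summary statistics for one variant and one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    n: int
    trait_type: str = "continuous"
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in _ALLELES or self.other_allele not in _ALLELES:
            raise InputError(f"{self.variant_id}: alleles must be one of A/C/G/T")
        if self.effect_allele == self.other_allele:
            raise InputError(f"{self.variant_id}: alleles must differ")
        if not 0.0 < self.eaf < 1.0:
            raise InputError(f"{self.variant_id}: eaf must lie in (0, 1)")
        if self.se <= 0:
            raise InputError(f"{self.variant_id}: se must be positive")
        if self.n < 2:
            raise InputError(f"{self.variant_id}: n must be >= 2")
        if self.trait_type not in ("continuous", "binary"):
            raise InputError(f"{self.variant_id}: unknown trait type {self.trait_type}")
        if self.trait_type == "binary":
            if self.n_cases is None or self.n_controls is None:
                raise InputError(f"{self.variant_id}: binary trait needs case/control counts")
            if self.n_cases + self.n_controls != self.n:
                raise InputError(
                    f"{self.variant_id}: n_cases + n_controls must equal n"
                )

    @property
    def maf(self) -> float:
        """Minor allele frequency min(eaf, 1 − eaf)."""
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous (A/T or C/G) variants."""
        return frozenset((self.effect_allele, self.other_allele)) in _PALINDROMIC

    def flipped(self) -> "SummaryRecord":
        """The same record expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass(frozen=True)
class HarmonizedPair:
    """Outcome/covariate records for one variant on a common effect allele."""

    outcome: SummaryRecord
    covariate: SummaryRecord
    flipped: bool
    af_diff_p: float = float("nan")

    @property
    def is_palindromic(self) -> bool:
        return self.outcome.is_palindromic


@dataclass
class ReadReport:
    """Book-keeping from :func:`read_sumstats`: rows dropped per reason."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    drop_reasons: dict[str, int] | None = None


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    sep: str | None = None,
) -> tuple[list[SummaryRecord], ReadReport]:
    """Read a delimited summary-statistics file into records.

    Rows violating record invariants (e.g. se <= 0, eaf outside (0,1)) are
    dropped and counted in the returned :class:`ReadReport`; duplicated
    variant ids or zero valid rows raise :class:`InputError`.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=sep, engine="python")
    required = ["variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "n"]
    if trait_type == "binary":
        required += ["n_cases", "n_controls"]
    missing = [cols[k] for k in required if cols[k] not in df.columns]
    if missing:
        raise ConfigurationError(f"missing mapped columns: {missing}")

    report = ReadReport(n_read=len(df), drop_reasons={})
    records: list[SummaryRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        try:
            kwargs = dict(
                variant_id=str(row[cols["variant_id"]]),
                effect_allele=str(row[cols["effect_allele"]]).upper(),
                other_allele=str(row[cols["other_allele"]]).upper(),
                eaf=float(row[cols["eaf"]]),
                beta=float(row[cols["beta"]]),
                se=float(row[cols["se"]]),
                n=int(row[cols["n"]]),
                trait_type=trait_type,
            )
            if trait_type == "binary":
                kwargs["n_cases"] = int(row[cols["n_cases"]])
                kwargs["n_controls"] = int(row[cols["n_controls"]])
            rec = SummaryRecord(**kwargs)
        except (InputError, ValueError) as exc:
            report.n_dropped += 1
            reason = str(exc)
            report.drop_reasons[reason] = report.drop_reasons.get(reason, 0) + 1
            continue
        if rec.variant_id in seen:
            raise InputError(f"duplicated variant_id: {rec.variant_id}")
        seen.add(rec.variant_id)
        records.append(rec)
    report.n_kept = len(records)
    if not records:
        raise InputError(f"no valid rows in {path}")
    return records, report


def write_sumstats(records: Iterable[SummaryRecord], path, sep: str = "\t") -> None:
    """Write records back to a delimited file (round-trips read_sumstats)."""
    rows = []
    for r in records:
        rows.append(
            dict(
                variant_id=r.variant_id,
                effect_allele=r.effect_allele,
                other_allele=r.other_allele,
                eaf=r.eaf,
                beta=r.beta,
                se=r.se,
                n=r.n,
                n_cases="" if r.n_cases is None else r.n_cases,
                n_controls="" if r.n_controls is None else r.n_controls,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def harmonize(outcome: SummaryRecord, covariate: SummaryRecord) -> HarmonizedPair:
    """Express both records on the outcome's effect allele.

    If the covariate's alleles are swapped relative to the outcome, its beta is
    negated and its EAF reflected.  Strand flips are not attempted (alleles
    must match as written); incompatible alleles raise
    :class:`HarmonizationError`.  Idempotent: harmonizing an already
    harmonized pair changes nothing.
    """
    if outcome.variant_id != covariate.variant_id:
        raise HarmonizationError(
            outcome.variant_id, f"variant ids differ ({covariate.variant_id})"
        )
    if (outcome.effect_allele, outcome.other_allele) == (
        covariate.effect_allele,
        covariate.other_allele,
    ):
        return HarmonizedPair(outcome, covariate, flipped=False)
    if (outcome.effect_allele, outcome.other_allele) == (
        covariate.other_allele,
        covariate.effect_allele,
    ):
        return HarmonizedPair(outcome, covariate.flipped(), flipped=True)
    raise HarmonizationError(
        outcome.variant_id,
        f"incompatible alleles {outcome.effect_allele}/{outcome.other_allele} vs "
        f"{covariate.effect_allele}/{covariate.other_allele}",
    )


def af_discrepancy_test(pair: HarmonizedPair) -> float:
    """Two-proportion z-test p-value for equal allele frequencies.

    Compares allele counts 2n·EAF between the outcome and covariate datasets
    using the pooled-variance normal approximation.
    """
    a1, a2 = 2 * pair.outcome.n, 2 * pair.covariate.n
    f1, f2 = pair.outcome.eaf, pair.covariate.eaf
    pooled = (a1 * f1 + a2 * f2) / (a1 + a2)
    var = pooled * (1.0 - pooled) * (1.0 / a1 + 1.0 / a2)
    if var <= 0:  # pooled frequency of 0 or 1 cannot occur for valid records
        return 1.0
    z = (f1 - f2) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def af_discrepancy_filter(
    pairs: Sequence[HarmonizedPair], alpha: float = 0.05
) -> tuple[list[HarmonizedPair], list[HarmonizedPair]]:
    """Partition pairs by the Bonferroni-corrected allele-frequency test.

    A pair is removed when its two-proportion test p-value falls below
    ``alpha / len(pairs)``.  Returns ``(kept, removed)`` with the per-pair
    p-value recorded in ``af_diff_p``; empty input yields two empty lists.
    """
    pairs = list(pairs)
    if not pairs:
        return [], []
    threshold = significance_threshold(alpha, len(pairs))
    kept: list[HarmonizedPair] = []
    removed: list[HarmonizedPair] = []
    for pair in pairs:
        p = af_discrepancy_test(pair)
        annotated = replace(pair, af_diff_p=p)
        (removed if p < threshold else kept).append(annotated)
    return kept, removed


def significance_threshold(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected significance level alpha / n_tests."""
    if n_tests < 1:
        raise ConfigurationError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    return alpha / n_tests
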