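"""Core domain types for GWAS summary statistics.

The central design problem this module solves is the p-value: genome-wide
association studies on large cohorts routinely report p-values far below the
smallest positive IEEE double (~5e-324).  ``PValue`` therefore stores a
canonical decimal mantissa in [1, 10) together with an unbounded signed
integer exponent, so ``3.2e-450`` survives parsing, comparison, rounding and
re-serialisation without ever being squeezed through a float.

Records and datasets are deliberately *permissive* containers: they can hold
values that violate the reporting standard (a negative standard error, an
``N`` allele).  Judging conformance is the validator's job; producers that
want guaranteed-valid values use the strict helpers (``Allele``,
``parse_pvalue``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation, ROUND_HALF_EVEN, localcontext
from typing import Optional


class SumStatsError(Exception):
    """Base class for all errors raised by this package."""

    code: str = "ERROR"


class PValueParseError(SumStatsError):
    """The text is not a decimal or scientific-notation numeral."""

    code = "P_PARSE"


class PValueRangeError(SumStatsError):
    """The numeral is a number, but not a probability in (0, 1]."""

    code = "P_OUT_OF_RANGE"


#: Accepted chromosome tokens (human autosomes, sex chromosomes, mitochondrion).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

#: Unambiguous nucleotide alphabet for alleles.
ALLELE_BASES = frozenset("ACGT")

# Enough working precision for canonicalising any mantissa we will ever meet;
# exponent range in `decimal` defaults far beyond +-500 so tiny p-values are safe.
_DECIMAL_PRECISION = 50


class Ordering(enum.IntEnum):
    """Result of a three-way comparison."""

    LESS = -1
    EQUAL = 0
    GREATER = 1


class EffectType(str, enum.Enum):
    """Scale on which the per-allele effect is reported."""

    BETA = "beta"
    ODDS_RATIO = "odds_ratio"

    @property
    def column(self) -> str:
        return self.value


@dataclass(frozen=True)
class PValue:
    """A positive real number ``mantissa * 10**exponent`` in canonical form.

    The representation is canonical: ``1 <= mantissa < 10``.  Any positive
    value can be held (the validator flags values above 1); zero and negative
    numbers are unrepresentable by construction.

    Parameters
    ----------
    mantissa:
        Decimal (or anything `Decimal` accepts) significand.  Re-scaled into
        [1, 10) on construction, adjusting the exponent accordingly.
    exponent:
        Power of ten.  Plain Python int, so -450 is as good as -4.
    """

    mantissa: Decimal
    exponent: int

    def __post_init__(self) -> None:
        m = self.mantissa if isinstance(self.mantissa, Decimal) else Decimal(str(self.mantissa))
        if not m.is_finite() or m <= 0:
            raise PValueParseError(f"mantissa must be a finite positive number, got {self.mantissa!r}")
        exp = int(self.exponent)
        shift = m.adjusted()  # position of the most significant digit
        if shift != 0:
            with localcontext() as ctx:
                ctx.prec = _DECIMAL_PRECISION
                m = m.scaleb(-shift)
            exp += shift
        object.__setattr__(self, "mantissa", m)
        object.__setattr__(self, "exponent", exp)

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_string(cls, text: str) -> "PValue":
        """Parse a numeral (decimal or scientific) into a canonical PValue.

        Performs no range check: ``"2"`` parses to 2e0.  Use
        :func:`parse_pvalue` to enforce the (0, 1] probability range.
        """
        try:
            d = Decimal(text.strip())
        except (InvalidOperation, ValueError, ArithmeticError) as err:
            raise PValueParseError(f"not a numeral: {text!r}") from err
        if not d.is_finite():
            raise PValueParseError(f"not a finite numeral: {text!r}")
        if d <= 0:
            raise PValueRangeError(f"p-value must be > 0, got {text!r}")
        return cls(d, 0)

    @classmethod
    def from_float(cls, value: float) -> "PValue":
        if not (value > 0):
            raise PValueRangeError(f"p-value must be > 0, got {value!r}")
        return cls(Decimal(repr(value)), 0)

    # -- accessors ------------------------------------------------------

    @property
    def value(self) -> float:
        """The value as a float; underflows to 0.0 below ~1e-323."""
        return float(self.mantissa.scaleb(self.exponent))

    @property
    def log10(self) -> float:
        """log10 of the value, computed without underflow."""
        import math

        return self.exponent + math.log10(float(self.mantissa))

    def is_probability(self) -> bool:
        """True when the value lies in (0, 1]."""
        return self.exponent < 0 or (self.exponent == 0 and self.mantissa == 1)

    # -- comparison -----------------------------------------------------

    def compare(self, other: "PValue") -> Ordering:
        """Three-way comparison on the represented real values."""
        if self.exponent != other.exponent:
            return Ordering.LESS if self.exponent < other.exponent else Ordering.GREATER
        c = self.mantissa.compare(other.mantissa)
        return Ordering(int(c))

    def __lt__(self, other: "PValue") -> bool:
        return self.compare(other) is Ordering.LESS

    def __le__(self, other: "PValue") -> bool:
        return self.compare(other) is not Ordering.GREATER

    def __gt__(self, other: "PValue") -> bool:
        return self.compare(other) is Ordering.GREATER

    def __ge__(self, other: "PValue") -> bool:
        return self.compare(other) is not Ordering.LESS

    def __str__(self) -> str:
        return f"{self.mantissa}e{self.exponent}"


def parse_pvalue(text: str) -> PValue:
    """Parse a numeral into a canonical :class:`PValue` in (0, 1].

    Raises
    ------
    PValueParseError
        When the text is not a decimal/scientific numeral.
    PValueRangeError
        When the number is <= 0 (including an explicit 0, which is rejected
        rather than silently floored) or > 1.
    """
    p = PValue.from_string(text)
    if not p.is_probability():
        raise PValueRangeError(f"p-value must be in (0, 1], got {text!r}")
    return p


def format_pvalue(p: PValue, sig_digits: int) -> str:
    """Render a PValue as ``<mantissa>e<exponent>`` scientific notation.

    The mantissa carries exactly ``sig_digits`` significant digits, rounded
    half-even.  A rounding carry (9.99... -> 10.0) re-canonicalises the
    exponent, so the output mantissa is always in [1, 10).
    """
    if sig_digits < 1:
        raise ValueError("sig_digits must be >= 1")
    quantum = Decimal(1).scaleb(1 - sig_digits)
    with localcontext() as ctx:
        ctx.prec = _DECIMAL_PRECISION
        m = p.mantissa.quantize(quantum, rounding=ROUND_HALF_EVEN)
        exp = p.exponent
        if m >= 10:
            m = m.scaleb(-1).quantize(quantum, rounding=ROUND_HALF_EVEN)
            exp += 1
    return f"{m}e{exp}"


def compare_pvalues(a: PValue, b: PValue) -> Ordering:
    """Total order on p-values, consistent with real-number order."""
    return a.compare(b)


@dataclass(frozen=True)
class Allele:
    """A non-empty uppercase A/C/G/T sequence.

    Indels are written as full alternate sequences; legacy "-", "D", "I"
    tokens and IUPAC ambiguity codes are rejected so alleles are unambiguous
    without a reference genome.
    """

    bases: str

    def __post_init__(self) -> None:
        if not Allele.is_valid(self.bases):
            raise ValueError(f"invalid allele {self.bases!r}: need non-empty uppercase A/C/G/T")

    @staticmethod
    def is_valid(bases: object) -> bool:
        return isinstance(bases, str) and len(bases) >= 1 and set(bases) <= ALLELE_BASES

    def __str__(self) -> str:
        return self.bases


@dataclass
class SumStatsRecord:
    """One variant's association result (the standard reporting elements).

    Fields are deliberately loosely typed so a record can carry values that
    break the standard; :mod:`sumstatskit.validator` turns violations into
    coded findings.  Coordinates are 1-based and fully closed.
    """

    variant_id: Optional[str] = None
    chromosome: Optional[str] = None
    base_pair_location: Optional[int] = None
    effect_allele: Optional[str] = None
    other_allele: Optional[str] = None
    effect_allele_frequency: Optional[float] = None
    beta: Optional[float] = None
    odds_ratio: Optional[float] = None
    standard_error: Optional[float] = None
    p_value: Optional[PValue] = None
    ci_upper: Optional[float] = None
    ci_lower: Optional[float] = None

    @property
    def effect_value(self) -> Optional[float]:
        """Whichever effect field is populated (beta preferred if both)."""
        return self.beta if self.beta is not None else self.odds_ratio

    def identified(self) -> bool:
        """Variant identification rule: rsID, or chromosome + position."""
        return self.variant_id is not None or (
            self.chromosome is not None and self.base_pair_location is not None
        )


#: Canonical column order of the standard (effect column slot marked "<effect>").
STANDARD_COLUMN_ORDER: tuple[str, ...] = (
    "variant_id",
    "chromosome",
    "base_pair_location",
    "p_value",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "<effect>",
    "standard_error",
    "ci_upper",
    "ci_lower",
)

#: All recognised standard column headers (both effect spellings included).
STANDARD_COLUMNS: frozenset[str] = frozenset(
    c for c in STANDARD_COLUMN_ORDER if c != "<effect>"
) | {"beta", "odds_ratio"}


def standard_column_order(effect_type: EffectType) -> tuple[str, ...]:
    """The printed column order with the effect slot resolved."""
    return tuple(
        effect_type.column if c == "<effect>" else c for c in STANDARD_COLUMN_ORDER
    )


def column_sort_key(column: str) -> tuple[int, str]:
    """Deterministic ordering key: standard columns first in printed order."""
    name = "<effect>" if column in ("beta", "odds_ratio", "effect") else column
    try:
        return (STANDARD_COLUMN_ORDER.index(name), column)
    except ValueError:
        return (len(STANDARD_COLUMN_ORDER), column)


@dataclass
class Dataset:
    """An ordered collection of records plus file-level descriptors.

    ``auxiliary_columns`` preserves non-standard columns verbatim, keyed by
    their original header, one string cell per record.  ``columns`` lists the
    standard columns actually present (None means the full standard set for
    the dataset's effect type) so a file missing an optional column round-trips
    without inventing it.
    """

    records: list[SumStatsRecord] = field(default_factory=list)
    effect_type: EffectType = EffectType.BETA
    genome_build: Optional[str] = None
    auxiliary_columns: dict[str, list[Optional[str]]] = field(default_factory=dict)
    source_name: str = ""
    columns: Optional[tuple[str, ...]] = None

    def __len__(self) -> int:
        return len(self.records)

    def standard_columns(self) -> tuple[str, ...]:
        if self.columns is not None:
            return self.columns
        return standard_column_order(self.effect_type)
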