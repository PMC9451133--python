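"""Rule-based conformance validation for SumStats datasets.

Findings are returned, never thrown: every departure from the reporting
standard becomes a :class:`ValidationIssue` with a code from the published
registry, a severity, and a (row, column) location.  Row 0 is the file/header
level; data rows are numbered from 1 in file order.

The registry below is the single source of truth for issue codes.  Where the
standard leaves "minimally acceptable responses" open, the registry entry
documents this toolkit's choice.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, TYPE_CHECKING

from .core_model import (
    CHROMOSOMES,
    Allele,
    Dataset,
    SumStatsRecord,
    column_sort_key,
)

if TYPE_CHECKING:  # pragma: no cover
    from .metadata import StudyMetadata

ERROR = "ERROR"
WARNING = "WARNING"

_RSID_RE = re.compile(r"^rs[0-9]+$")

#: Published code registry: code -> (default severity, description).
CODE_REGISTRY: dict[str, tuple[str, str]] = {
    # header / file level
    "MISSING_MANDATORY": (ERROR, "A mandatory column is absent (column token 'effect' means neither odds_ratio nor beta is present)"),
    "VARIANT_ID_RULE": (ERROR, "Neither variant_id nor the chromosome + base_pair_location pair is present"),
    "EFFECT_COLUMN_CONFLICT": (ERROR, "Both odds_ratio and beta columns are present; exactly one effect scale per file"),
    "CI_BOUND_SINGLE": (WARNING, "Only one of ci_lower/ci_upper is present"),
    "MISSING_GENOME_BUILD": (ERROR, "Records rely on chromosome + position identification but no genome build is declared"),
    "UNKNOWN_COLUMN": (WARNING, "Column is not a standard reporting element; preserved as auxiliary"),
    "DUPLICATE_HEADER": (ERROR, "The same column header appears more than once"),
    "ROW_FIELD_COUNT": (ERROR, "Row has a different number of fields than the header (row skipped)"),
    "EMPTY_CELL": (WARNING, "Empty cell normalised to missing; the standard missing token is 'NA'"),
    "PARSE_ERROR": (ERROR, "Cell could not be parsed as the column's declared type"),
    "P_PARSE": (ERROR, "p_value cell is not a decimal or scientific numeral"),
    "P_ZERO_FLOORED": (WARNING, "p_value of 0 replaced by the configured floor"),
    "EMPTY_DATASET": (ERROR, "Dataset contains no records"),
    # record level
    "P_OUT_OF_RANGE": (ERROR, "p-value outside (0, 1]"),
    "EAF_OUT_OF_RANGE": (ERROR, "effect_allele_frequency outside [0, 1]"),
    "BAD_ALLELE": (ERROR, "Allele is not a non-empty uppercase A/C/G/T sequence"),
    "ALLELES_IDENTICAL": (ERROR, "effect_allele equals other_allele"),
    "BAD_CHROMOSOME": (ERROR, "Chromosome token not in {1..22, X, Y, MT}"),
    "BAD_POSITION": (ERROR, "base_pair_location is not a positive integer (1-based)"),
    "BAD_RSID": (ERROR, "variant_id does not match ^rs[0-9]+$"),
    "NEG_SE": (ERROR, "standard_error is negative"),
    "NONPOS_OR": (ERROR, "odds_ratio is not strictly positive"),
    "CI_ORDER": (ERROR, "ci_lower exceeds ci_upper (or a non-positive bound with an odds-ratio effect)"),
    "MISSING_MANDATORY_VALUE": (ERROR, "A mandatory cell is missing ('NA')"),
    "DUPLICATE_VARIANT": (WARNING, "Repeated (chromosome, position, effect_allele, other_allele) tuple"),
    # harmonizer
    "HARMONIZE_AMBIGUOUS": (ERROR, "An ambiguous source header touching a mandatory element was not resolved by an override"),
    "CHR_PREFIX_NORMALIZED": (WARNING, "'chr'-prefixed chromosome token normalised"),
    "ALLELE_CASE_NORMALIZED": (WARNING, "Lower-case allele normalised to upper case"),
    # metadata
    "META_MISSING": (ERROR, "A mandatory study-metadata element is absent"),
    "META_BAD_VALUE": (ERROR, "A metadata value is outside its allowed set or range"),
    "ACCESSION_PATTERN": (ERROR, "Accession does not match ^GCST[0-9]{6,}$"),
    "EFO_PATTERN": (ERROR, "Trait ontology ID is not a CURIE like EFO_0001360"),
    "SAMPLE_COUNT_INCONSISTENT": (ERROR, "n_cases + n_controls exceeds n_total"),
    "PARTIAL_REASON_MISSING": (ERROR, "Dataset flagged partial without a reason"),
    "ANCESTRY_UNKNOWN": (WARNING, "Ancestry category not in the configured controlled vocabulary"),
    "UNKNOWN_METADATA_KEY": (WARNING, "Metadata key not in the schema; preserved verbatim"),
    # lifecycle
    "LIFECYCLE_RETRACTED": (ERROR, "Operation not permitted on a retracted accession"),
}

#: Record-level codes the error injector can synthesise (subset of the registry).
INJECTABLE_CODES: tuple[str, ...] = (
    "P_OUT_OF_RANGE",
    "EAF_OUT_OF_RANGE",
    "BAD_ALLELE",
    "ALLELES_IDENTICAL",
    "BAD_CHROMOSOME",
    "BAD_POSITION",
    "BAD_RSID",
    "NEG_SE",
    "NONPOS_OR",
    "CI_ORDER",
    "MISSING_MANDATORY_VALUE",
)

#: Columns whose cells are mandatory per record ("<effect>" = beta/odds_ratio).
MANDATORY_COLUMNS: tuple[str, ...] = (
    "p_value",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "<effect>",
    "standard_error",
)


@dataclass(frozen=True)
class ValidationIssue:
    """One machine-readable finding."""

    severity: str
    code: str
    row: int = 0
    column: str = ""
    message: str = ""
    observed: str = ""

    def __post_init__(self) -> None:
        if self.code not in CODE_REGISTRY:
            raise ValueError(f"unregistered issue code {self.code!r}")
        if self.row < 0:
            raise ValueError("row must be >= 0")


def issue(code: str, row: int = 0, column: str = "", message: str = "", observed: object = "") -> ValidationIssue:
    """Build an issue with the registry's default severity and description."""
    severity, description = CODE_REGISTRY[code]
    return ValidationIssue(
        severity=severity,
        code=code,
        row=row,
        column=column,
        message=message or description,
        observed="" if observed == "" else str(observed),
    )


@dataclass
class ValidationReport:
    """Aggregated findings for one dataset."""

    issues: list[ValidationIssue] = field(default_factory=list)
    records_checked: int = 0

    @property
    def counts_by_code(self) -> dict[str, int]:
        return dict(Counter(i.code for i in self.issues))

    @property
    def valid(self) -> bool:
        return not any(i.severity == ERROR for i in self.issues)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "valid": self.valid,
            "records_checked": self.records_checked,
            "counts_by_code": self.counts_by_code,
            "issues": [asdict(i) for i in self.issues],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=False)

    def to_text(self) -> str:
        lines = [
            f"records checked: {self.records_checked}",
            f"valid: {self.valid}",
        ]
        for i in self.issues:
            loc = f"row {i.row}" + (f", {i.column}" if i.column else "")
            obs = f" (observed: {i.observed})" if i.observed else ""
            lines.append(f"{i.severity} {i.code} [{loc}]: {i.message}{obs}")
        return "\n".join(lines)


def _sorted(issues: Iterable[ValidationIssue]) -> list[ValidationIssue]:
    return sorted(issues, key=lambda i: (i.row, column_sort_key(i.column), i.code))


def check_header(headers: Iterable[str]) -> list[ValidationIssue]:
    """Header-level rules, on columns already harmonised to standard names.

    Mandatory columns (p_value, effect_allele, other_allele,
    effect_allele_frequency, standard_error) must be present; one form of
    variant identification (variant_id, or chromosome + base_pair_location)
    is mandatory; exactly one effect column (odds_ratio or beta) is allowed.
    """
    present = set(headers)
    issues: list[ValidationIssue] = []
    for col in ("p_value", "effect_allele", "other_allele", "effect_allele_frequency", "standard_error"):
        if col not in present:
            issues.append(issue("MISSING_MANDATORY", column=col))
    if "variant_id" not in present and not {"chromosome", "base_pair_location"} <= present:
        issues.append(issue("VARIANT_ID_RULE"))
    has_or, has_beta = "odds_ratio" in present, "beta" in present
    if has_or and has_beta:
        issues.append(issue("EFFECT_COLUMN_CONFLICT", column="effect"))
    elif not has_or and not has_beta:
        issues.append(issue("MISSING_MANDATORY", column="effect"))
    if ("ci_lower" in present) != ("ci_upper" in present):
        only = "ci_lower" if "ci_lower" in present else "ci_upper"
        issues.append(issue("CI_BOUND_SINGLE", column=only))
    return _sorted(issues)


def validate_record(
    record: SumStatsRecord,
    row: int,
    *,
    effect_column: str = "beta",
    eaf_optional: bool = False,
) -> list[ValidationIssue]:
    """Record-level value rules; ``row`` is the 1-based data-row number.

    ``eaf_optional`` exempts a missing effect_allele_frequency from
    MISSING_MANDATORY_VALUE — used when the study metadata declares a privacy
    profile that masks frequencies.
    """
    issues: list[ValidationIssue] = []
    r = record

    if r.p_value is None:
        issues.append(issue("MISSING_MANDATORY_VALUE", row, "p_value"))
    elif not r.p_value.is_probability():
        issues.append(issue("P_OUT_OF_RANGE", row, "p_value", observed=str(r.p_value)))

    for col, allele in (("effect_allele", r.effect_allele), ("other_allele", r.other_allele)):
        if allele is None:
            issues.append(issue("MISSING_MANDATORY_VALUE", row, col))
        elif not Allele.is_valid(allele):
            issues.append(issue("BAD_ALLELE", row, col, observed=allele))
    if (
        r.effect_allele is not None
        and r.other_allele is not None
        and Allele.is_valid(r.effect_allele)
        and Allele.is_valid(r.other_allele)
        and r.effect_allele == r.other_allele
    ):
        issues.append(issue("ALLELES_IDENTICAL", row, "other_allele", observed=r.other_allele))

    if r.effect_allele_frequency is None:
        if not eaf_optional:
            issues.append(issue("MISSING_MANDATORY_VALUE", row, "effect_allele_frequency"))
    elif not 0.0 <= r.effect_allele_frequency <= 1.0:
        issues.append(issue("EAF_OUT_OF_RANGE", row, "effect_allele_frequency", observed=r.effect_allele_frequency))

    if r.chromosome is not None and r.chromosome not in CHROMOSOMES:
        issues.append(issue("BAD_CHROMOSOME", row, "chromosome", observed=r.chromosome))
    if r.base_pair_location is not None and (
        not isinstance(r.base_pair_location, int) or r.base_pair_location <= 0
    ):
        issues.append(issue("BAD_POSITION", row, "base_pair_location", observed=r.base_pair_location))
    if r.variant_id is not None and not _RSID_RE.match(r.variant_id):
        issues.append(issue("BAD_RSID", row, "variant_id", observed=r.variant_id))

    if effect_column == "odds_ratio":
        if r.odds_ratio is None:
            issues.append(issue("MISSING_MANDATORY_VALUE", row, "odds_ratio"))
        elif r.odds_ratio <= 0:
            issues.append(issue("NONPOS_OR", row, "odds_ratio", observed=r.odds_ratio))
    else:
        if r.beta is None:
            issues.append(issue("MISSING_MANDATORY_VALUE", row, "beta"))

    if r.standard_error is None:
        issues.append(issue("MISSING_MANDATORY_VALUE", row, "standard_error"))
    elif r.standard_error < 0:
        issues.append(issue("NEG_SE", row, "standard_error", observed=r.standard_error))

    if r.ci_lower is not None and r.ci_upper is not None:
        if r.ci_lower > r.ci_upper:
            issues.append(issue("CI_ORDER", row, "ci_lower", observed=f"[{r.ci_lower}, {r.ci_upper}]"))
        elif effect_column == "odds_ratio" and (r.ci_lower <= 0 or r.ci_upper <= 0):
            issues.append(issue("CI_ORDER", row, "ci_lower", observed=f"[{r.ci_lower}, {r.ci_upper}]"))

    return _sorted(issues)


def validate_dataset(
    dataset: Dataset,
    metadata: Optional["StudyMetadata"] = None,
) -> ValidationReport:
    """Full conformance check: header rules + per-record rules + dataset rules.

    When ``metadata`` declares a frequency-masking privacy profile, missing
    effect_allele_frequency values are accepted (the column itself must still
    be present).  Issue ordering is deterministic: row, then column in the
    standard's printed order.
    """
    issues: list[ValidationIssue] = list(check_header(dataset.standard_columns()))

    eaf_optional = bool(
        metadata is not None
        and metadata.privacy_profile_applied
        and "mask_frequencies" in metadata.privacy_profile_applied
    )

    if not dataset.records:
        issues.append(issue("EMPTY_DATASET"))
    else:
        needs_build = any(r.variant_id is None for r in dataset.records)
        if needs_build and not dataset.genome_build:
            issues.append(issue("MISSING_GENOME_BUILD", column="genome_build"))

    effect_column = dataset.effect_type.column
    seen: dict[tuple, int] = {}
    for row, record in enumerate(dataset.records, start=1):
        issues.extend(
            validate_record(record, row, effect_column=effect_column, eaf_optional=eaf_optional)
        )
        key = (record.chromosome, record.base_pair_location, record.effect_allele, record.other_allele)
        if all(k is not None for k in key):
            if key in seen:
                issues.append(
                    issue(
                        "DUPLICATE_VARIANT",
                        row,
                        "variant_id",
                        message=f"duplicate of row {seen[key]}",
                        observed=f"{key[0]}:{key[1]} {key[2]}/{key[3]}",
                    )
                )
            else:
                seen[key] = row

    return ValidationReport(issues=_sorted(issues), records_checked=len(dataset.records))
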