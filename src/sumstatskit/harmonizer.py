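"""Dialect detection and harmonisation of foreign SumStats files.

GWAS tools emit summary statistics under dozens of header conventions.  The
harmonizer maps those onto the standard elements using a shipped,
case-insensitive alias table — and refuses to guess where conventions
genuinely conflict.  Headers like ``A1``/``A2`` mean "effect allele" in some
pipelines and "reference allele" in others; assigning them silently would
corrupt effect directions downstream, so they are surfaced as *ambiguous*
and require an explicit per-file override.

Division of labour: the harmonizer fixes representational quirks it can fix
safely (``chr1`` -> ``1``, lower-case alleles), with a warning each time; the
validator judges everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .core_model import Dataset, PValue, SumStatsError
from .standard_io import FileDescriptor, build_dataset, read_raw_table, write_standard
from .validator import ValidationIssue, check_header, issue


class HarmonizeError(SumStatsError):
    code = "HARMONIZE"


class HarmonizeAmbiguousError(HarmonizeError):
    """An unresolved ambiguous header blocks a mandatory element."""

    code = "HARMONIZE_AMBIGUOUS"


class MissingMandatoryError(HarmonizeError):
    """Mandatory standard elements are absent after mapping."""

    code = "MISSING_MANDATORY"

    def __init__(self, elements: Sequence[str]):
        self.elements = tuple(elements)
        super().__init__(f"mandatory elements absent after mapping: {', '.join(self.elements)}")


@dataclass(frozen=True)
class AliasTable:
    """Case-folded alias lookup loaded from YAML configuration."""

    assign: dict[str, str]  # folded source header -> standard element
    ambiguous: dict[str, tuple[str, ...]]  # folded header -> candidate elements

    @classmethod
    def load(cls, path: Union[str, Path, None] = None) -> "AliasTable":
        if path is None:
            text = (resources.files("sumstatskit") / "data" / "aliases.yaml").read_text(
                encoding="utf-8"
            )
        else:
            text = Path(path).read_text(encoding="utf-8")
        doc = yaml.safe_load(text)
        assign: dict[str, str] = {}
        for element, names in doc.get("aliases", {}).items():
            for name in names:
                assign[str(name).casefold()] = element
        ambiguous = {
            str(name).casefold(): tuple(candidates)
            for name, candidates in doc.get("ambiguous", {}).items()
        }
        return cls(assign=assign, ambiguous=ambiguous)


_DEFAULT_TABLE: Optional[AliasTable] = None


def default_alias_table() -> AliasTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AliasTable.load()
    return _DEFAULT_TABLE


@dataclass
class ColumnMapping:
    """Result of dialect detection for one header row."""

    assignments: dict[str, str] = field(default_factory=dict)  # source -> element
    ambiguous: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        elements = list(self.assignments.values())
        if len(elements) != len(set(elements)):
            raise HarmonizeError("a standard element is assigned to two source headers")
        amb = {h for h, _ in self.ambiguous}
        if amb & set(self.assignments):
            raise HarmonizeError("a header cannot be both assigned and ambiguous")


def detect_dialect(
    headers: Sequence[str], table: Optional[AliasTable] = None
) -> ColumnMapping:
    """Map a header row onto standard elements via the shipped alias table.

    Exact standard headers map to themselves; known aliases are assigned
    case-insensitively; declared-ambiguous headers are listed with their
    candidate elements and never auto-assigned; everything else is unmapped.
    If two headers claim the same element, the first (in file order) wins and
    later claimants are demoted to ambiguous.
    """
    if not headers:
        raise HarmonizeError("empty header row")
    folded = [h.casefold() for h in headers]
    if len(set(folded)) != len(folded):
        dupes = sorted({f for f in folded if folded.count(f) > 1})
        raise HarmonizeError(f"duplicate headers after case-folding: {', '.join(dupes)}")

    table = table or default_alias_table()
    assignments: dict[str, str] = {}
    taken: set[str] = set()
    ambiguous: list[tuple[str, tuple[str, ...]]] = []
    unmapped: list[str] = []
    for header, f in zip(headers, folded):
        if f in table.ambiguous:
            ambiguous.append((header, table.ambiguous[f]))
        elif f in table.assign:
            element = table.assign[f]
            if element in taken:
                ambiguous.append((header, (element,)))
            else:
                assignments[header] = element
                taken.add(element)
        else:
            unmapped.append(header)
    return ColumnMapping(assignments=assignments, ambiguous=ambiguous, unmapped=unmapped)


def _normalize_cells(
    headers: list[str],
    element_of: dict[int, str],
    rows: list[list[str]],
) -> list[ValidationIssue]:
    """In-place safe normalisations: chr prefixes, allele case."""
    issues: list[ValidationIssue] = []
    chrom_idx = [i for i, e in element_of.items() if e == "chromosome"]
    allele_idx = [(i, e) for i, e in element_of.items() if e in ("effect_allele", "other_allele")]
    for rownum, row in enumerate(rows, start=1):
        if len(row) != len(headers):
            continue
        for i in chrom_idx:
            cell = row[i]
            if cell.lower().startswith("chr") and cell not in ("chr", ""):
                row[i] = cell[3:]
                issues.append(issue("CHR_PREFIX_NORMALIZED", rownum, "chromosome", observed=cell))
        for i, element in allele_idx:
            cell = row[i]
            if cell not in ("", "NA") and cell != cell.upper():
                row[i] = cell.upper()
                issues.append(issue("ALLELE_CASE_NORMALIZED", rownum, element, observed=cell))
    return issues


def apply_mapping(
    table: tuple[list[str], list[list[str]]],
    mapping: ColumnMapping,
    overrides: Optional[dict[str, str]] = None,
    *,
    genome_build: Optional[str] = None,
    source_name: str = "",
    p_zero_floor: Optional[PValue] = None,
) -> tuple[Dataset, list[ValidationIssue]]:
    """Apply a (possibly overridden) column mapping to a raw table.

    ``overrides`` maps source headers to standard elements and is the only
    way to resolve ambiguous headers.  Raises
    :class:`HarmonizeAmbiguousError` when an unresolved ambiguity could
    supply a missing mandatory element, and :class:`MissingMandatoryError`
    when the merged assignment still lacks mandatory elements.
    """
    headers, rows = table
    overrides = dict(overrides or {})
    merged = dict(mapping.assignments)
    ambiguous_left: dict[str, tuple[str, ...]] = dict(mapping.ambiguous)
    for src, element in overrides.items():
        if src not in headers:
            raise HarmonizeError(f"override source {src!r} is not a column of this file")
        merged[src] = element
        ambiguous_left.pop(src, None)
    elements = list(merged.values())
    if len(elements) != len(set(elements)):
        raise HarmonizeError("overrides assign one standard element to two source headers")

    header_findings = check_header(elements)
    missing: list[str] = []
    missing_elements: set[str] = set()
    for f in header_findings:
        if f.code == "MISSING_MANDATORY":
            missing.append(f.column)
            missing_elements |= {"beta", "odds_ratio"} if f.column == "effect" else {f.column}
        elif f.code == "VARIANT_ID_RULE":
            missing.append("variant_id or chromosome+base_pair_location")
            missing_elements |= {"variant_id", "chromosome", "base_pair_location"}
    if missing:
        blocking = {
            h: cands
            for h, cands in ambiguous_left.items()
            if missing_elements & set(cands)
        }
        if blocking:
            detail = "; ".join(f"{h} -> one of {'/'.join(c)}" for h, c in sorted(blocking.items()))
            raise HarmonizeAmbiguousError(
                f"ambiguous headers need an explicit override before mandatory "
                f"elements can be satisfied: {detail}"
            )
        raise MissingMandatoryError(missing)
    if any(f.code == "EFFECT_COLUMN_CONFLICT" for f in header_findings):
        raise HarmonizeError("both odds_ratio and beta are mapped; exactly one effect scale per file")

    element_of = {headers.index(src): element for src, element in merged.items()}
    rows = [list(r) for r in rows]
    norm_issues = _normalize_cells(headers, element_of, rows)
    dataset, build_issues = build_dataset(
        headers,
        element_of,
        rows,
        genome_build=genome_build,
        source_name=source_name,
        p_zero_floor=p_zero_floor,
    )
    return dataset, norm_issues + build_issues


def harmonize_file(
    source: Union[FileDescriptor, str, Path],
    overrides: Optional[dict[str, str]] = None,
    *,
    alias_table: Optional[AliasTable] = None,
    genome_build: Optional[str] = None,
) -> tuple[Dataset, ColumnMapping, list[ValidationIssue]]:
    """Read a foreign-dialect file and return the harmonised dataset."""
    fd = source if isinstance(source, FileDescriptor) else FileDescriptor(path=source)
    headers, rows = read_raw_table(fd)
    mapping = detect_dialect(headers, alias_table)
    name = Path(fd.path).name if fd.path else ""
    dataset, issues = apply_mapping(
        (headers, rows), mapping, overrides, genome_build=genome_build, source_name=name
    )
    return dataset, mapping, issues
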