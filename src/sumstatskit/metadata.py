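"""Study metadata: schema, YAML/JSON serialisation, and rule-based validation.

The mandatory elements mirror what the community agreed a deposited GWAS must
describe about itself: who was studied (sample sizes, cases/controls,
ancestry, cohorts), what was measured and how (trait, measurement method,
inclusions/exclusions), and how the analysis was run (genotyping technology,
imputation method and panel, covariates, model, software, MAF cutoff, QC,
number of variants analysed).

Metadata live in a sidecar document (``<accession>-meta.yaml``) next to the
data file, keeping the SumStats file itself strictly tabular.  Parsing never
invents values: an absent field stays absent and validation is a separate,
pure step.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import IO, Optional, Union

import yaml

from .core_model import SumStatsError
from .validator import ValidationIssue, issue

ACCESSION_RE = re.compile(r"^GCST[0-9]{6,}$")
EFO_CURIE_RE = re.compile(r"^[A-Za-z]+_[0-9]+$")
GENOTYPING_TECHNOLOGIES = ("array", "WGS", "WES", "mixed")
DEFAULT_LICENSE = "CC0"


class MetadataParseError(SumStatsError):
    code = "META_PARSE"


def load_ancestry_vocabulary(path: Union[str, Path, None] = None) -> tuple[str, ...]:
    """Controlled ancestry categories; shipped list is editable configuration."""
    if path is None:
        text = (resources.files("sumstatskit") / "data" / "ancestry.yaml").read_text(
            encoding="utf-8"
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    return tuple(yaml.safe_load(text)["categories"])


@dataclass
class SampleGroup:
    """One analysed sample stratum."""

    n_total: Optional[int] = None
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    ancestry_category: Optional[str] = None
    cohort_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v is not None and v != []:
                d[f.name] = v
        return d

    @classmethod
    def from_dict(cls, doc: dict) -> tuple["SampleGroup", list[str]]:
        known = {f.name for f in dc_fields(cls)}
        unknown = [k for k in doc if k not in known]
        return cls(**{k: v for k, v in doc.items() if k in known}), unknown


@dataclass
class StudyMetadata:
    """All study-level descriptors for one GWAS SumStats dataset.

    Every field defaults to absent; :func:`validate_metadata` decides which
    absences are errors.  ``extras`` preserves unknown keys verbatim so a
    round trip is lossless.
    """

    accession: Optional[str] = None
    trait_label: Optional[str] = None
    trait_efo_id: Optional[str] = None
    measurement_method: Optional[str] = None
    samples: list[SampleGroup] = field(default_factory=list)
    genotyping_technology: Optional[str] = None
    imputation_method: Optional[str] = None
    imputation_panel: Optional[str] = None
    covariates: Optional[list[str]] = None
    analysis_software: Optional[str] = None
    analysis_model: Optional[str] = None
    maf_cutoff: Optional[float] = None
    n_variants_analyzed: Optional[int] = None
    genome_build: Optional[str] = None
    qc_description: Optional[str] = None
    inclusion_exclusion: Optional[str] = None
    license: Optional[str] = None
    doi: Optional[str] = None
    pmid: Optional[str] = None
    is_partial: bool = False
    partial_reason: Optional[str] = None
    privacy_profile_applied: Optional[str] = None
    version: int = 1
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d: dict = {}
        for f in dc_fields(self):
            if f.name == "extras":
                continue
            v = getattr(self, f.name)
            if f.name == "samples":
                if v:
                    d["samples"] = [s.to_dict() for s in v]
                continue
            if f.name == "is_partial":
                if v:
                    d["is_partial"] = True
                continue
            if v is not None:
                d[f.name] = v
        d.update(self.extras)
        return d


#: (attribute, human label) pairs that must be present for valid metadata.
MANDATORY_FIELDS: tuple[tuple[str, str], ...] = (
    ("trait_label", "trait"),
    ("measurement_method", "trait measurement method"),
    ("genotyping_technology", "genotyping/sequencing technology"),
    ("imputation_method", "imputation method"),
    ("imputation_panel", "imputation reference panel"),
    ("covariates", "covariates"),
    ("analysis_software", "analysis software"),
    ("analysis_model", "analysis model"),
    ("maf_cutoff", "minor allele frequency cutoff"),
    ("n_variants_analyzed", "number of variants analyzed"),
    ("qc_description", "trait quality control"),
    ("inclusion_exclusion", "sample inclusions/exclusions"),
)


def validate_metadata(
    meta: StudyMetadata,
    ancestry_vocabulary: Optional[tuple[str, ...]] = None,
) -> list[ValidationIssue]:
    """Pure rule check over one metadata object (row is always 0)."""
    vocab = ancestry_vocabulary if ancestry_vocabulary is not None else load_ancestry_vocabulary()
    issues: list[ValidationIssue] = []

    for attr, label in MANDATORY_FIELDS:
        if getattr(meta, attr) is None:
            issues.append(issue("META_MISSING", column=attr, message=f"mandatory metadata element absent: {label}"))

    if not meta.samples:
        issues.append(issue("META_MISSING", column="samples", message="at least one sample group with size and ancestry is mandatory"))
    for i, s in enumerate(meta.samples):
        where = f"samples[{i}]"
        if s.n_total is None:
            issues.append(issue("META_MISSING", column=f"{where}.n_total"))
        elif s.n_total <= 0:
            issues.append(issue("META_BAD_VALUE", column=f"{where}.n_total", observed=s.n_total))
        if s.ancestry_category is None:
            issues.append(issue("META_MISSING", column=f"{where}.ancestry_category"))
        elif s.ancestry_category not in vocab:
            issues.append(issue("ANCESTRY_UNKNOWN", column=f"{where}.ancestry_category", observed=s.ancestry_category))
        if not s.cohort_names:
            issues.append(issue("META_MISSING", column=f"{where}.cohort_names", message="cohort descriptors are mandatory"))
        if s.n_cases is not None and s.n_controls is not None and s.n_total is not None:
            if s.n_cases + s.n_controls > s.n_total:
                issues.append(
                    issue(
                        "SAMPLE_COUNT_INCONSISTENT",
                        column=f"{where}",
                        observed=f"cases {s.n_cases} + controls {s.n_controls} > total {s.n_total}",
                    )
                )

    if meta.accession is not None and not ACCESSION_RE.match(meta.accession):
        issues.append(issue("ACCESSION_PATTERN", column="accession", observed=meta.accession))
    if meta.trait_efo_id is not None and not EFO_CURIE_RE.match(meta.trait_efo_id):
        issues.append(issue("EFO_PATTERN", column="trait_efo_id", observed=meta.trait_efo_id))
    if meta.genotyping_technology is not None and meta.genotyping_technology not in GENOTYPING_TECHNOLOGIES:
        issues.append(issue("META_BAD_VALUE", column="genotyping_technology", observed=meta.genotyping_technology))
    if meta.maf_cutoff is not None and not 0.0 <= meta.maf_cutoff <= 1.0:
        issues.append(issue("META_BAD_VALUE", column="maf_cutoff", observed=meta.maf_cutoff))
    if meta.is_partial and not meta.partial_reason:
        issues.append(issue("PARTIAL_REASON_MISSING", column="partial_reason"))
    if meta.version < 1:
        issues.append(issue("META_BAD_VALUE", column="version", observed=meta.version))

    return sorted(issues, key=lambda i: (i.column, i.code))


def read_metadata(
    source: Union[str, Path, IO[str]],
) -> tuple[StudyMetadata, list[ValidationIssue]]:
    """Parse a YAML (or JSON) metadata document.

    Unknown keys are preserved in ``extras`` with an UNKNOWN_METADATA_KEY
    warning.  No defaults are invented: validation is a separate step.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = "<stream>"
    else:
        text = Path(source).read_text(encoding="utf-8")
        name = str(source)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as err:
        mark = getattr(err, "problem_mark", None)
        loc = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise MetadataParseError(f"malformed metadata document {name}{loc}: {err}") from err
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise MetadataParseError(f"metadata document {name} must be a mapping, got {type(doc).__name__}")

    issues: list[ValidationIssue] = []
    known = {f.name for f in dc_fields(StudyMetadata)} - {"extras", "samples"}
    meta = StudyMetadata()
    extras: dict = {}
    for key, value in doc.items():
        if key == "samples":
            groups = []
            for i, sdoc in enumerate(value or []):
                group, unknown = SampleGroup.from_dict(sdoc or {})
                groups.append(group)
                for k in unknown:
                    issues.append(issue("UNKNOWN_METADATA_KEY", column=f"samples[{i}].{k}", observed=k))
            meta.samples = groups
        elif key in known:
            setattr(meta, key, value)
        else:
            extras[key] = value
            issues.append(issue("UNKNOWN_METADATA_KEY", column=key, observed=key))
    meta.extras = extras
    return meta, issues


def write_metadata(
    meta: StudyMetadata,
    dest: Union[str, Path, IO[str]],
    *,
    fmt: str = "yaml",
    apply_default_license: bool = False,
) -> int:
    """Serialise metadata deterministically (sorted keys); returns byte count.

    ``apply_default_license`` fills an absent license with CC0 at write time —
    the only place any default is ever applied, and only on request.
    """
    doc = meta.to_dict()
    if apply_default_license and "license" not in doc:
        doc["license"] = DEFAULT_LICENSE
    if fmt == "json":
        text = json.dumps(doc, indent=2, sort_keys=True) + "\n"
    else:
        text = yaml.safe_dump(doc, sort_keys=True, allow_unicode=True, default_flow_style=False)
    data = text.encode("utf-8")
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text, encoding="utf-8")
    return len(data)
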