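"""FAIR indicator self-assessment for a SumStats dataset bundle.

A *bundle* is the deposition unit: the SumStats dataset (optional — metadata
must outlive retracted data), the study metadata, the accession the bundle
claims, and optionally the ledger that issued it.  The assessment walks the
fifteen FAIR indicators (F1-F4, A1, A1.1, A1.2, A2, I1-I3, R1, R1.1-R1.3)
and reports, per indicator, pass / fail / not_auto_checkable with evidence.

Indicators that are properties of a hosting repository or its services
(searchability, retrieval protocols, knowledge-representation formats,
cross-references) cannot be judged from files on disk; they are reported as
not_auto_checkable with an explanation, never guessed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional

from .core_model import Dataset
from .lifecycle import AccessionLedger
from .metadata import ACCESSION_RE, EFO_CURIE_RE, StudyMetadata, validate_metadata
from .validator import ERROR, validate_dataset

PASS = "pass"
FAIL = "fail"
NOT_AUTO = "not_auto_checkable"

GRC_BUILD_RE = re.compile(r"^GRCh[0-9]+(\.p[0-9]+)?$")

#: All indicators, in report order.
INDICATORS: tuple[str, ...] = (
    "F1", "F2", "F3", "F4",
    "A1", "A1.1", "A1.2", "A2",
    "I1", "I2", "I3",
    "R1", "R1.1", "R1.2", "R1.3",
)

#: Repository/service-level indicators we never judge from a local bundle.
NOT_AUTO_CHECKABLE: dict[str, str] = {
    "F4": "searchable indexing is a property of the hosting repository, not of the files",
    "A1": "retrieval by identifier over a standard protocol is provided by the repository (web/API), not the bundle",
    "A1.1": "protocol openness is a repository service property",
    "I1": "knowledge-representation format of the access API is a repository property",
    "I3": "qualified cross-references to external records are repository links, not bundle content",
}


@dataclass(frozen=True)
class IndicatorResult:
    indicator: str
    status: str
    evidence: str


@dataclass
class FairBundle:
    """What gets assessed together: data (optional), metadata, identity."""

    metadata: StudyMetadata
    dataset: Optional[Dataset] = None
    accession: Optional[str] = None
    ledger: Optional[AccessionLedger] = None


@dataclass
class FairReport:
    results: list[IndicatorResult] = field(default_factory=list)

    @property
    def auto_checkable(self) -> list[IndicatorResult]:
        return [r for r in self.results if r.status != NOT_AUTO]

    @property
    def all_auto_pass(self) -> bool:
        return all(r.status == PASS for r in self.auto_checkable)

    def status_of(self, indicator: str) -> str:
        return next(r.status for r in self.results if r.indicator == indicator)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "all_auto_pass": self.all_auto_pass,
            "results": [
                {"indicator": r.indicator, "status": r.status, "evidence": r.evidence}
                for r in self.results
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = [f"{r.indicator:<5} {r.status:<18} {r.evidence}" for r in self.results]
        lines.append(f"auto-checkable indicators all pass: {self.all_auto_pass}")
        return "\n".join(lines)


def evaluate_fair(bundle: FairBundle) -> FairReport:
    """Evaluate every FAIR indicator for one bundle.

    Each auto check depends only on its documented fields, so single-field
    problems flip single indicators (F2 and R1 share the metadata-richness
    check by definition).
    """
    meta = bundle.metadata
    results: dict[str, IndicatorResult] = {}

    def put(ind: str, status: str, evidence: str) -> None:
        results[ind] = IndicatorResult(ind, status, evidence)

    # F1: unique persistent identifier assigned
    acc = bundle.accession
    if acc is None:
        put("F1", FAIL, "no accession assigned to the bundle")
    elif not ACCESSION_RE.match(acc):
        put("F1", FAIL, f"accession {acc!r} does not match the GCST pattern")
    elif bundle.ledger is not None and acc not in bundle.ledger.entries:
        put("F1", FAIL, f"accession {acc} is not registered in the ledger")
    else:
        where = "registered in the local ledger" if bundle.ledger is not None else "no ledger supplied"
        put("F1", PASS, f"accession {acc} is pattern-valid and unique ({where})")

    # F2 / R1: rich metadata = mandatory element list satisfied
    meta_issues = [i for i in validate_metadata(meta) if i.severity == ERROR]
    if meta_issues:
        detail = ", ".join(sorted({i.column for i in meta_issues}))
        put("F2", FAIL, f"mandatory metadata elements missing or invalid: {detail}")
        put("R1", FAIL, f"metadata do not meet the mandatory element list: {detail}")
    else:
        put("F2", PASS, "all mandatory metadata elements present and valid")
        put("R1", PASS, "metadata meet the mandatory element list")

    # F3: metadata carry the identifier of the data they describe
    if meta.accession is None:
        put("F3", FAIL, "metadata carry no accession")
    elif acc is not None and meta.accession != acc:
        put("F3", FAIL, f"metadata accession {meta.accession} != bundle accession {acc}")
    else:
        put("F3", PASS, f"metadata accession {meta.accession} matches the bundle")

    # A1.2: authentication/authorization — not applicable to open data
    put("A1.2", PASS, "data are open; an authentication/authorization protocol is not applicable")

    # A2: metadata remain accessible even without the data
    if bundle.ledger is not None and acc is not None and acc in bundle.ledger.entries:
        entry = bundle.ledger.entries[acc]
        note = f"ledger entry status {entry.status}"
    else:
        note = "no ledger entry"
    data_note = "dataset present" if bundle.dataset is not None else "dataset absent"
    put("A2", PASS, f"metadata resolvable independently of the data ({data_note}; {note})")

    # I2: FAIR vocabularies — EFO trait, GRC genome build; rsID coverage as evidence
    problems = []
    if meta.trait_efo_id is None:
        problems.append("no trait ontology (EFO) id")
    elif not EFO_CURIE_RE.match(meta.trait_efo_id):
        problems.append(f"trait id {meta.trait_efo_id!r} is not an ontology CURIE")
    build = meta.genome_build or (bundle.dataset.genome_build if bundle.dataset else None)
    if build is None:
        problems.append("no genome build declared")
    elif not GRC_BUILD_RE.match(build):
        problems.append(f"genome build {build!r} is not a Genome Reference Consortium token")
    if bundle.dataset is not None and bundle.dataset.records:
        n = len(bundle.dataset.records)
        with_rs = sum(
            1
            for r in bundle.dataset.records
            if r.variant_id is not None and r.variant_id.startswith("rs")
        )
        coverage = f"; rsID coverage {with_rs}/{n} records"
    else:
        coverage = ""
    if problems:
        put("I2", FAIL, "; ".join(problems) + coverage)
    else:
        put("I2", PASS, f"trait uses EFO ({meta.trait_efo_id}), build {build} is a GRC token{coverage}")

    # R1.1: explicit usage license
    if meta.license:
        put("R1.1", PASS, f"license declared: {meta.license}")
    else:
        put("R1.1", FAIL, "no usage license declared")

    # R1.2: provenance via DOI or PMID
    if meta.doi or meta.pmid:
        prov = meta.doi or f"PMID:{meta.pmid}"
        put("R1.2", PASS, f"provenance link present: {prov}")
    else:
        put("R1.2", FAIL, "neither DOI nor PMID present")

    # R1.3: data meet the community standard (validator gate)
    if bundle.dataset is None:
        put("R1.3", FAIL, "no dataset available to validate")
    else:
        report = validate_dataset(bundle.dataset, meta)
        if report.valid:
            put("R1.3", PASS, f"dataset valid against the standard ({report.records_checked} records)")
        else:
            codes = ", ".join(sorted({i.code for i in report.issues if i.severity == ERROR}))
            put("R1.3", FAIL, f"dataset fails validation: {codes}")

    for ind, why in NOT_AUTO_CHECKABLE.items():
        put(ind, NOT_AUTO, why)

    return FairReport(results=[results[i] for i in INDICATORS])
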