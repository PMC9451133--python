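"""Dataset lifecycle: local accession ledger and privacy-reduction transforms.

The ledger mimics the accessioning behaviour a central deposition resource
provides — unique ``GCST``-style identifiers issued at submission time,
content-addressed version chains, and retraction tombstones that keep the
accession and its full history resolvable — but it is deliberately *local*:
tokens are format-compatible yet namespaced as locally issued in metadata,
so the toolkit is fully testable without any service.

Persistence is an append-only JSON-lines operation log; replaying the log
reconstructs the ledger state exactly.

Privacy transforms implement the two mitigations recommended for sensitive
studies: withholding study-specific allele frequencies (the column is kept
for schema conformance, every value becomes missing) and reducing p-value
precision to a fixed number of significant digits.
"""

from __future__ import annotations

import copy
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

from .core_model import Dataset, SumStatsError, format_pvalue, PValue
from .metadata import StudyMetadata

logger = logging.getLogger(__name__)

ACTIVE = "active"
RETRACTED = "retracted"


class LedgerError(SumStatsError):
    code = "LEDGER"


class UnknownAccessionError(LedgerError):
    code = "UNKNOWN_ACCESSION"


class RetractedAccessionError(LedgerError):
    """New versions cannot be registered on a retracted accession."""

    code = "LIFECYCLE_RETRACTED"


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass
class LedgerVersion:
    number: int
    digest: str
    timestamp: str


@dataclass
class LedgerEntry:
    accession: str
    versions: list[LedgerVersion] = field(default_factory=list)
    status: str = ACTIVE
    retraction_reason: Optional[str] = None
    retraction_timestamp: Optional[str] = None

    @property
    def latest(self) -> Optional[int]:
        return self.versions[-1].number if self.versions else None

    def to_dict(self) -> dict:
        return {
            "accession": self.accession,
            "status": self.status,
            "retraction_reason": self.retraction_reason,
            "retraction_timestamp": self.retraction_timestamp,
            "versions": [
                {"number": v.number, "digest": v.digest, "timestamp": v.timestamp}
                for v in self.versions
            ],
        }


class AccessionLedger:
    """GCST-style identifier registry with versions and tombstones.

    Serial numbers start at 1 and are zero-padded to six digits, so tokens
    sort identically as strings and as numbers.  When a ``path`` is given,
    every state-changing operation appends one JSON line *before* mutating
    memory; a persistence failure therefore consumes no serial.
    """

    def __init__(self, path: Union[str, Path, None] = None):
        self.path = Path(path) if path is not None else None
        self.entries: dict[str, LedgerEntry] = {}
        self.next_serial: int = 1

    # -- persistence ----------------------------------------------------

    @classmethod
    def load(cls, path: Union[str, Path]) -> "AccessionLedger":
        """Rebuild ledger state by replaying the JSON-lines operation log."""
        ledger = cls(path)
        p = Path(path)
        if p.exists():
            with open(p, "r", encoding="utf-8") as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        ledger._apply(json.loads(line))
        return ledger

    def _append(self, event: dict) -> None:
        if self.path is None:
            return
        try:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(event, sort_keys=True) + "\n")
        except OSError as err:
            raise SumStatsError(f"ledger persistence failure: {err}") from err

    def _apply(self, event: dict) -> None:
        op = event["op"]
        if op == "assign":
            acc = event["accession"]
            self.entries[acc] = LedgerEntry(accession=acc)
            self.next_serial = int(acc[4:]) + 1
        elif op == "register_version":
            entry = self.entries[event["accession"]]
            entry.versions.append(
                LedgerVersion(event["number"], event["digest"], event["timestamp"])
            )
        elif op == "retract":
            entry = self.entries[event["accession"]]
            entry.status = RETRACTED
            entry.retraction_reason = event["reason"]
            entry.retraction_timestamp = event["timestamp"]
        else:  # pragma: no cover - future-proofing
            raise LedgerError(f"unknown ledger operation {op!r}")

    # -- operations -----------------------------------------------------

    def assign_accession(self) -> str:
        """Issue the next accession token, e.g. ``GCST000001``."""
        token = f"GCST{self.next_serial:06d}"
        event = {"op": "assign", "accession": token, "timestamp": _now()}
        self._append(event)
        self._apply(event)
        return token

    def register_version(self, accession: str, digest: str) -> int:
        """Append the next version with a content digest; returns its number."""
        entry = self._entry(accession)
        if entry.status == RETRACTED:
            raise RetractedAccessionError(
                f"{accession} is retracted ({entry.retraction_reason!r}); no new versions"
            )
        number = (entry.latest or 0) + 1
        event = {
            "op": "register_version",
            "accession": accession,
            "number": number,
            "digest": digest,
            "timestamp": _now(),
        }
        self._append(event)
        self._apply(event)
        return number

    def retract(self, accession: str, reason: str) -> LedgerEntry:
        """Tombstone an accession; the entry and its history stay resolvable."""
        entry = self._entry(accession)
        if entry.status == RETRACTED:
            logger.warning("accession %s is already retracted; retract is idempotent", accession)
            return entry
        event = {"op": "retract", "accession": accession, "reason": reason, "timestamp": _now()}
        self._append(event)
        self._apply(event)
        return entry

    def status(self, accession: str) -> LedgerEntry:
        """Resolve an accession; retracted entries carry the retraction indication."""
        return self._entry(accession)

    def latest(self, accession: str) -> Optional[int]:
        return self._entry(accession).latest

    def _entry(self, accession: str) -> LedgerEntry:
        try:
            return self.entries[accession]
        except KeyError:
            raise UnknownAccessionError(f"unknown accession {accession!r}") from None


def dataset_digest(dataset: Dataset) -> str:
    """SHA-256 of the canonical serialised bytes; versions are content-addressed."""
    from .standard_io import FileDescriptor, write_standard

    buf = io.StringIO()
    write_standard(dataset, FileDescriptor(stream=buf))
    return "sha256:" + hashlib.sha256(buf.getvalue().encode("utf-8")).hexdigest()


# -- privacy ---------------------------------------------------------------


@dataclass(frozen=True)
class PrivacyProfile:
    """Which privacy-reduction transforms to apply; at least one must be on."""

    mask_frequencies: bool = False
    p_sig_digits: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.mask_frequencies and self.p_sig_digits is None:
            raise ValueError("a privacy profile must enable at least one transform")
        if self.p_sig_digits is not None and self.p_sig_digits < 1:
            raise ValueError("p_sig_digits must be >= 1")

    def descriptor(self) -> str:
        parts = []
        if self.mask_frequencies:
            parts.append("mask_frequencies")
        if self.p_sig_digits is not None:
            parts.append(f"p_sig_digits={self.p_sig_digits}")
        return ";".join(parts)


def apply_privacy_profile(
    dataset: Dataset, meta: StudyMetadata, profile: PrivacyProfile
) -> tuple[Dataset, StudyMetadata]:
    """Return privacy-reduced copies of a dataset and its metadata.

    ``mask_frequencies`` blanks every effect_allele_frequency value (the
    column stays, for schema conformance).  ``p_sig_digits=k`` rounds every
    p-value half-even to k significant digits, which bounds the relative
    error by 0.5 * 10**(1 - k) and can merge but never reorder p-values.
    Everything else is untouched; the transform is idempotent.
    """
    out = copy.deepcopy(dataset)
    for record in out.records:
        if profile.mask_frequencies:
            record.effect_allele_frequency = None
        if profile.p_sig_digits is not None and record.p_value is not None:
            rounded = format_pvalue(record.p_value, profile.p_sig_digits)
            record.p_value = PValue.from_string(rounded)
    new_meta = copy.deepcopy(meta)
    new_meta.privacy_profile_applied = profile.descriptor()
    return out, new_meta
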