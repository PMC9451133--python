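"""Reader/writer for the standard tab-separated SumStats format.

The on-disk format is UTF-8, LF line endings, tab delimiter, a single header
row with the standard column tokens, one GWAS per file, ``NA`` for missing
values.  Files may be gzip-compressed (detected by a ``.gz`` suffix, or
forced through :class:`FileDescriptor`).

Reading is forgiving and transparent: every departure from the standard is
reported as a :class:`~sumstatskit.validator.ValidationIssue`, unknown
columns are preserved verbatim as auxiliary columns, and all parseable rows
are returned even when some rows fail.  Writing is canonical and
deterministic: identical datasets produce identical bytes.
"""

from __future__ import annotations

import csv
import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Optional, Union

from .core_model import (
    Dataset,
    EffectType,
    PValue,
    PValueParseError,
    PValueRangeError,
    SumStatsError,
    SumStatsRecord,
    STANDARD_COLUMNS,
    standard_column_order,
)
from .validator import ValidationIssue, issue

DEFAULT_TOP_THRESHOLD = PValue(1, -5)

MISSING = "NA"


class SumStatsIOError(SumStatsError):
    """Unreadable source, empty file, or unwritable destination."""

    code = "IO_ERROR"


class StructuralError(SumStatsError):
    """The file has no recognisable header row."""

    code = "NO_HEADER"


class EmptyDatasetError(SumStatsError):
    """Refusing to write a dataset with no records."""

    code = "EMPTY_DATASET"


@dataclass
class FileDescriptor:
    """Where to read/write and how.

    compression "auto" keys off a ``.gz`` path suffix.  ``sig_digits``
    controls p-value emission: an integer routes through
    :func:`~sumstatskit.core_model.format_pvalue`; None emits the stored
    mantissa at full precision (exact round trips).
    """

    path: Union[str, Path, None] = None
    stream: Optional[IO] = None
    compression: str = "auto"  # none | gzip | auto
    sig_digits: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sig_digits is not None and self.sig_digits < 1:
            raise ValueError("sig_digits must be >= 1")
        if self.path is None and self.stream is None:
            raise ValueError("need a path or a stream")

    def _gzipped(self) -> bool:
        if self.compression == "gzip":
            return True
        if self.compression == "none":
            return False
        return self.path is not None and str(self.path).endswith(".gz")

    def open_read(self) -> IO[str]:
        if self.stream is not None:
            return self.stream
        try:
            if self._gzipped():
                return gzip.open(self.path, "rt", encoding="utf-8", newline="")
            return open(self.path, "r", encoding="utf-8", newline="")
        except OSError as err:
            raise SumStatsIOError(f"cannot read {self.path}: {err}") from err

    def open_write(self) -> IO[str]:
        if self.stream is not None:
            return self.stream
        try:
            if self._gzipped():
                return gzip.open(self.path, "wt", encoding="utf-8", newline="")
            return open(self.path, "w", encoding="utf-8", newline="")
        except OSError as err:
            raise SumStatsIOError(f"cannot write {self.path}: {err}") from err


def _as_descriptor(source: Union[FileDescriptor, str, Path]) -> FileDescriptor:
    if isinstance(source, FileDescriptor):
        return source
    return FileDescriptor(path=source)


def read_raw_table(source: Union[FileDescriptor, str, Path]) -> tuple[list[str], list[list[str]]]:
    """Read a TSV into (headers, rows) without interpreting anything."""
    fd = _as_descriptor(source)
    fh = fd.open_read()
    try:
        reader = csv.reader(fh, delimiter="\t")
        table = [row for row in reader if row]
    finally:
        if fd.stream is None:
            fh.close()
    if not table:
        raise SumStatsIOError(f"empty file: {fd.path}")
    return table[0], table[1:]


# -- cell parsing -----------------------------------------------------------


def parse_cell(element: str, text: str, row: int):
    """Parse one cell for a standard element.

    Returns (value, issues).  A missing token gives (None, []).  Parse
    failures give (None, [ERROR issue]); range problems on p-values are
    reported here too (the cell is syntactically a number but not a
    probability, so no value is stored).
    """
    if text == MISSING:
        return None, []
    if text == "":
        return None, [issue("EMPTY_CELL", row, element)]
    if element in ("variant_id", "chromosome"):
        return text, []
    if element == "base_pair_location":
        try:
            return int(text), []
        except ValueError:
            return None, [issue("PARSE_ERROR", row, element, observed=text)]
    if element == "p_value":
        try:
            return PValue.from_string(text), []
        except PValueRangeError:
            return None, [issue("P_OUT_OF_RANGE", row, element, observed=text)]
        except PValueParseError:
            return None, [issue("P_PARSE", row, element, observed=text)]
    if element in ("effect_allele", "other_allele"):
        return text, []
    # remaining standard elements are plain floats
    try:
        return float(text), []
    except ValueError:
        return None, [issue("PARSE_ERROR", row, element, observed=text)]


def build_dataset(
    headers: list[str],
    element_of: dict[int, str],
    rows: list[list[str]],
    *,
    genome_build: Optional[str] = None,
    source_name: str = "",
    p_zero_floor: Optional[PValue] = None,
) -> tuple[Dataset, list[ValidationIssue]]:
    """Assemble a Dataset from a raw table and a column-index -> element map.

    Columns without an element mapping are preserved as auxiliary.  Shared by
    the standard reader and the harmonizer so both produce identical datasets
    for identical semantics.
    """
    issues: list[ValidationIssue] = []
    aux_indices = [i for i in range(len(headers)) if i not in element_of]
    aux: dict[str, list[Optional[str]]] = {headers[i]: [] for i in aux_indices}

    present = [element_of[i] for i in sorted(element_of)]
    if "odds_ratio" in present and "beta" not in present:
        effect_type = EffectType.ODDS_RATIO
    else:
        effect_type = EffectType.BETA
    ordered = [c for c in standard_column_order(effect_type) if c in present]
    # keep any off-order extras (e.g. both effect columns) so nothing is dropped
    ordered += [c for c in present if c not in ordered]

    records: list[SumStatsRecord] = []
    for rownum, row in enumerate(rows, start=1):
        if len(row) != len(headers):
            issues.append(
                issue("ROW_FIELD_COUNT", rownum, message=f"expected {len(headers)} fields, got {len(row)}")
            )
            continue
        record = SumStatsRecord()
        for idx, element in element_of.items():
            value, cell_issues = parse_cell(element, row[idx], rownum)
            if (
                value is None
                and p_zero_floor is not None
                and element == "p_value"
                and any(i.code == "P_OUT_OF_RANGE" for i in cell_issues)
                and _is_zero_numeral(row[idx])
            ):
                value = p_zero_floor
                cell_issues = [issue("P_ZERO_FLOORED", rownum, element, observed=row[idx])]
            issues.extend(cell_issues)
            setattr(record, element, value)
        records.append(record)
        for i in aux_indices:
            aux[headers[i]].append(None if row[i] == MISSING else row[i])

    dataset = Dataset(
        records=records,
        effect_type=effect_type,
        genome_build=genome_build,
        auxiliary_columns=aux,
        source_name=source_name,
        columns=tuple(ordered),
    )
    return dataset, issues


def _is_zero_numeral(text: str) -> bool:
    try:
        from decimal import Decimal

        return Decimal(text) == 0
    except Exception:
        return False


def read_standard(
    source: Union[FileDescriptor, str, Path],
    *,
    genome_build: Optional[str] = None,
    p_zero_floor: Optional[PValue] = None,
) -> tuple[Dataset, list[ValidationIssue]]:
    """Read a standard-format SumStats file.

    Recognises exactly the standard column headers; anything else is kept as
    an auxiliary column with an UNKNOWN_COLUMN warning.  ``NA`` maps to
    missing.  Structural problems (ragged rows, duplicate headers, empty
    cells) are reported as issues; all parseable records are returned.

    ``p_zero_floor`` optionally maps an explicit ``0`` p-value to a floor
    (with a warning) instead of dropping it with P_OUT_OF_RANGE.
    """
    fd = _as_descriptor(source)
    headers, rows = read_raw_table(fd)

    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    element_of: dict[int, str] = {}
    for idx, header in enumerate(headers):
        if header in seen:
            issues.append(issue("DUPLICATE_HEADER", 0, header, observed=header))
            continue
        seen.add(header)
        if header in STANDARD_COLUMNS:
            element_of[idx] = header
        else:
            issues.append(issue("UNKNOWN_COLUMN", 0, header, observed=header))

    if not element_of:
        raise StructuralError(
            f"no standard column headers found in {fd.path}; is the header row present?"
        )

    name = Path(fd.path).name if fd.path else ""
    dataset, build_issues = build_dataset(
        headers,
        element_of,
        rows,
        genome_build=genome_build,
        source_name=name,
        p_zero_floor=p_zero_floor,
    )
    return dataset, issues + build_issues


# -- writing ----------------------------------------------------------------


def _format_float(value: float) -> str:
    return repr(float(value))


def format_cell(element: str, value, sig_digits: Optional[int]) -> str:
    if value is None:
        return MISSING
    if element == "p_value":
        if sig_digits is None:
            return str(value)
        from .core_model import format_pvalue

        return format_pvalue(value, sig_digits)
    if element == "base_pair_location":
        return str(int(value))
    if element in ("variant_id", "chromosome", "effect_allele", "other_allele"):
        return str(value)
    return _format_float(value)


def write_standard(dataset: Dataset, dest: Union[FileDescriptor, str, Path]) -> int:
    """Write a dataset in canonical standard form; returns bytes written.

    Standard columns first in the printed order (with the dataset's effect
    column), then auxiliary columns in their preserved order; missing values
    as ``NA``.  Output is byte-deterministic.
    """
    if not dataset.records:
        raise EmptyDatasetError("refusing to write a dataset with no records")
    fd = _as_descriptor(dest)

    columns = list(dataset.standard_columns())
    aux_names = list(dataset.auxiliary_columns)

    buf = io.StringIO()
    buf.write("\t".join(columns + aux_names) + "\n")
    for rownum, record in enumerate(dataset.records):
        cells = [
            format_cell(c, getattr(record, c), fd.sig_digits) for c in columns
        ]
        for name in aux_names:
            col = dataset.auxiliary_columns[name]
            v = col[rownum] if rownum < len(col) else None
            cells.append(MISSING if v is None else str(v))
        buf.write("\t".join(cells) + "\n")

    data = buf.getvalue().encode("utf-8")
    fh = fd.open_write()
    try:
        fh.write(buf.getvalue())
    finally:
        if fd.stream is None:
            fh.close()
    return len(data)


def extract_top_associations(
    dataset: Dataset, threshold: PValue = DEFAULT_TOP_THRESHOLD
) -> Dataset:
    """Records with p strictly below ``threshold`` (default 1e-5), in order.

    The default matches the conventional "top association" cut-off used for
    reporting suggestive GWAS hits.
    """
    keep = [
        i
        for i, r in enumerate(dataset.records)
        if r.p_value is not None and r.p_value < threshold
    ]
    return Dataset(
        records=[dataset.records[i] for i in keep],
        effect_type=dataset.effect_type,
        genome_build=dataset.genome_build,
        auxiliary_columns={
            name: [col[i] if i < len(col) else None for i in keep]
            for name, col in dataset.auxiliary_columns.items()
        },
        source_name=dataset.source_name,
        columns=dataset.columns,
    )
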