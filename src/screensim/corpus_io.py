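"""Read, validate, deduplicate and write labeled bibliographic corpora.

A corpus is an ordered collection of records, one per publication, each
carrying a title, an abstract and a set of three-state relevance labels
(relevant / irrelevant / missing) attached to named label columns.  Label
columns play screening-stage roles: two independent title-abstract raters
(typically clinicians), their consolidated decision, a research
methodologist's re-evaluation, and the final full-text inclusion.

Supported on-disk formats are a canonical CSV schema and (read-only) RIS
reference files.  Preprocessing removes records without an abstract and
collapses duplicate titles, mirroring the cleaning usually applied before
a screening-prioritization run.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .exceptions import ConfigurationError, EmptyCorpusError, ValidationError

#: Canonical CSV label columns, in on-disk order.
CANONICAL_LABEL_COLUMNS = (
    "label_clinician1",
    "label_clinician2",
    "label_clinician",
    "label_methodologist",
    "label_fulltext",
)

#: Columns the synthetic generator adds on top of the canonical schema.
TRUTH_COLUMN = "truth"

_LABEL_TOKENS = {
    "": None,
    "NA": None,
    "0": 0,
    "1": 1,
}


@dataclass(frozen=True)
class Record:
    """One publication: identifier, title, abstract and three-state labels.

    ``labels`` maps a label-column name to 1 (relevant), 0 (irrelevant) or
    ``None`` (missing).
    """

    record_id: str
    title: str
    abstract: str
    labels: dict[str, int | None] = field(default_factory=dict)

    @property
    def text(self) -> str:
        """Model text: title and abstract concatenated, title first."""
        return f"{self.title} {self.abstract}".strip()


@dataclass
class Corpus:
    """An ordered list of records plus provenance and stage-column names."""

    records: list[Record]
    stage_columns: list[str] = field(default_factory=list)
    source: str | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValidationError(f"duplicate record_id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def texts(self) -> list[str]:
        return [r.text for r in self.records]

    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def labels(self, column: str) -> list[int | None]:
        """Three-state label vector for one column, in record order."""
        return [r.labels.get(column) for r in self.records]

    def with_column(self, column: str, values: list[int | None]) -> "Corpus":
        """Return a copy with ``column`` set (or replaced) on every record."""
        if len(values) != len(self.records):
            raise ValidationError(
                f"column {column!r}: {len(values)} values for {len(self.records)} records"
            )
        records = [
            replace(r, labels={**r.labels, column: v})
            for r, v in zip(self.records, values)
        ]
        cols = list(self.stage_columns)
        if column not in cols:
            cols.append(column)
        return Corpus(records, cols, self.source, list(self.log))


def _parse_label(cell: str, row: int, column: str) -> int | None:
    token = cell.strip()
    if token in _LABEL_TOKENS:
        return _LABEL_TOKENS[token]
    # accept float renderings of 0/1 that spreadsheets produce
    if token in {"0.0", "1.0"}:
        return int(float(token))
    raise ValidationError(
        f"unparseable label {cell!r} in column {column!r}, row {row}"
    )


def _normalize_title(title: str) -> str:
    """Case-fold and collapse punctuation/whitespace for duplicate detection."""
    return re.sub(r"[\W_]+", " ", title.casefold()).strip()


def read_corpus(
    path,
    format: str = "csv",
    column_map: dict[str, str] | None = None,
) -> Corpus:
    """Read a labeled corpus from ``path``.

    Parameters
    ----------
    path
        CSV or RIS file.
    format
        ``"csv"`` or ``"ris"``.
    column_map
        Maps canonical names (``record_id``, ``title``, ``abstract`` and
        label columns) to the columns actually present in the file.
        Canonical columns found in the file are picked up automatically.

    Returns
    -------
    Corpus
        One record per row/entry, input order preserved.  Label cells are
        mapped 1 -> relevant, 0 -> irrelevant, empty/NA -> missing.
    """
    if format == "csv":
        return _read_csv(path, column_map or {})
    if format == "ris":
        return _read_ris(path)
    raise ConfigurationError(f"unknown corpus format {format!r}")


def _read_csv(path, column_map: dict[str, str]) -> Corpus:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)

    def resolve(canonical: str) -> str | None:
        actual = column_map.get(canonical, canonical)
        if canonical in column_map and actual not in frame.columns:
            raise ConfigurationError(
                f"mapped column {actual!r} (for {canonical!r}) not in {path}"
            )
        return actual if actual in frame.columns else None

    title_col = resolve("title")
    abstract_col = resolve("abstract")
    if title_col is None or abstract_col is None:
        raise ConfigurationError(
            f"{path}: need title and abstract columns (have {list(frame.columns)})"
        )
    id_col = resolve("record_id")

    label_cols: dict[str, str] = {}
    for canonical in CANONICAL_LABEL_COLUMNS + (TRUTH_COLUMN,):
        actual = resolve(canonical)
        if actual is not None:
            label_cols[canonical] = actual
    # any extra mapped label columns beyond the canonical set
    for canonical, actual in column_map.items():
        if canonical.startswith("label_") and canonical not in label_cols:
            if actual not in frame.columns:
                raise ConfigurationError(f"mapped column {actual!r} not in {path}")
            label_cols[canonical] = actual

    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        row = dict(zip(frame.columns, row))
        rid = row[id_col].strip() if id_col else str(i)
        labels = {
            canonical: _parse_label(row[actual], i, actual)
            for canonical, actual in label_cols.items()
        }
        records.append(
            Record(rid, row[title_col].strip(), row[abstract_col].strip(), labels)
        )
    return Corpus(records, list(label_cols), source=str(path))


_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def _read_ris(path) -> Corpus:
    """Minimal RIS reader: TI -> title, AB -> abstract, ID -> record_id.

    Records end at the ER tag; untagged lines continue the previous tag.
    Labels are not representable in RIS and come back missing everywhere.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    records: list[Record] = []
    entry: dict[str, str] = {}
    last_tag: str | None = None
    saw_tag = False

    def flush() -> None:
        nonlocal entry
        if entry:
            rid = entry.get("ID", str(len(records)))
            records.append(
                Record(rid.strip(), entry.get("TI", "").strip(), entry.get("AB", "").strip())
            )
        entry = {}

    for line in lines:
        m = _RIS_TAG.match(line)
        if m:
            saw_tag = True
            tag, value = m.group(1), m.group(2)
            if tag == "ER":
                flush()
                last_tag = None
            else:
                entry[tag] = (entry[tag] + " " + value).strip() if tag in entry else value
                last_tag = tag
        elif line.strip() and last_tag:
            entry[last_tag] = (entry[last_tag] + " " + line.strip()).strip()
    flush()

    if not saw_tag:
        raise ConfigurationError(f"{path}: no RIS tags found")
    if not any(r.title for r in records):
        raise ConfigurationError(f"{path}: no TI (title) tags found")
    return Corpus(records, [], source=str(path))


def preprocess(corpus: Corpus) -> Corpus:
    """Drop records without an abstract; collapse duplicate titles.

    A record is kept when its abstract contains non-whitespace text and no
    earlier surviving record shares its normalized title (case-folded,
    punctuation and whitespace collapsed).  Removals are appended to the
    provenance log.  Idempotent, and never alters surviving records.
    """
    if not corpus.records:
        raise EmptyCorpusError("cannot preprocess an empty corpus")

    log = list(corpus.log)
    survivors: list[Record] = []
    seen_titles: set[str] = set()
    for record in corpus.records:
        if not record.abstract.strip():
            log.append(f"removed {record.record_id}: missing abstract")
            continue
        key = _normalize_title(record.title)
        if key in seen_titles:
            log.append(f"removed {record.record_id}: duplicate title")
            continue
        seen_titles.add(key)
        survivors.append(record)

    if not survivors:
        raise EmptyCorpusError("preprocessing removed every record")
    return Corpus(survivors, list(corpus.stage_columns), corpus.source, log)


def write_corpus(corpus: Corpus, path, format: str = "csv") -> None:
    """Write ``corpus`` as canonical CSV; round-trips through read_corpus.

    Missing labels are written as empty cells, never as 0.
    """
    if format != "csv":
        raise ConfigurationError(f"unsupported write format {format!r}")
    label_cols = list(corpus.stage_columns)
    rows = []
    for r in corpus.records:
        row = {"record_id": r.record_id, "title": r.title, "abstract": r.abstract}
        for col in label_cols:
            value = r.labels.get(col)
            row[col] = "" if value is None else str(int(value))
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["record_id", "title", "abstract", *label_cols])
    frame.to_csv(path, index=False)
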