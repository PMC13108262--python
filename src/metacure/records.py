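"""Metadata records and their readers/writers.

A :class:`MetadataRecord` is an ordered list of (field name, field value)
pairs plus an optional free-text description block, as found in NCBI
sample repositories. Three serializations are supported:

* BioSample attribute XML (the NCBI dialect: ``<BioSample>`` elements with
  ``<Attribute>`` children),
* GEO SOFT (line-oriented ``^SAMPLE`` blocks with ``!Sample_* = value``
  lines),
* a JSONL interchange dialect (one record per line) used as the pipeline's
  canonical corpus format.

Malformed BioSample entries are skipped and counted rather than aborting
the read, mirroring how corpora are assembled in practice (records with
XML formatting errors are removed, not fatal).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from lxml import etree

from ._text import normalize

__all__ = [
    "MetadataRecord",
    "RecordReadError",
    "ReadResult",
    "read_biosample_xml",
    "read_geo_soft",
    "read_jsonl",
    "write_jsonl",
]

SOURCES = ("biosample", "geo", "synthetic")


class RecordReadError(ValueError):
    """Raised when an input file yields no usable records."""


@dataclass
class MetadataRecord:
    """One sample's metadata: ordered field name/value pairs.

    Duplicate field names are permitted (multi-valued attributes) and pair
    order is preserved. ``description`` holds GEO-style long free text.
    """

    record_id: str
    source: str = "synthetic"
    pairs: list[tuple[str, str]] = field(default_factory=list)
    description: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        for name, _ in self.pairs:
            if not name:
                raise ValueError(f"record {self.record_id}: empty field name")

    def values(self, name: str) -> list[str]:
        """All values whose canonical field name matches ``name``."""
        key = normalize(name)
        return [v for n, v in self.pairs if normalize(n) == key]

    def first(self, name: str) -> Optional[str]:
        vals = self.values(name)
        return vals[0] if vals else None

    @property
    def is_empty(self) -> bool:
        return not self.pairs and not (self.description or "").strip()

    def replace_pairs(self, pairs: list[tuple[str, str]]) -> "MetadataRecord":
        return MetadataRecord(
            record_id=self.record_id,
            source=self.source,
            pairs=list(pairs),
            description=self.description,
        )


class ReadResult(list):
    """A list of records that also carries the count of skipped entries."""

    def __init__(self, records: list[MetadataRecord], skipped: int = 0):
        super().__init__(records)
        self.skipped = skipped


_BIOSAMPLE_OPEN = re.compile(r"<BioSample[\s>]")
_BIOSAMPLE_ELEM = re.compile(r"<BioSample[\s>].*?</BioSample>", re.DOTALL)


def _record_from_biosample(elem: etree._Element) -> MetadataRecord:
    accession = elem.get("accession") or elem.get("id")
    if not accession:
        ids = elem.findall(".//Id")
        for node in ids:
            if node.text and node.text.strip():
                accession = node.text.strip()
                break
    if not accession:
        raise ValueError("BioSample element without accession or id")
    pairs: list[tuple[str, str]] = []
    for attr in elem.findall(".//Attribute"):
        name = (
            attr.get("harmonized_name")
            or attr.get("display_name")
            or attr.get("attribute_name")
        )
        if not name:
            continue
        pairs.append((name, (attr.text or "").strip()))
    description = None
    para = elem.find(".//Description/Comment/Paragraph")
    if para is not None and para.text and para.text.strip():
        description = para.text.strip()
    return MetadataRecord(
        record_id=accession, source="biosample", pairs=pairs, description=description
    )


def read_biosample_xml(path: str | Path) -> ReadResult:
    """Read BioSample attribute XML; skip-and-count malformed entries.

    Each complete ``<BioSample>`` element becomes one record; attributes
    map to pairs using their harmonized name when present, display name
    otherwise. Truncated or unparseable elements are counted in
    ``result.skipped``. A file containing openings but zero well-formed
    records raises :class:`RecordReadError` (distinct message from a file
    with no BioSample elements at all).
    """
    path = Path(path)
    if not path.exists():
        raise RecordReadError(f"file not found: {path}")
    text = path.read_text(encoding="utf-8", errors="replace")
    n_open = len(_BIOSAMPLE_OPEN.findall(text))
    if n_open == 0:
        raise RecordReadError(f"{path}: no BioSample elements found")
    records: list[MetadataRecord] = []
    complete = _BIOSAMPLE_ELEM.findall(text)
    skipped = n_open - len(complete)
    for chunk in complete:
        try:
            elem = etree.fromstring(chunk.encode("utf-8"))
            records.append(_record_from_biosample(elem))
        except (etree.XMLSyntaxError, ValueError):
            skipped += 1
    if not records:
        raise RecordReadError(
            f"{path}: zero well-formed BioSample records ({skipped} malformed skipped)"
        )
    return ReadResult(records, skipped=skipped)


_CHAR_KEY = re.compile(r"^!Sample_characteristics(?:_ch\d+)?$", re.IGNORECASE)


def read_geo_soft(path: str | Path) -> ReadResult:
    """Read GEO SOFT sample blocks.

    ``!Sample_characteristics_ch1 = tissue: X`` lines split on the first
    colon into a (tissue, X) pair (field name trimmed + case-folded);
    characteristic lines without a colon are kept verbatim under the
    ``characteristics_ch1`` field name. ``!Sample_description`` lines feed
    the free-text block; other ``!Sample_<key>`` lines become pairs named
    by the key suffix.
    """
    path = Path(path)
    if not path.exists():
        raise RecordReadError(f"file not found: {path}")
    records: list[MetadataRecord] = []
    current_id: Optional[str] = None
    pairs: list[tuple[str, str]] = []
    desc_lines: list[str] = []

    def flush() -> None:
        nonlocal current_id, pairs, desc_lines
        if current_id is not None:
            records.append(
                MetadataRecord(
                    record_id=current_id,
                    source="geo",
                    pairs=pairs,
                    description="\n".join(desc_lines) if desc_lines else None,
                )
            )
        current_id, pairs, desc_lines = None, [], []

    for raw in path.read_text(encoding="utf-8", errors="replace").splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("^SAMPLE"):
            flush()
            _, _, ident = line.partition("=")
            current_id = ident.strip() or "unnamed-sample"
            continue
        if current_id is None or not line.startswith("!"):
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if _CHAR_KEY.match(key):
            fname, sep, fvalue = value.partition(":")
            if sep:
                pairs.append((normalize(fname), fvalue.strip()))
            else:
                # unparseable characteristic: keep raw under the key suffix
                pairs.append((key[len("!Sample_"):].lower(), value))
        elif key.lower() == "!sample_description":
            desc_lines.append(value)
        elif key.startswith("!Sample_"):
            pairs.append((key[len("!Sample_"):], value))
    flush()
    if not records:
        raise RecordReadError(f"{path}: no ^SAMPLE blocks found")
    return ReadResult(records, skipped=0)


def write_jsonl(records: list[MetadataRecord], path: str | Path) -> int:
    """Write records to JSONL; returns the number of lines written."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "record_id": rec.record_id,
                "source": rec.source,
                "pairs": [[n, v] for n, v in rec.pairs],
            }
            if rec.description is not None:
                obj["description"] = rec.description
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    return len(records)


def read_jsonl(path: str | Path) -> list[MetadataRecord]:
    """Read a JSONL corpus; parse errors report the offending line number."""
    path = Path(path)
    if not path.exists():
        raise RecordReadError(f"file not found: {path}")
    records: list[MetadataRecord] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise RecordReadError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            try:
                records.append(
                    MetadataRecord(
                        record_id=obj["record_id"],
                        source=obj.get("source", "synthetic"),
                        pairs=[(n, v) for n, v in obj.get("pairs", [])],
                        description=obj.get("description"),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise RecordReadError(f"{path}:{lineno}: invalid record: {exc}") from exc
    return records


def iter_jsonl(path: str | Path) -> Iterator[MetadataRecord]:
    yield from read_jsonl(path)
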