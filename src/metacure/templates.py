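"""Machine-readable metadata templates and repository data dictionaries.

Two kinds of symbolic knowledge source are modeled:

* :class:`Template` — a CEDAR-style structured template: an ordered set of
  field specifications, each with a data-type restriction (string, integer,
  date) and optionally an enumerated permissible-value set whose terms may
  be tagged with a source vocabulary (e.g. an UBERON branch for tissue
  terms) and a usage frequency.
* :class:`DataDictionary` — a repository data dictionary: field names with
  descriptions and free-form format strings, but *no* permissible-value
  enumeration. The absence of value sets is the property that distinguishes
  a dictionary from a template.

Both are serialized as plain text (a small JSON dialect for templates,
TSV or JSON for dictionaries); see ``data/template.schema.json`` for a
reference description of the template dialect.

Value compliance is checked by :func:`validate_value`, which applies the
data-type restriction and then set membership under the package-wide
normalization rule (NFC + trim + case-fold; see :mod:`metacure._text`).
All outcomes are :class:`ComplianceVerdict` values — validation never
raises for a merely bad value.
"""

from __future__ import annotations

import datetime
import enum
import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

from ._text import normalize

__all__ = [
    "Datatype",
    "PermissibleValue",
    "FieldSpec",
    "Template",
    "DictionaryEntry",
    "DataDictionary",
    "VerdictStatus",
    "ComplianceVerdict",
    "TemplateError",
    "load_template",
    "write_template",
    "load_data_dictionary",
    "validate_value",
]


class TemplateError(ValueError):
    """Raised for malformed template or data-dictionary files."""


class Datatype(str, enum.Enum):
    string = "string"
    integer = "integer"
    date = "date"


class PermissibleValue(BaseModel):
    """One allowed term for a value-restricted field.

    ``vocabulary`` and ``term_id`` identify the controlled vocabulary the
    term was drawn from (e.g. ``"UBERON"``, ``"UBERON:0002048"``);
    ``frequency`` is an optional observed usage frequency in [0, 1].
    """

    term: str
    vocabulary: Optional[str] = None
    term_id: Optional[str] = None
    frequency: Optional[float] = Field(default=None, ge=0.0, le=1.0)

    @field_validator("term")
    @classmethod
    def _term_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("permissible value term must be non-empty")
        return v


class FieldSpec(BaseModel):
    """Specification of one metadata field.

    ``permissible_values`` is ``None`` for an unrestricted field; when
    present, terms must be unique after normalization.
    """

    name: str
    description: str = ""
    datatype: Datatype = Datatype.string
    required: bool = False
    permissible_values: Optional[list[PermissibleValue]] = None

    @field_validator("name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("field name must be non-empty")
        return v

    @model_validator(mode="after")
    def _unique_terms(self) -> "FieldSpec":
        if self.permissible_values is not None:
            seen: set[str] = set()
            for pv in self.permissible_values:
                key = normalize(pv.term)
                if key in seen:
                    raise ValueError(
                        f"field {self.name!r}: duplicate permissible value "
                        f"{pv.term!r} after normalization"
                    )
                seen.add(key)
        return self

    @property
    def restricted(self) -> bool:
        return self.permissible_values is not None

    def term_index(self) -> dict[str, str]:
        """Mapping normalized term -> canonical (as-stored) term."""
        if self.permissible_values is None:
            return {}
        return {normalize(pv.term): pv.term for pv in self.permissible_values}


class Template(BaseModel):
    """Ordered collection of field specifications."""

    name: str
    provenance: str = ""
    fields: list[FieldSpec]

    @model_validator(mode="after")
    def _check(self) -> "Template":
        if not self.fields:
            raise ValueError("template must contain at least one field")
        seen: set[str] = set()
        for spec in self.fields:
            key = normalize(spec.name)
            if key in seen:
                raise ValueError(f"duplicate field name {spec.name!r} in template")
            seen.add(key)
        return self

    def field(self, name: str) -> Optional[FieldSpec]:
        """Look up a field spec by canonical (normalized) name."""
        key = normalize(name)
        for spec in self.fields:
            if normalize(spec.name) == key:
                return spec
        return None

    def validate_pair(self, name: str, value: str) -> "ComplianceVerdict":
        """Verdict for a (field name, value) pair; unknown fields flagged."""
        spec = self.field(name)
        if spec is None:
            return ComplianceVerdict(
                status=VerdictStatus.unknown_field,
                message=f"field {name!r} is not defined in template {self.name!r}",
            )
        return validate_value(spec, value)


class DictionaryEntry(BaseModel):
    """One data-dictionary row: name, prose description, format string."""

    name: str
    description: str = ""
    format: str = ""
    examples: list[str] = Field(default_factory=list)

    @field_validator("name")
    @classmethod
    def _name_nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("dictionary entry name must be non-empty")
        return v


class DataDictionary(BaseModel):
    """Ordered data dictionary; order is preserved for prompt construction."""

    name: str = "data dictionary"
    entries: list[DictionaryEntry]

    @model_validator(mode="after")
    def _check(self) -> "DataDictionary":
        if not self.entries:
            raise ValueError("data dictionary must contain at least one entry")
        seen: set[str] = set()
        for e in self.entries:
            key = normalize(e.name)
            if key in seen:
                raise ValueError(f"duplicate entry name {e.name!r} in data dictionary")
            seen.add(key)
        return self


class VerdictStatus(str, enum.Enum):
    ok = "ok"
    datatype_violation = "datatype_violation"
    not_in_value_set = "not_in_value_set"
    unknown_field = "unknown_field"


class ComplianceVerdict(BaseModel):
    """Outcome of checking one value against one field specification.

    ``matched_term`` is the canonical permissible value and is present iff
    the verdict is ``ok`` *and* the field carries a value-set restriction.
    """

    status: VerdictStatus
    message: str = ""
    matched_term: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.status is VerdictStatus.ok


def _parses_as(datatype: Datatype, value: str) -> bool:
    text = value.strip()
    if datatype is Datatype.string:
        return True
    if datatype is Datatype.integer:
        try:
            int(text)
        except ValueError:
            return False
        return True
    if datatype is Datatype.date:
        try:
            datetime.date.fromisoformat(text)
        except ValueError:
            return False
        return True
    raise AssertionError(datatype)


def validate_value(spec: FieldSpec, value: str) -> ComplianceVerdict:
    """Check ``value`` against a field spec's restrictions.

    Deterministic and pure: the verdict depends only on (spec, value).
    Dates must be ISO-8601 calendar dates (one unambiguous dialect,
    avoiding locale drift).
    """
    if not _parses_as(spec.datatype, value):
        return ComplianceVerdict(
            status=VerdictStatus.datatype_violation,
            message=f"value {value!r} does not parse as {spec.datatype.value}",
        )
    if not spec.restricted:
        return ComplianceVerdict(status=VerdictStatus.ok, message="no value restriction")
    index = spec.term_index()
    canonical = index.get(normalize(value))
    if canonical is None:
        return ComplianceVerdict(
            status=VerdictStatus.not_in_value_set,
            message=f"value {value!r} is not a permissible value of field {spec.name!r}",
        )
    return ComplianceVerdict(
        status=VerdictStatus.ok, message="permissible value", matched_term=canonical
    )


def load_template(path: str | Path) -> Template:
    """Load a template-dialect JSON file.

    Raises :class:`TemplateError` for a missing file, invalid JSON, or any
    invariant violation (the message names the offending field).
    """
    path = Path(path)
    if not path.exists():
        raise TemplateError(f"template file not found: {path}")
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise TemplateError(f"{path}: invalid JSON: {exc}") from exc
    try:
        return Template.model_validate(payload)
    except Exception as exc:  # pydantic ValidationError carries the field path
        raise TemplateError(f"{path}: invalid template: {exc}") from exc


def write_template(template: Template, path: str | Path) -> None:
    """Serialize a template back to the JSON dialect (lossless round trip)."""
    payload = template.model_dump(exclude_none=True, mode="json")
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def _dictionary_from_tsv(path: Path) -> DataDictionary:
    entries: list[DictionaryEntry] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and normalize(parts[0]) == "name":
                continue  # header row
            if len(parts) < 3:
                raise TemplateError(
                    f"{path}:{lineno}: expected 3 tab-separated columns "
                    "(name, description, format)"
                )
            entries.append(
                DictionaryEntry(name=parts[0], description=parts[1], format=parts[2])
            )
    try:
        return DataDictionary(name=path.stem, entries=entries)
    except Exception as exc:
        raise TemplateError(f"{path}: invalid data dictionary: {exc}") from exc


def load_data_dictionary(path: str | Path) -> DataDictionary:
    """Load a data dictionary from TSV (name, description, format) or JSON."""
    path = Path(path)
    if not path.exists():
        raise TemplateError(f"data dictionary file not found: {path}")
    if path.suffix.lower() in {".json"}:
        try:
            payload = json.loads(path.read_text(encoding="utf-8"))
            return DataDictionary.model_validate(payload)
        except TemplateError:
            raise
        except Exception as exc:
            raise TemplateError(f"{path}: invalid data dictionary: {exc}") from exc
    return _dictionary_from_tsv(path)
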