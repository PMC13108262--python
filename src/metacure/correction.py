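"""Record correction: prompt building, backends, compliance enforcement.

The correction stage rewrites noisy field values toward the canonical
forms a template or data dictionary prescribes. The actual rewriter is a
pluggable :class:`CorrectionBackend` — any procedure (an LLM behind an
API, or the deterministic reference backends shipped here) that maps a
guidance prompt plus a record to a response text containing one JSON
object of field name -> corrected value.

Two guidance modes exist, mirroring the two kinds of symbolic knowledge
source:

* ``DD`` — the prompt carries the entire data dictionary (names,
  descriptions, formats) and the record; no value enumeration exists, so
  no compliance enforcement is possible afterwards.
* ``CEDAR`` — the prompt additionally enumerates, per restricted field,
  its datatype and full permissible-value list; after the backend runs,
  :func:`enforce_compliance` guarantees that every value in a restricted
  field is either a canonical permissible term or the untouched original.

Backend failures (errors, unparseable responses) fall back to the
original record rather than dropping it: retrieval evaluation needs every
record to stay in the corpus.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Protocol, Union, runtime_checkable

from ._text import normalize, tokens
from .records import MetadataRecord
from .templates import (
    ComplianceVerdict,
    DataDictionary,
    FieldSpec,
    Template,
    VerdictStatus,
    validate_value,
)

__all__ = [
    "CorrectionGuidance",
    "CorrectionResult",
    "CorrectionBackend",
    "BackendError",
    "ResponseParseError",
    "build_prompt",
    "parse_backend_response",
    "enforce_compliance",
    "deterministic_backend_correct",
    "DeterministicTemplateBackend",
    "DeterministicDictionaryBackend",
    "load_synonyms",
    "default_synonyms",
    "correct_corpus",
    "derive_seed",
]


class BackendError(RuntimeError):
    """Declared failure of a correction backend on one record."""


class ResponseParseError(ValueError):
    """No usable JSON object could be extracted from a backend response."""


@dataclass(frozen=True)
class CorrectionGuidance:
    """Guidance payload handed to the prompt builder: DD or CEDAR mode."""

    mode: Literal["DD", "CEDAR"]
    payload: Union[DataDictionary, Template]

    def __post_init__(self) -> None:
        if self.mode == "DD" and not isinstance(self.payload, DataDictionary):
            raise TypeError("DD guidance requires a DataDictionary payload")
        if self.mode == "CEDAR" and not isinstance(self.payload, Template):
            raise TypeError("CEDAR guidance requires a Template payload")


@dataclass
class CorrectionResult:
    """Original and corrected record plus the per-field change log."""

    original: MetadataRecord
    corrected: MetadataRecord
    changes: list[tuple[str, str, str, str]] = field(default_factory=list)
    compliance: dict[str, ComplianceVerdict] = field(default_factory=dict)
    backend_name: str = ""
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if self.corrected.record_id != self.original.record_id:
            raise ValueError("corrected record must keep the original record_id")
        if self.fallback_used and self.corrected.pairs != self.original.pairs:
            raise ValueError("fallback_used implies corrected == original")


@runtime_checkable
class CorrectionBackend(Protocol):
    """Contract for pluggable correctors.

    ``correct(prompt, record, rng_seed)`` must be total: return a response
    text or raise :class:`BackendError`. ``deterministic`` declares whether
    the output depends on ``rng_seed``.
    """

    name: str
    deterministic: bool

    def correct(
        self, prompt: str, record: MetadataRecord, rng_seed: Optional[int] = None
    ) -> str: ...


_OUTPUT_INSTRUCTION = (
    "Return ONLY a single JSON object mapping each metadata field name to its "
    "corrected value, with no additional commentary."
)


def _serialize_record(record: MetadataRecord) -> str:
    lines = [f"Record {record.record_id} ({record.source}):"]
    lines += [f"  {name}: {value}" for name, value in record.pairs]
    if record.description:
        lines.append(f"  description: {record.description}")
    return "\n".join(lines)


def build_prompt(record: MetadataRecord, guidance: CorrectionGuidance) -> str:
    """Assemble the correction prompt for one record.

    DD mode serializes every dictionary entry; CEDAR mode enumerates each
    field's datatype, requiredness and full permissible-value list. Both
    end with the JSON output-format instruction.
    """
    if record.is_empty:
        raise ValueError(f"record {record.record_id} is empty: nothing to correct")
    lines: list[str] = [
        "You are a biomedical metadata curator. Correct the metadata record "
        "below so that every field value adheres to the guidance that follows. "
        "Keep values you cannot confidently improve unchanged.",
        "",
        _serialize_record(record),
        "",
    ]
    if guidance.mode == "DD":
        dd = guidance.payload
        assert isinstance(dd, DataDictionary)
        lines.append("Data dictionary (allowed fields, descriptions, formats):")
        for entry in dd.entries:
            lines.append(f"  - {entry.name}: {entry.description} [format: {entry.format}]")
    else:
        template = guidance.payload
        assert isinstance(template, Template)
        lines.append(f"Template '{template.name}' field restrictions:")
        for spec in template.fields:
            req = "required" if spec.required else "optional"
            lines.append(
                f"  - {spec.name} ({spec.datatype.value}, {req}): {spec.description}"
            )
            if spec.restricted:
                assert spec.permissible_values is not None
                terms = ", ".join(pv.term for pv in spec.permissible_values)
                lines.append(f"    permissible values: {terms}")
    lines += ["", _OUTPUT_INSTRUCTION]
    return "\n".join(lines)


def parse_backend_response(text: str, original: MetadataRecord) -> MetadataRecord:
    """Extract the first well-formed JSON object from a backend response.

    Tolerates fenced code blocks and leading prose by scanning for the
    first decodable ``{...}``. The mapping is applied over the original
    pairs (every occurrence of a mapped field gets the new value; mapped
    fields absent from the original are appended). Raises
    :class:`ResponseParseError` when no object is found or when the object
    carries non-text values — a declared signal, never a silent original.
    """
    decoder = json.JSONDecoder()
    obj: Optional[dict] = None
    idx = text.find("{")
    while idx != -1:
        try:
            candidate, _ = decoder.raw_decode(text, idx)
        except json.JSONDecodeError:
            idx = text.find("{", idx + 1)
            continue
        if isinstance(candidate, dict):
            obj = candidate
            break
        idx = text.find("{", idx + 1)
    if obj is None:
        raise ResponseParseError("no JSON object found in backend response")
    for key, value in obj.items():
        if not isinstance(value, str):
            raise ResponseParseError(
                f"backend response value for {key!r} is not text: {value!r}"
            )
    mapping = {normalize(k): v for k, v in obj.items()}
    used: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for name, value in original.pairs:
        key = normalize(name)
        if key in mapping:
            pairs.append((name, mapping[key]))
            used.add(key)
        else:
            pairs.append((name, value))
    for key, value in obj.items():
        if normalize(key) not in used and all(
            normalize(key) != normalize(n) for n, _ in original.pairs
        ):
            pairs.append((key, value))
    return original.replace_pairs(pairs)


def _diff(original: MetadataRecord, corrected: MetadataRecord, reason: str):
    changes = []
    o_pairs, c_pairs = original.pairs, corrected.pairs
    for i, (name, new) in enumerate(c_pairs):
        old = o_pairs[i][1] if i < len(o_pairs) and o_pairs[i][0] == name else None
        if old is None:
            changes.append((name, "", new, "added"))
        elif old != new:
            changes.append((name, old, new, reason))
    return changes


def enforce_compliance(
    candidate: MetadataRecord,
    original: MetadataRecord,
    template: Template,
    *,
    backend_name: str = "",
) -> CorrectionResult:
    """Post-hoc guard for CEDAR-mode corrections.

    Restricted fields whose candidate value violates the datatype or the
    value set are restored to the original value and the verdict recorded;
    compliant values are replaced by their canonical permissible term;
    fields absent from the template pass through unchanged.
    """
    originals: dict[str, list[str]] = {}
    for name, value in original.pairs:
        originals.setdefault(normalize(name), []).append(value)
    occurrence: dict[str, int] = {}
    compliance: dict[str, ComplianceVerdict] = {}
    pairs: list[tuple[str, str]] = []
    for name, value in candidate.pairs:
        key = normalize(name)
        spec = template.field(name)
        if spec is None:
            pairs.append((name, value))
            continue
        verdict = validate_value(spec, value)
        compliance[key] = verdict
        if verdict.ok:
            pairs.append((name, verdict.matched_term or value))
        else:
            idx = occurrence.get(key, 0)
            fallback_values = originals.get(key, [])
            if idx < len(fallback_values):
                pairs.append((name, fallback_values[idx]))
            # a non-compliant field invented by the backend is dropped
        occurrence[key] = occurrence.get(key, 0) + 1
    corrected = candidate.replace_pairs(pairs)
    return CorrectionResult(
        original=original,
        corrected=corrected,
        changes=_diff(original, corrected, "corrected"),
        compliance=compliance,
        backend_name=backend_name,
        fallback_used=False,
    )


def deterministic_backend_correct(
    record: MetadataRecord,
    template: Template,
    synonyms: Mapping[str, str],
) -> str:
    """Reference corrector: pure, deterministic, idempotent.

    For each value-restricted field, in order: (1) a value already in the
    value set maps to its canonical term; (2) else a synonym-table hit maps
    to its canonical target; (3) else, if exactly one permissible term
    occurs as a case-insensitive token of the value, that term; (4) else
    the value is left unchanged. Unrestricted fields pass through. The
    response is the JSON object format expected by
    :func:`parse_backend_response`.
    """
    if not any(spec.restricted for spec in template.fields):
        raise ValueError("template has no value-restricted field")
    norm_synonyms = {normalize(k): v for k, v in synonyms.items()}
    out: dict[str, str] = {}
    for name, value in record.pairs:
        key = normalize(name)
        if key in out:
            continue  # first occurrence wins in the JSON mapping
        spec = template.field(name)
        if spec is None or not spec.restricted:
            out[key] = value
            continue
        index = spec.term_index()
        norm = normalize(value)
        if norm in index:
            out[key] = index[norm]
            continue
        syn = norm_synonyms.get(norm)
        if syn is not None and normalize(syn) in index:
            out[key] = index[normalize(syn)]
            continue
        toks = set(tokens(value))
        hits = [term for n, term in index.items() if n in toks]
        out[key] = hits[0] if len(hits) == 1 else value
    return json.dumps(out, ensure_ascii=False)


class DeterministicTemplateBackend:
    """CEDAR-mode reference backend wrapping :func:`deterministic_backend_correct`."""

    name = "deterministic-template"
    deterministic = True

    def __init__(self, template: Template, synonyms: Mapping[str, str]):
        self.template = template
        self.synonyms = dict(synonyms)

    def correct(
        self, prompt: str, record: MetadataRecord, rng_seed: Optional[int] = None
    ) -> str:
        return deterministic_backend_correct(record, self.template, self.synonyms)


class DeterministicDictionaryBackend:
    """DD-mode reference backend: synonym-table lookup only.

    A data dictionary enumerates no permissible values, so this backend
    has no value set to target: it maps a value through the synonym table
    when the whole normalized value is a known variant, and otherwise
    leaves it untouched.
    """

    name = "deterministic-dictionary"
    deterministic = True

    def __init__(self, synonyms: Mapping[str, str]):
        self.synonyms = {normalize(k): v for k, v in synonyms.items()}

    def correct(
        self, prompt: str, record: MetadataRecord, rng_seed: Optional[int] = None
    ) -> str:
        out: dict[str, str] = {}
        for name, value in record.pairs:
            key = normalize(name)
            if key in out:
                continue
            out[key] = self.synonyms.get(normalize(value), value)
        return json.dumps(out, ensure_ascii=False)


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Load a (variant, canonical) TSV synonym table."""
    table: dict[str, str] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        if lineno == 1 and normalize(line.split("\t")[0]) == "variant":
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        table[normalize(parts[0])] = parts[1].strip()
    return table


def default_synonyms() -> dict[str, str]:
    """The packaged synonym table (blood preparations, disease-name variants)."""
    from importlib import resources

    with resources.as_file(
        resources.files("metacure.data").joinpath("synonyms.tsv")
    ) as p:
        return load_synonyms(p)


def derive_seed(master_seed: int, run_index: int, record_id: str) -> int:
    """Stable sub-seed from (master seed, run index, record id).

    Hash-based so per-record reproducibility is independent of corpus
    order; kept below 2**31.
    """
    digest = hashlib.sha256(
        f"{master_seed}|{run_index}|{record_id}".encode("utf-8")
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def correct_corpus(
    records: list[MetadataRecord],
    guidance: CorrectionGuidance,
    backend: CorrectionBackend,
    runs: int = 1,
    seed: int = 0,
) -> list[list[CorrectionResult]]:
    """Run the backend over the corpus ``runs`` times.

    Deterministic backends yield identical runs; stochastic backends see a
    derived sub-seed per (seed, run index, record id). Any backend error or
    unparseable response falls back to the original record
    (``fallback_used=True``); the pipeline never drops a record.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    template = guidance.payload if guidance.mode == "CEDAR" else None
    all_runs: list[list[CorrectionResult]] = []
    for run_idx in range(runs):
        run_results: list[CorrectionResult] = []
        for rec in records:
            if rec.is_empty:
                run_results.append(
                    CorrectionResult(
                        original=rec,
                        corrected=rec,
                        backend_name=backend.name,
                        fallback_used=True,
                    )
                )
                continue
            prompt = build_prompt(rec, guidance)
            sub_seed = derive_seed(seed, run_idx, rec.record_id)
            try:
                response = backend.correct(prompt, rec, rng_seed=sub_seed)
                candidate = parse_backend_response(response, rec)
            except (BackendError, ResponseParseError):
                run_results.append(
                    CorrectionResult(
                        original=rec,
                        corrected=rec,
                        backend_name=backend.name,
                        fallback_used=True,
                    )
                )
                continue
            if template is not None:
                assert isinstance(template, Template)
                result = enforce_compliance(
                    candidate, rec, template, backend_name=backend.name
                )
            else:
                result = CorrectionResult(
                    original=rec,
                    corrected=candidate,
                    changes=_diff(rec, candidate, "corrected"),
                    backend_name=backend.name,
                )
            run_results.append(result)
        all_runs.append(run_results)
    return all_runs
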