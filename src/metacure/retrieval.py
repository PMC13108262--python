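"""field:value query parsing and exact-match retrieval.

Queries use the ``field:value`` syntax (e.g. ``tissue:lung``). A record is
retrieved iff ANY of its pairs whose canonical field name equals the query
field has a value that is byte-identical to the query value after
normalization (NFC + trim + case-fold). There is no partial matching,
stemming, or synonym expansion; ``raw_exact=True`` disables normalization
for strict byte equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from ._text import normalize
from .records import MetadataRecord

__all__ = ["Query", "QueryError", "parse_query", "search"]


class QueryError(ValueError):
    """Raised for malformed query strings."""


@dataclass(frozen=True)
class Query:
    field: str
    value: str

    def __post_init__(self) -> None:
        if not self.field or not self.value:
            raise QueryError("query field and value must both be non-empty")

    def __str__(self) -> str:
        return f"{self.field}:{self.value}"


def parse_query(text: str) -> Query:
    """Parse ``field:value`` into a Query (field case-folded, both trimmed)."""
    if ":" not in text:
        raise QueryError(f"query {text!r} lacks the ':' separator")
    field, _, value = text.partition(":")
    field, value = normalize(field), value.strip()
    if not field or not value:
        raise QueryError(f"query {text!r} has an empty field or value")
    return Query(field=field, value=value)


def search(
    corpus: Iterable[MetadataRecord], query: Query, *, raw_exact: bool = False
) -> list[str]:
    """Record ids matching the query, in corpus order.

    ANY-match semantics over duplicate field names: a multi-valued
    attribute is findable by each of its values.
    """
    want_field = normalize(query.field)
    want_value = query.value if raw_exact else normalize(query.value)
    hits: list[str] = []
    for rec in corpus:
        for name, value in rec.pairs:
            if normalize(name) != want_field:
                continue
            candidate = value if raw_exact else normalize(value)
            if candidate == want_value:
                hits.append(rec.record_id)
                break
    return hits
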