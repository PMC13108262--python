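"""Text canonicalization shared by compliance checking and retrieval.

A single normalization rule is used everywhere a stored value is compared
with a query value or a permissible term: Unicode NFC, strip surrounding
whitespace, case-fold. No stemming, no synonym expansion — matching after
normalization is still *exact* matching.
"""

from __future__ import annotations

import re
import unicodedata

__all__ = ["normalize", "tokens"]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def normalize(text: str) -> str:
    """Canonical form used for exact value comparison."""
    return unicodedata.normalize("NFC", text).strip().casefold()


def tokens(text: str) -> list[str]:
    """Case-folded alphanumeric tokens of ``text``."""
    return [t.casefold() for t in _TOKEN_RE.findall(text)]
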