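"""Rule-based tissue labeling: the approximate gold standard.

Because no formal gold standard exists for tissue annotations in sample
repositories, retrieval evaluation uses labels assigned by a short ordered
keyword cascade over the record's tissue field: lung; else liver/HCC; else
ovary/ovarian; else PBMC/blood; else plasma; else lymph; else unknown.

"Contains the word" is implemented as case-insensitive substring matching,
not word-boundary matching: acronyms like "HCC" and "PBMC" routinely occur
inside compound tokens ("PBMCs", "HCC-derived") in real metadata. The
``case_sensitive_acronyms`` switch restricts the acronym keywords to exact
case for callers who want the stricter reading. Labels depend only on the
tissue-field values — never on other fields, the description block, or
record order — so the heuristic deliberately misses tissue information
recorded only in free text.
"""

from __future__ import annotations

import enum
from collections import Counter
from typing import Iterable, Mapping

from ._text import normalize
from .records import MetadataRecord

__all__ = ["GoldLabel", "assign_tissue_label", "label_corpus", "label_distribution"]


class GoldLabel(str, enum.Enum):
    lung = "lung"
    liver = "liver"
    ovary = "ovary"
    blood = "blood"
    plasma = "plasma"
    lymph = "lymph"
    unknown = "unknown"


# (label, case-insensitive keywords, acronym keywords) in rule order
_RULES: list[tuple[GoldLabel, tuple[str, ...], tuple[str, ...]]] = [
    (GoldLabel.lung, ("lung",), ()),
    (GoldLabel.liver, ("liver",), ("HCC",)),
    (GoldLabel.ovary, ("ovary", "ovarian"), ()),
    (GoldLabel.blood, ("blood",), ("PBMC",)),
    (GoldLabel.plasma, ("plasma",), ()),
    (GoldLabel.lymph, ("lymph",), ()),
]


def assign_tissue_label(
    record: MetadataRecord, *, case_sensitive_acronyms: bool = False
) -> GoldLabel:
    """Apply the ordered keyword rules to a record's tissue field.

    Multi-valued tissue fields are concatenated (separator ``" | "``)
    before matching so that rule order holds across values. Records with
    no tissue field are ``unknown``.
    """
    raw = " | ".join(record.values("tissue"))
    folded = raw.casefold()
    for label, keywords, acronyms in _RULES:
        if any(kw in folded for kw in keywords):
            return label
        if case_sensitive_acronyms:
            if any(ac in raw for ac in acronyms):
                return label
        elif any(ac.casefold() in folded for ac in acronyms):
            return label
    return GoldLabel.unknown


def label_corpus(
    records: Iterable[MetadataRecord], *, case_sensitive_acronyms: bool = False
) -> dict[str, GoldLabel]:
    """Label every record; record ids must be unique within the corpus."""
    labels: dict[str, GoldLabel] = {}
    for rec in records:
        if rec.record_id in labels:
            raise ValueError(f"duplicate record_id {rec.record_id!r} in corpus")
        labels[rec.record_id] = assign_tissue_label(
            rec, case_sensitive_acronyms=case_sensitive_acronyms
        )
    return labels


def label_distribution(labels: Mapping[str, GoldLabel]) -> dict[GoldLabel, float]:
    """Fraction of records per label (empty mapping -> empty summary).

    Emitted alongside labeling runs so a curator can eyeball prevalences
    (e.g. the expected ~50% blood share) before trusting the labels.
    """
    if not labels:
        return {}
    counts = Counter(labels.values())
    n = len(labels)
    return {label: counts.get(label, 0) / n for label in GoldLabel}


def write_labels_tsv(labels: Mapping[str, GoldLabel], path) -> None:
    from pathlib import Path

    lines = ["record_id\tlabel"]
    lines += [f"{rid}\t{lab.value}" for rid, lab in labels.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_labels_tsv(path) -> dict[str, GoldLabel]:
    from pathlib import Path

    labels: dict[str, GoldLabel] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or (lineno == 1 and line.startswith("record_id")):
            continue
        rid, _, lab = line.partition("\t")
        labels[rid] = GoldLabel(normalize(lab))
    return labels
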