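"""Synthetic metadata corpora with known labels and controlled corruption.

Real sample-repository corpora cannot be redistributed here, so the
generator emulates their failure modes instead: tissue values confounded
by disease names ("lung cancer" in a tissue field), blood values hidden
behind preparation terms (PBMC, whole blood, blood sample), verbose
GEO-style free text mentioning unrelated organs, empty values, and a
~50% blood prevalence among labeled records.

Each record starts from a TRUE tissue label and a clean canonical value;
one corruption operator is then drawn per record from a categorical
distribution over {value_drop, disease_name_swap, synonym_variant, none}
whose probabilities are the configured rates (they must sum to at most
1). The free-text confounder composes independently because it touches
only the description block, never the tissue value. TRUE labels are
returned alongside the corpus so tests can also quantify how conservative
the rule-based gold standard itself is.

The module also ships a stochastic mock correction backend that behaves
like the deterministic template backend but, with a configurable error
rate, swaps a correct tissue value for a biased wrong canonical term
(default bias: blood -> lung, the characteristic long-record confusion),
and can emit malformed non-JSON responses to exercise fallback paths.
"""

from __future__ import annotations

import json
from typing import Mapping, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from ._text import normalize
from .correction import deterministic_backend_correct
from .goldstandard import GoldLabel
from .records import MetadataRecord
from .templates import Template

__all__ = [
    "SyntheticConfig",
    "generate_corpus",
    "MockLLMBackend",
    "mock_llm_backend",
    "SYNONYM_VARIANTS",
    "CANONICAL_TISSUES",
]

CANONICAL_TISSUES = ("lung", "liver", "ovary", "blood", "plasma", "lymph")

# per-label surface variants; every variant keeps the rule-based gold label
# of its TRUE tissue (so corrupted corpora stay label-consistent)
SYNONYM_VARIANTS: dict[str, list[str]] = {
    "lung": ["lung tissue", "left lung", "lung biopsy"],
    "liver": ["liver tissue", "HCC", "resected liver biopsy"],
    "ovary": ["ovarian tissue", "ovary biopsy", "ovarian tumor"],
    "blood": ["PBMC", "whole blood", "blood sample", "peripheral blood"],
    "plasma": ["plasma sample", "plasma specimen"],
    "lymph": ["lymph node", "lymph node biopsy"],
}

_DISTRACTORS = ["kidney", "brain", "skin", "muscle", "heart", "not applicable"]
_CONFOUNDER_ORGANS = ["lung", "liver", "brain", "bone"]


def _disease_swap(label: str) -> str:
    return "ovarian cancer" if label == "ovary" else f"{label} cancer"


class SyntheticConfig(BaseModel):
    """Study conditions for one synthetic corpus."""

    n_records: int = Field(default=2400, gt=0)
    label_distribution: dict[str, float] = Field(
        default_factory=lambda: {
            "blood": 0.50,
            "lung": 0.15,
            "liver": 0.15,
            "ovary": 0.15,
            "plasma": 0.03,
            "lymph": 0.02,
        }
    )
    unknown_fraction: float = Field(default=0.10, ge=0.0, le=1.0)
    value_drop: float = Field(default=0.0, ge=0.0, le=1.0)
    disease_name_swap: float = Field(default=0.6, ge=0.0, le=1.0)
    synonym_variant: float = Field(default=0.3, ge=0.0, le=1.0)
    verbose_freetext: float = Field(default=0.2, ge=0.0, le=1.0)
    seed: int = 0
    source_style: str = Field(default="biosample", pattern="^(biosample|geo)$")

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for label, p in self.label_distribution.items():
            if label not in CANONICAL_TISSUES:
                raise ValueError(f"unknown tissue label {label!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {label!r} outside [0, 1]")
        total = sum(self.label_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"label_distribution must sum to 1, got {total}")
        if self.value_drop + self.disease_name_swap + self.synonym_variant > 1 + 1e-9:
            raise ValueError("tissue corruption rates must sum to at most 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def generate_corpus(
    config: SyntheticConfig,
) -> tuple[list[MetadataRecord], dict[str, GoldLabel]]:
    """Generate a corpus plus its TRUE (pre-corruption) labels.

    Identical configs (including seed) produce identical corpora.
    """
    rng = np.random.default_rng(config.seed)
    labels = list(config.label_distribution)
    probs = np.array([config.label_distribution[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    records: list[MetadataRecord] = []
    truth: dict[str, GoldLabel] = {}
    for i in range(config.n_records):
        rid = f"SYN{i:06d}"
        if rng.random() < config.unknown_fraction:
            label = None
            tissue = _DISTRACTORS[rng.integers(len(_DISTRACTORS))]
        else:
            label = labels[rng.choice(len(labels), p=probs)]
            tissue = label
        sex = "female" if rng.random() < 0.5 else "male"
        age = int(rng.integers(20, 90))
        # one corruption operator per labeled record
        if label is not None:
            u = rng.random()
            if u < config.value_drop:
                tissue = ""
            elif u < config.value_drop + config.disease_name_swap:
                tissue = _disease_swap(label)
            elif u < (
                config.value_drop + config.disease_name_swap + config.synonym_variant
            ):
                variants = SYNONYM_VARIANTS[label]
                tissue = variants[rng.integers(len(variants))]
        description = None
        if config.source_style == "geo":
            description = (
                f"Expression profiling of sample {rid}; total RNA extracted "
                "and hybridized following the standard protocol."
            )
        if rng.random() < config.verbose_freetext:
            organ = _CONFOUNDER_ORGANS[rng.integers(len(_CONFOUNDER_ORGANS))]
            note = (
                f"Clinical notes: patient with prior history of {organ} "
                "metastasis; sample collected during routine follow-up."
            )
            description = f"{description} {note}" if description else note
        records.append(
            MetadataRecord(
                record_id=rid,
                source="synthetic",
                pairs=[
                    ("organism", "Homo sapiens"),
                    ("tissue", tissue),
                    ("sex", sex),
                    ("age", str(age)),
                ],
                description=description,
            )
        )
        truth[rid] = GoldLabel(label) if label is not None else GoldLabel.unknown
    return records, truth


class MockLLMBackend:
    """Seeded stochastic backend emulating an imperfect LLM corrector.

    Behaves like the deterministic template backend, except that per
    record, with probability ``malformed_rate`` it emits non-JSON prose
    (driving the fallback path), and with probability ``error_rate`` it
    replaces the corrected tissue value with a wrong canonical term —
    biased per ``confusion_bias`` (default blood -> lung), otherwise a
    seeded draw among the remaining canonical tissues.
    """

    deterministic = False

    def __init__(
        self,
        template: Template,
        synonyms: Mapping[str, str],
        error_rate: float = 0.1,
        confusion_bias: Optional[Mapping[str, str]] = None,
        malformed_rate: float = 0.0,
    ):
        if not 0.0 <= error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0.0 <= malformed_rate <= 1.0:
            raise ValueError("malformed_rate must be in [0, 1]")
        self.template = template
        self.synonyms = dict(synonyms)
        self.error_rate = error_rate
        self.confusion_bias = dict(confusion_bias or {"blood": "lung"})
        self.malformed_rate = malformed_rate
        self.name = f"mock-llm(err={error_rate},malformed={malformed_rate})"

    def correct(
        self, prompt: str, record: MetadataRecord, rng_seed: Optional[int] = None
    ) -> str:
        rng = np.random.default_rng(rng_seed)
        if rng.random() < self.malformed_rate:
            return "Sure! Here are the corrections you asked for."
        response = deterministic_backend_correct(record, self.template, self.synonyms)
        if rng.random() >= self.error_rate:
            return response
        obj = json.loads(response)
        tissue = obj.get("tissue")
        if tissue is None:
            return response
        current = normalize(tissue)
        wrong = self.confusion_bias.get(current)
        if wrong is None:
            others = [t for t in CANONICAL_TISSUES if t != current]
            wrong = others[rng.integers(len(others))]
        obj["tissue"] = wrong
        return json.dumps(obj, ensure_ascii=False)


def mock_llm_backend(
    template: Template,
    synonyms: Mapping[str, str],
    error_rate: float = 0.1,
    confusion_bias: Optional[Mapping[str, str]] = None,
    malformed_rate: float = 0.0,
) -> MockLLMBackend:
    """Factory mirroring :class:`MockLLMBackend` (kept for discoverability)."""
    return MockLLMBackend(
        template,
        synonyms,
        error_rate=error_rate,
        confusion_bias=confusion_bias,
        malformed_rate=malformed_rate,
    )
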