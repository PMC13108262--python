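"""Retrieval evaluation: confusion outcomes, metrics, run statistics.

Evaluation is record-wise against the rule-based gold standard. For a
query ``tissue:X``, a record is a true positive when its gold label is X
and the curated tissue value is X (normalized exact equality, the same
rule retrieval uses); a false positive when the curated value is X but
the gold label is not; a false negative when the gold label is X but the
curated value is not (including unknown or missing values); a true
negative otherwise. Because retrieval is exact on the same normalization,
this record-wise framing is equivalent to evaluating the retrieved set of
the corresponding query.

Run-level statistics follow the convention of treating each corpus-wide
run as the independent unit: mean over runs, sample SD (n-1 denominator),
SE = SD/sqrt(n), error limits clamped at zero because the metrics are
non-negative. Conditions are compared with one-way ANOVA and Cohen's d
(pooled SD; |d| bands at 0.2 / 0.5 / 0.8).

Zero-denominator metrics are reported as an undefined flag (``None``) —
never silently zero, never an exception; run-level averages skip
undefined values and count how many were skipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from ._text import normalize
from .goldstandard import GoldLabel
from .records import MetadataRecord
from .retrieval import Query

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ConditionSummary",
    "EffectSize",
    "confusion",
    "metrics",
    "summarize_runs",
    "anova",
    "cohens_d",
    "evaluate_conditions",
    "EvaluationReport",
    "side_by_side_report",
]

METRIC_NAMES = ("precision", "recall", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Precision/recall/F1; ``None`` marks an undefined (0/0) metric."""

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]

    def get(self, name: str) -> Optional[float]:
        return getattr(self, name)


def curated_tissue_values(corpus: Iterable[MetadataRecord]) -> dict[str, str]:
    """record_id -> first tissue value ('' when the field is absent)."""
    return {rec.record_id: rec.first("tissue") or "" for rec in corpus}


def confusion(
    corpus: Sequence[MetadataRecord],
    curated_values: Mapping[str, str],
    gold: Mapping[str, GoldLabel],
    query: Query,
) -> ConfusionCounts:
    """Record-wise confusion counts for a ``tissue:X`` query.

    ``curated_values`` and ``gold`` must cover every record; counts always
    sum to the corpus size.
    """
    if normalize(query.field) != "tissue":
        raise ValueError("confusion evaluation is defined for tissue queries")
    x = normalize(query.value)
    tp = fp = fn = tn = 0
    for rec in corpus:
        rid = rec.record_id
        if rid not in curated_values:
            raise KeyError(f"record {rid} missing from curated_values")
        if rid not in gold:
            raise KeyError(f"record {rid} missing from gold labels")
        relevant = gold[rid].value == x
        retrieved = normalize(curated_values[rid]) == x
        if relevant and retrieved:
            tp += 1
        elif retrieved:
            fp += 1
        elif relevant:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den else None


def metrics(c: ConfusionCounts) -> MetricSet:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R)."""
    p = _ratio(c.tp, c.tp + c.fp)
    r = _ratio(c.tp, c.tp + c.fn)
    if p is None or r is None or (p + r) == 0:
        f1 = None
    else:
        f1 = 2 * p * r / (p + r)
    return MetricSet(precision=p, recall=r, f1=f1)


@dataclass
class ConditionSummary:
    """Across-run summary of one metric under one condition."""

    condition: str
    metric: str
    values: list[Optional[float]]
    n: int = 0
    n_undefined: int = 0
    mean: Optional[float] = None
    sd: Optional[float] = None
    se: Optional[float] = None
    err_lower: Optional[float] = None
    err_upper: Optional[float] = None


def summarize_runs(
    values: Sequence[Optional[float]], metric: str = "", condition: str = ""
) -> ConditionSummary:
    """Mean, sample SD, SE = SD/sqrt(n), zero-clamped error limits.

    Undefined run values are skipped and counted (``n_undefined``); with a
    single defined run, SD/SE stay undefined.
    """
    if not values:
        raise ValueError("summarize_runs needs at least one run value")
    defined = [v for v in values if v is not None]
    summary = ConditionSummary(
        condition=condition,
        metric=metric,
        values=list(values),
        n=len(defined),
        n_undefined=len(values) - len(defined),
    )
    if not defined:
        return summary
    arr = np.asarray(defined, dtype=float)
    summary.mean = float(arr.mean())
    if len(defined) >= 2:
        summary.sd = float(arr.std(ddof=1))
        summary.se = summary.sd / math.sqrt(len(defined))
        summary.err_lower = max(0.0, summary.mean - summary.se)
        summary.err_upper = summary.mean + summary.se
    return summary


def anova(groups: Sequence[Sequence[float]]) -> tuple[Optional[float], Optional[float]]:
    """One-way ANOVA over two or more groups of per-run values.

    Degenerate input (every value identical in every group) yields the
    undefined flag ``(None, None)`` instead of an exception.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each ANOVA group needs at least two values")
    flat = [v for g in groups for v in g]
    if max(flat) == min(flat):
        return (None, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, p_val = _scipy_stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    if not math.isfinite(f_stat):
        return (None, None)
    return (float(f_stat), float(p_val))


@dataclass(frozen=True)
class EffectSize:
    d: Optional[float]
    band: str  # negligible | small | medium | large | undefined


def _band(d: float) -> str:
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def cohens_d(group_a: Sequence[float], group_b: Sequence[float]) -> EffectSize:
    """Pooled-SD standardized mean difference (n-1 weights)."""
    na, nb = len(group_a), len(group_b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two values")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        return EffectSize(d=None, band="undefined")
    d = float((a.mean() - b.mean()) / math.sqrt(pooled_var))
    return EffectSize(d=d, band=_band(d))


@dataclass
class EvaluationReport:
    """Everything the evaluation stage computes, renderable as text/TSV."""

    queries: list[Query]
    # per (condition, query string, run index) metric sets
    per_run: dict[tuple[str, str, int], MetricSet] = field(default_factory=dict)
    # per (condition, query string, metric) summaries
    per_query_summary: dict[tuple[str, str, str], ConditionSummary] = field(
        default_factory=dict
    )
    # per (condition, metric, weighting) query-averaged summaries
    condition_summary: dict[tuple[str, str, str], ConditionSummary] = field(
        default_factory=dict
    )
    # per (cond_a, cond_b, metric): ANOVA (F, p) and Cohen's d
    comparisons: dict[tuple[str, str, str], dict] = field(default_factory=dict)
    side_by_side: str = ""

    def metrics_table(self):
        import pandas as pd

        rows = []
        for (cond, q, run), ms in self.per_run.items():
            rows.append(
                {
                    "condition": cond,
                    "query": q,
                    "run": run,
                    "precision": ms.precision,
                    "recall": ms.recall,
                    "f1": ms.f1,
                }
            )
        return pd.DataFrame(rows)

    def summary_table(self):
        import pandas as pd

        rows = []
        for (cond, metric, weighting), s in self.condition_summary.items():
            rows.append(
                {
                    "condition": cond,
                    "metric": metric,
                    "weighting": weighting,
                    "mean": s.mean,
                    "sd": s.sd,
                    "se": s.se,
                    "err_lower": s.err_lower,
                    "err_upper": s.err_upper,
                    "n_runs": s.n,
                    "n_undefined": s.n_undefined,
                }
            )
        return pd.DataFrame(rows)

    def comparisons_table(self):
        import pandas as pd

        rows = []
        for (a, b, metric), c in self.comparisons.items():
            rows.append(
                {
                    "condition_a": a,
                    "condition_b": b,
                    "metric": metric,
                    "anova_f": c["anova_f"],
                    "anova_p": c["anova_p"],
                    "cohens_d": c["cohens_d"],
                    "band": c["band"],
                }
            )
        return pd.DataFrame(rows)


def _query_average(
    per_query: Mapping[str, Optional[float]], weights: Mapping[str, int], weighted: bool
) -> Optional[float]:
    pairs = [(v, weights[q]) for q, v in per_query.items() if v is not None]
    if not pairs:
        return None
    if not weighted:
        return float(np.mean([v for v, _ in pairs]))
    total = sum(w for _, w in pairs)
    if total == 0:
        return None
    return sum(v * w for v, w in pairs) / total


def side_by_side_report(
    original: Sequence[MetadataRecord], corrected: Sequence[MetadataRecord]
) -> str:
    """Plain-text side-by-side view of changed field values.

    A lightweight substitute for interactive review interfaces: curators
    can eyeball each correction next to the uncorrected value.
    """
    corrected_by_id = {rec.record_id: rec for rec in corrected}
    lines = ["record_id\tfield\toriginal\tcorrected"]
    for rec in original:
        after = corrected_by_id.get(rec.record_id)
        if after is None:
            continue
        before_pairs = rec.pairs
        after_pairs = after.pairs
        for i, (name, new) in enumerate(after_pairs):
            old = (
                before_pairs[i][1]
                if i < len(before_pairs) and before_pairs[i][0] == name
                else ""
            )
            if old != new:
                lines.append(f"{rec.record_id}\t{name}\t{old}\t{new}")
    return "\n".join(lines) + "\n"


def evaluate_conditions(
    condition_runs: Mapping[str, Sequence[Sequence[MetadataRecord]]],
    gold: Mapping[str, GoldLabel],
    queries: Sequence[Query],
    *,
    baseline_condition: Optional[str] = None,
) -> EvaluationReport:
    """Full evaluation across conditions, queries and runs.

    ``condition_runs`` maps a condition label to its per-run corpora (a
    deterministic condition may supply a single run). All conditions must
    cover the same record set. Produces per-run metric sets, per-query and
    query-averaged summaries (both unweighted and weighted by each query's
    relevant-record count), and pairwise ANOVA + Cohen's d on the
    query-averaged per-run values for every condition pair with >= 2 runs.
    """
    if not condition_runs:
        raise ValueError("no conditions supplied")
    report = EvaluationReport(queries=list(queries))
    ids_reference: Optional[frozenset[str]] = None
    for cond, runs in condition_runs.items():
        for corpus in runs:
            ids = frozenset(rec.record_id for rec in corpus)
            if ids_reference is None:
                ids_reference = ids
            elif ids != ids_reference:
                raise ValueError(
                    f"condition {cond!r} covers a different record set"
                )
    # relevant-record count per query, for size-weighted averaging
    weights = {
        str(q): sum(1 for lab in gold.values() if lab.value == normalize(q.value))
        for q in queries
    }

    run_counts: dict[str, int] = {}
    for cond, runs in condition_runs.items():
        run_counts[cond] = len(runs)
        for run_idx, corpus in enumerate(runs):
            curated = curated_tissue_values(corpus)
            for q in queries:
                c = confusion(corpus, curated, gold, q)
                report.per_run[(cond, str(q), run_idx)] = metrics(c)
        for q in queries:
            for metric in METRIC_NAMES:
                vals = [
                    report.per_run[(cond, str(q), r)].get(metric)
                    for r in range(len(runs))
                ]
                report.per_query_summary[(cond, str(q), metric)] = summarize_runs(
                    vals, metric=metric, condition=cond
                )
        for metric in METRIC_NAMES:
            for weighting in ("unweighted", "size_weighted"):
                per_run_avgs: list[Optional[float]] = []
                for r in range(len(runs)):
                    per_query = {
                        str(q): report.per_run[(cond, str(q), r)].get(metric)
                        for q in queries
                    }
                    per_run_avgs.append(
                        _query_average(per_query, weights, weighting == "size_weighted")
                    )
                report.condition_summary[(cond, metric, weighting)] = summarize_runs(
                    per_run_avgs, metric=metric, condition=cond
                )

    conds = list(condition_runs)
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            for metric in METRIC_NAMES:
                va = [
                    v
                    for v in report.condition_summary[(a, metric, "unweighted")].values
                    if v is not None
                ]
                vb = [
                    v
                    for v in report.condition_summary[(b, metric, "unweighted")].values
                    if v is not None
                ]
                if len(va) < 2 or len(vb) < 2:
                    continue
                f_stat, p_val = anova([va, vb])
                eff = cohens_d(va, vb)
                report.comparisons[(a, b, metric)] = {
                    "anova_f": f_stat,
                    "anova_p": p_val,
                    "cohens_d": eff.d,
                    "band": eff.band,
                }
    return report
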