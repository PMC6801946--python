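"""Exact-match span evaluation: per-type TP/FP/FN and precision/recall/F1.

A predicted span counts as a true positive only when a gold span with
identical token boundaries *and* semantic type exists; each gold span can be
matched at most once.  Counts are pooled over documents within each type
before computing P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R), with the
zero conventions P=0 when TP+FP=0, R=0 when TP+FN=0, F=0 when P+R=0.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .annotate import EntitySpan

__all__ = ["EvalReport", "match_spans", "prf", "report", "weighted_f1"]


def _check_disjoint(spans: Sequence[EntitySpan], which: str) -> None:
    ordered = sorted(spans, key=lambda s: s.token_start)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping {which} spans {a.key} / {b.key}")


def match_spans(gold: Sequence[EntitySpan],
                pred: Sequence[EntitySpan]) -> dict[str, tuple[int, int, int]]:
    """Per-type (TP, FP, FN) under the exact-match criterion.

    Spans within each list must be non-overlapping.  A boundary-correct but
    type-wrong prediction contributes one FP (its own type) and one FN (the
    gold type).
    """
    _check_disjoint(gold, "gold")
    _check_disjoint(pred, "predicted")
    types = sorted({s.type_id for s in gold} | {s.type_id for s in pred})
    counts = {}
    for t in types:
        gold_t = [s for s in gold if s.type_id == t]
        tp = 0
        remaining = Counter(s.key for s in gold_t)
        for p in pred:
            if p.type_id == t and remaining.get(p.key, 0) > 0:
                remaining[p.key] -= 1
                tp += 1
        fp = sum(1 for p in pred if p.type_id == t) - tp
        fn = len(gold_t) - tp
        counts[t] = (tp, fp, fn)
    return counts


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from integer counts, with zero conventions."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


@dataclass
class EvalReport:
    """Per-type counts and scores plus micro and support-weighted aggregates."""

    per_type: dict[str, dict[str, float]] = field(default_factory=dict)
    micro: dict[str, float] = field(default_factory=dict)
    weighted: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"per_type": self.per_type, "micro": self.micro,
                           "weighted": self.weighted}, indent=2)

    def to_tsv(self) -> str:
        """Per-type rows with P/R/F as percentages to 2 d.p."""
        lines = ["type\tTP\tFP\tFN\tP\tR\tF"]
        rows = list(self.per_type.items()) + [("micro", self.micro)]
        for name, row in rows:
            lines.append(
                f"{name}\t{int(row.get('TP', 0))}\t{int(row.get('FP', 0))}"
                f"\t{int(row.get('FN', 0))}\t{100 * row['P']:.2f}"
                f"\t{100 * row['R']:.2f}\t{100 * row['F']:.2f}")
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv(), encoding="utf-8")


def report(gold_corpus: Mapping[str, Sequence[EntitySpan]] | Sequence,
           pred_corpus: Mapping[str, Sequence[EntitySpan]] | Sequence) -> EvalReport:
    """Corpus-level evaluation with counts pooled over documents per type.

    Both corpora are either aligned sequences of span lists or mappings
    doc_id -> spans; mappings must cover identical doc_id sets.
    """
    if isinstance(gold_corpus, Mapping) or isinstance(pred_corpus, Mapping):
        if set(gold_corpus) != set(pred_corpus):
            raise ValueError("gold and predicted corpora cover different doc_ids")
        pairs = [(gold_corpus[k], pred_corpus[k]) for k in sorted(gold_corpus)]
    else:
        if len(gold_corpus) != len(pred_corpus):
            raise ValueError("gold and predicted corpora have different lengths")
        pairs = list(zip(gold_corpus, pred_corpus))

    totals: dict[str, list[int]] = {}
    for gold, pred in pairs:
        for t, (tp, fp, fn) in match_spans(gold, pred).items():
            acc = totals.setdefault(t, [0, 0, 0])
            acc[0] += tp
            acc[1] += fp
            acc[2] += fn

    rep = EvalReport()
    mtp = mfp = mfn = 0
    for t in sorted(totals):
        tp, fp, fn = totals[t]
        p, r, f = prf(tp, fp, fn)
        rep.per_type[t] = {"TP": tp, "FP": fp, "FN": fn, "P": p, "R": r,
                           "F": f, "support": tp + fn}
        mtp, mfp, mfn = mtp + tp, mfp + fp, mfn + fn
    p, r, f = prf(mtp, mfp, mfn)
    rep.micro = {"TP": mtp, "FP": mfp, "FN": mfn, "P": p, "R": r, "F": f}
    support = sum(row["support"] for row in rep.per_type.values())
    if support:
        for key in ("P", "R", "F"):
            rep.weighted[key] = sum(row[key] * row["support"]
                                    for row in rep.per_type.values()) / support
    else:
        rep.weighted = {"P": 0.0, "R": 0.0, "F": 0.0}
    return rep


def weighted_f1(gold_corpus, pred_corpus) -> float:
    """Support-weighted mean of per-type exact-match F1 (early-stop monitor)."""
    return report(gold_corpus, pred_corpus).weighted["F"]
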