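"""Per-tag precision/recall/F1 with micro and macro averaging, k-fold
splitting, cross-validation, and the answer-to-question transfer harness.

The primary metric is positionwise tag classification over the entity tags
(``B-T``/``I-T``); ``O`` never enters the averages and positions whose gold
label is ``X`` (BERT scheme) are skipped entirely.  Micro averaging pools
true/false positive/negative counts across tags before computing the
metrics, so frequent tags dominate; macro averaging takes the unweighted
mean over the tags present in the gold data, so rare tags weigh equally.
Entity-level exact-match scores are available as a secondary report via
span decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .annotation_io import AnnotatedDocument, LabelSequence, Scheme
from . import labeling

__all__ = [
    "PRF",
    "TagScore",
    "MetricsReport",
    "tag_metrics",
    "corpus_tag_metrics",
    "entity_metrics",
    "kfold_split",
    "type_micro",
    "cross_validate",
    "CrossValReport",
    "evaluate_transfer",
    "TransferReport",
]


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    f1: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "PRF":
        # zero-division convention: 0, so averages are always computable
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return cls(p, r, f)

    def to_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall, "f1": self.f1}


@dataclass(frozen=True)
class TagScore:
    tp: int
    fp: int
    fn: int
    prf: PRF

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "TagScore":
        return cls(tp, fp, fn, PRF.from_counts(tp, fp, fn))

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, **self.prf.to_dict()}


@dataclass(frozen=True)
class MetricsReport:
    """Per-tag counts and scores plus pooled (micro) and unweighted-mean
    (macro) averages; macro runs over tags with gold support only."""

    per_tag: dict[str, TagScore]
    micro: PRF
    macro: PRF
    n_positions: int
    n_repairs: int = 0

    def to_dict(self) -> dict:
        return {
            "per_tag": {t: s.to_dict() for t, s in self.per_tag.items()},
            "micro": self.micro.to_dict(),
            "macro": self.macro.to_dict(),
            "n_positions": self.n_positions,
            "n_repairs": self.n_repairs,
        }


def _entity_tags(tag_set: Sequence[str]) -> list[str]:
    return [f"{p}-{t}" for t in tag_set for p in ("B", "I")]


def _report_from_counts(counts: dict[str, list[int]], n_positions: int,
                        n_repairs: int = 0) -> MetricsReport:
    per_tag = {t: TagScore.from_counts(*c) for t, c in counts.items()}
    tp = sum(c[0] for c in counts.values())
    fp = sum(c[1] for c in counts.values())
    fn = sum(c[2] for c in counts.values())
    micro = PRF.from_counts(tp, fp, fn)
    present = [t for t, c in counts.items() if c[0] + c[2] > 0]
    if present:
        macro = PRF(
            float(np.mean([per_tag[t].prf.precision for t in present])),
            float(np.mean([per_tag[t].prf.recall for t in present])),
            float(np.mean([per_tag[t].prf.f1 for t in present])),
        )
    else:
        macro = PRF(0.0, 0.0, 0.0)
    return MetricsReport(per_tag, micro, macro, n_positions, n_repairs)


def type_micro(report: MetricsReport, etype: str) -> PRF:
    """Micro scores for one entity type: B-T and I-T counts pooled."""
    tags = [t for t in report.per_tag if t.endswith(f"-{etype}")]
    if not tags:
        raise ValueError(f"no tags of type {etype!r} in the report")
    tp = sum(report.per_tag[t].tp for t in tags)
    fp = sum(report.per_tag[t].fp for t in tags)
    fn = sum(report.per_tag[t].fn for t in tags)
    return PRF.from_counts(tp, fp, fn)


def corpus_tag_metrics(pairs: Iterable[tuple[LabelSequence, LabelSequence]],
                       included_tags: Sequence[str] | None = None,
                       n_repairs: int = 0) -> MetricsReport:
    """Pool positionwise counts over (gold, pred) sequence pairs."""
    counts: dict[str, list[int]] | None = None
    n_positions = 0
    for gold, pred in pairs:
        if gold.scheme != pred.scheme:
            raise ValueError(
                f"scheme mismatch: gold {gold.scheme.value} vs pred {pred.scheme.value}"
            )
        if len(gold) != len(pred):
            raise ValueError(
                f"length mismatch: gold {len(gold)} vs pred {len(pred)}"
            )
        if counts is None:
            tags = list(included_tags) if included_tags is not None \
                else _entity_tags(gold.tag_set)
            counts = {t: [0, 0, 0] for t in tags}
        for g, p in zip(gold, pred):
            if g == "X":  # BERT-scheme placeholders are skipped entirely
                continue
            n_positions += 1
            if g == p:
                if g in counts:
                    counts[g][0] += 1
            else:
                if p in counts:
                    counts[p][1] += 1
                if g in counts:
                    counts[g][2] += 1
    if counts is None:
        raise ValueError("no sequence pairs supplied")
    return _report_from_counts(counts, n_positions, n_repairs)


def tag_metrics(gold: LabelSequence, pred: LabelSequence,
                included_tags: Sequence[str] | None = None) -> MetricsReport:
    """Positionwise per-tag metrics for one aligned sequence pair."""
    return corpus_tag_metrics([(gold, pred)], included_tags)


def entity_metrics(gold_docs: Sequence[AnnotatedDocument],
                   pred_spans: Sequence[Sequence[labeling.EntitySpan]]
                   ) -> MetricsReport:
    """Secondary report: entity-level exact-match (type + both offsets)."""
    if len(gold_docs) != len(pred_spans):
        raise ValueError("document/prediction count mismatch")
    tag_set = gold_docs[0].tag_set if gold_docs else ()
    counts = {t: [0, 0, 0] for t in tag_set}
    n = 0
    for doc, preds in zip(gold_docs, pred_spans):
        g = set(doc.spans)
        p = set(preds)
        n += len(g)
        for sp in g & p:
            counts[sp.etype][0] += 1
        for sp in p - g:
            if sp.etype in counts:
                counts[sp.etype][1] += 1
        for sp in g - p:
            counts[sp.etype][2] += 1
    return _report_from_counts(counts, n)


# ---------------------------------------------------------------------------
# splits and harnesses
# ---------------------------------------------------------------------------

def kfold_split(docs: Sequence, k: int, seed: int
                ) -> list[tuple[list, list]]:
    """Seeded shuffle then contiguous split into k (train, test) partitions.

    Test folds are disjoint, cover all documents, and differ in size by at
    most one.
    """
    n = len(docs)
    if k < 2 or k > n:
        raise ValueError(f"k={k} out of range for {n} documents")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    out = []
    for f in folds:
        test_idx = set(int(i) for i in f)
        test = [docs[i] for i in sorted(test_idx)]
        train = [docs[i] for i in range(n) if i not in test_idx]
        out.append((train, test))
    return out


@dataclass(frozen=True)
class CrossValReport:
    fold_reports: tuple[MetricsReport, ...]
    mean_micro: PRF
    mean_macro: PRF

    def to_dict(self) -> dict:
        return {
            "folds": [r.to_dict() for r in self.fold_reports],
            "mean_micro": self.mean_micro.to_dict(),
            "mean_macro": self.mean_macro.to_dict(),
        }


def _mean_prf(prfs: Sequence[PRF]) -> PRF:
    return PRF(
        float(np.mean([x.precision for x in prfs])),
        float(np.mean([x.recall for x in prfs])),
        float(np.mean([x.f1 for x in prfs])),
    )


def _evaluate_model(model, docs: Sequence[AnnotatedDocument],
                    scheme: Scheme) -> MetricsReport:
    pairs = []
    for doc in docs:
        gold = labeling.gold_label_sequence(doc, scheme)
        pred = model.predict(doc)
        pairs.append((gold, pred))
    return corpus_tag_metrics(pairs)


def cross_validate(tagger_factory: Callable[[], object],
                   docs: Sequence[AnnotatedDocument], k: int, seed: int,
                   scheme: Scheme = Scheme.IOB_CHAR) -> CrossValReport:
    """k-fold cross-validation; reports each fold and the unweighted mean.

    ``tagger_factory`` returns a fresh tagger exposing ``fit(train_docs)``
    and ``predict(doc) -> LabelSequence`` in the given scheme.
    """
    reports = []
    for train, test in kfold_split(docs, k, seed):
        tagger = tagger_factory()
        tagger.fit(train)
        reports.append(_evaluate_model(tagger, test, scheme))
    return CrossValReport(
        tuple(reports),
        _mean_prf([r.micro for r in reports]),
        _mean_prf([r.macro for r in reports]),
    )


@dataclass(frozen=True)
class TransferReport:
    """In-domain vs shifted-domain evaluation of one trained model."""

    source: MetricsReport
    target: MetricsReport
    per_tag_f1_delta: dict[str, float]
    per_tag_recall_delta: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "source": self.source.to_dict(),
            "target": self.target.to_dict(),
            "per_tag_f1_delta": self.per_tag_f1_delta,
            "per_tag_recall_delta": self.per_tag_recall_delta,
        }


def evaluate_transfer(model, source_docs: Sequence[AnnotatedDocument],
                      target_docs: Sequence[AnnotatedDocument],
                      scheme: Scheme = Scheme.IOB_CHAR) -> TransferReport:
    """Evaluate one model on held-out source-domain and shifted target-domain
    documents; deltas are target minus source (negative = degradation)."""
    if not target_docs:
        raise ValueError("empty target document set")
    src = _evaluate_model(model, source_docs, scheme)
    tgt = _evaluate_model(model, target_docs, scheme)
    f1_delta = {}
    rec_delta = {}
    for tag in src.per_tag:
        f1_delta[tag] = tgt.per_tag[tag].prf.f1 - src.per_tag[tag].prf.f1
        rec_delta[tag] = tgt.per_tag[tag].prf.recall - src.per_tag[tag].prf.recall
    return TransferReport(src, tgt, f1_delta, rec_delta)
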