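"""Instance-level exact-match evaluation.

Every mention occurrence is scored separately.  Under the exact-match
criterion a prediction counts only if its boundary — and, in normalization
mode, its normalized ID — fully coincides with a gold annotation.  Species
and species-prefix annotations are pooled together by default, matching how
instance-level species corpora count prefixes as species instances.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

logger = logging.getLogger(__name__)

__all__ = ["PRF", "evaluate"]


@dataclass(frozen=True)
class PRF:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int) -> "PRF":
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return cls(tp=tp, fp=fp, fn=fn, precision=p, recall=r, f=f)


def _items(annotations):
    for item in annotations:
        if isinstance(item, tuple):
            yield item
        else:
            yield None, item


def _key(doc_id, ann, mode: str, warn_unresolved: bool):
    if mode == "recognition":
        return (doc_id, ann.offset, ann.length)
    if not ann.resolved:
        if warn_unresolved:
            logger.warning("annotation %r at %d has %d IDs; counted as "
                           "non-match in normalization mode",
                           ann.text, ann.offset, len(ann.norm_ids))
        return None
    return (doc_id, ann.offset, ann.length, ann.norm_ids[0])


def evaluate(gold, pred, mode: str = "normalization") -> PRF:
    """Instance-level PRF under the exact-match criterion.

    ``gold`` and ``pred`` are annotation sequences (optionally
    ``(doc_id, annotation)`` tuples when scoring multi-document sets).
    ``mode="recognition"`` matches on ``(document, span)``;
    ``mode="normalization"`` additionally requires the normalized ID.
    Each gold instance matches at most one prediction and vice versa.
    """
    if mode not in ("recognition", "normalization"):
        raise ValueError(f"unknown evaluation mode: {mode!r}")
    gold_keys = Counter()
    gold_total = 0
    for doc_id, ann in _items(gold):
        gold_total += 1
        key = _key(doc_id, ann, mode, warn_unresolved=False)
        if key is not None:
            gold_keys[key] += 1
    pred_keys = Counter()
    pred_total = 0
    for doc_id, ann in _items(pred):
        pred_total += 1
        key = _key(doc_id, ann, mode, warn_unresolved=True)
        if key is not None:
            pred_keys[key] += 1
    tp = sum(min(n, gold_keys[k]) for k, n in pred_keys.items())
    return PRF.from_counts(tp=tp, fp=pred_total - tp, fn=gold_total - tp)
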