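"""Entity-level scoring under exact and inexact span-matching schemes.

Exact match credits a prediction only when type and both boundaries agree
with the gold standard; inexact match credits a same-typed prediction that
overlaps a gold entity.  Matching is one-to-one within each sentence and
type: a gold entity can validate at most one prediction, so a single long
prediction cannot collect credit for several gold spans.  For interval
overlap graphs over two non-overlapping span sets, the greedy left-to-right
assignment used here attains maximum cardinality; a brute-force bipartite
matching oracle backs this in :func:`oracle_equivalence_check`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .corpus import CorpusError, Document, EntitySpan, validate_spans

SCHEMES = ("exact", "inexact")


def _spans_match(g: EntitySpan, p: EntitySpan, scheme: str, require_type: bool = True) -> bool:
    if require_type and g.type != p.type:
        return False
    if scheme == "exact":
        return g.start == p.start and g.end == p.end
    if scheme == "inexact":
        return g.overlaps(p)
    raise ValueError(f"unknown scheme {scheme!r}")


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __iadd__(self, other):
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


def match_spans(
    gold: Sequence[EntitySpan],
    predicted: Sequence[EntitySpan],
    scheme: str,
    require_type: bool = True,
) -> dict[str, MatchCounts]:
    """Per-type TP/FP/FN for one sentence under a one-to-one assignment.

    Greedy by gold start: each gold span takes the first matching, unused
    prediction (predictions ordered by start).  Unmatched predictions are
    FP, unmatched gold are FN.
    """
    gold = validate_spans(gold)
    predicted = validate_spans(predicted)
    counts: dict[str, MatchCounts] = {}
    used = [False] * len(predicted)
    for g in gold:
        c = counts.setdefault(g.type, MatchCounts())
        hit = False
        for j, p in enumerate(predicted):
            if used[j]:
                continue
            if _spans_match(g, p, scheme, require_type):
                used[j] = True
                hit = True
                break
        if hit:
            c.tp += 1
        else:
            c.fn += 1
    for j, p in enumerate(predicted):
        if not used[j]:
            counts.setdefault(p.type, MatchCounts()).fp += 1
    return counts


def match_documents(
    gold_docs: Sequence[Document],
    pred_docs: Sequence[Document],
    scheme: str,
    require_type: bool = True,
) -> dict[str, MatchCounts]:
    if len(gold_docs) != len(pred_docs):
        raise CorpusError("gold and predicted corpora differ in document count")
    totals: dict[str, MatchCounts] = {}
    for gd, pd_ in zip(gold_docs, pred_docs):
        if len(gd.sentences) != len(pd_.sentences):
            raise CorpusError(f"sentence count mismatch in document {gd.id!r}")
        for gs, ps in zip(gd.sentences, pd_.sentences):
            for t, c in match_spans(gs.spans, ps.spans, scheme, require_type).items():
                totals.setdefault(t, MatchCounts())
                totals[t] += c
    return totals


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


@dataclass
class EvalReport:
    """Per-type and aggregated precision/recall/F1 under one match scheme."""

    scheme: str
    per_type: dict[str, dict] = field(default_factory=dict)
    macro: dict = field(default_factory=dict)
    micro: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"entity_type": t, **metrics} for t, metrics in sorted(self.per_type.items())
        ]
        rows.append({"entity_type": "macro", **self.macro})
        rows.append({"entity_type": "micro", **self.micro})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "per_type": self.per_type,
            "macro": self.macro,
            "micro": self.micro,
        }


def score(counts: dict[str, MatchCounts], scheme: str = "exact") -> EvalReport:
    """Aggregate per-type counts into an evaluation report.

    Macro averages over exactly the types present in gold (TP + FN > 0);
    micro pools counts over all types.  Undefined ratios (0/0) report 0.
    """
    report = EvalReport(scheme=scheme)
    macro_f1s, macro_ps, macro_rs = [], [], []
    tot = MatchCounts()
    for t, c in counts.items():
        p, r, f = _prf(c.tp, c.fp, c.fn)
        report.per_type[t] = {
            "precision": p, "recall": r, "f1": f, "tp": c.tp, "fp": c.fp, "fn": c.fn,
        }
        tot += c
        if c.tp + c.fn > 0:  # gold-present types only
            macro_ps.append(p)
            macro_rs.append(r)
            macro_f1s.append(f)
    mp = float(np.mean(macro_ps)) if macro_ps else 0.0
    mr = float(np.mean(macro_rs)) if macro_rs else 0.0
    mf = float(np.mean(macro_f1s)) if macro_f1s else 0.0
    report.macro = {"precision": mp, "recall": mr, "f1": mf}
    p, r, f = _prf(tot.tp, tot.fp, tot.fn)
    report.micro = {"precision": p, "recall": r, "f1": f, "tp": tot.tp, "fp": tot.fp, "fn": tot.fn}
    return report


def evaluate(gold_docs, pred_docs, scheme: str, require_type: bool = True) -> EvalReport:
    return score(match_documents(gold_docs, pred_docs, scheme, require_type), scheme)


def evaluate_both_schemes(gold_docs, pred_docs) -> dict[str, EvalReport]:
    """Evaluate under both schemes and assert inexact dominates exact."""
    out = {s: evaluate(gold_docs, pred_docs, s) for s in SCHEMES}
    if out["inexact"].micro["f1"] < out["exact"].micro["f1"] - 1e-12:
        raise AssertionError("inexact-match F1 fell below exact-match F1")
    return out


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def _max_matching_counts(gold, predicted, scheme, require_type=True) -> dict[str, MatchCounts]:
    """Maximum-cardinality bipartite matching oracle (per type)."""
    counts: dict[str, MatchCounts] = {}
    types = {s.type for s in gold} | {s.type for s in predicted}
    for t in sorted(types):
        G = nx.Graph()
        gs = [s for s in gold if s.type == t]
        ps = [s for s in predicted if s.type == t]
        left = [("g", i) for i in range(len(gs))]
        right = [("p", j) for j in range(len(ps))]
        G.add_nodes_from(left, bipartite=0)
        G.add_nodes_from(right, bipartite=1)
        for i, g in enumerate(gs):
            for j, p in enumerate(ps):
                if _spans_match(g, p, scheme, require_type):
                    G.add_edge(("g", i), ("p", j))
        matching = nx.algorithms.matching.max_weight_matching(G, maxcardinality=True)
        tp = len(matching)
        counts[t] = MatchCounts(tp=tp, fp=len(ps) - tp, fn=len(gs) - tp)
    return counts


def oracle_equivalence_check(gold, predicted, scheme: str) -> bool:
    """True iff the greedy engine's counts equal the maximum-matching oracle's."""
    a = match_spans(gold, predicted, scheme)
    b = _max_matching_counts(gold, predicted, scheme)
    keys = set(a) | set(b)
    return all(
        (a.get(k, MatchCounts()).tp, a.get(k, MatchCounts()).fp, a.get(k, MatchCounts()).fn)
        == (b.get(k, MatchCounts()).tp, b.get(k, MatchCounts()).fp, b.get(k, MatchCounts()).fn)
        for k in keys
    )


# ---------------------------------------------------------------------------
# Annotator agreement
# ---------------------------------------------------------------------------

def cohen_kappa(tags_a: Sequence[str], tags_b: Sequence[str]) -> float:
    """Chance-corrected agreement between two BIO tag sequences.

    Computed per character over the full label alphabet (B-T, I-T and O all
    distinct), the unit at which annotation happens.
    """
    if len(tags_a) != len(tags_b):
        raise ValueError("tag sequences must have equal length")
    if list(tags_a) == list(tags_b):
        return 1.0
    return float(cohen_kappa_score(list(tags_a), list(tags_b)))


def corpus_kappa(docs_a: Sequence[Document], docs_b: Sequence[Document]) -> float:
    tags_a = [t for d in docs_a for s in d.sentences for t in (s.tags or s.with_tags().tags)]
    tags_b = [t for d in docs_b for s in d.sentences for t in (s.tags or s.with_tags().tags)]
    return cohen_kappa(tags_a, tags_b)


def format_mean_std(values: Iterable[float], decimals: int = 2) -> str:
    """Render a multi-run metric as ``mean ± sample-std`` (e.g. ``85.00 ± 7.07``)."""
    vals = np.asarray(list(values), dtype=float)
    std = vals.std(ddof=1) if len(vals) > 1 else 0.0
    return f"{vals.mean():.{decimals}f} ± {std:.{decimals}f}"
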