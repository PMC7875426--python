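"""Benchmark scoring of ranked edge lists and gene-class enrichment.

AUPR uses the step (average-precision) curve: sweeping the inclusion
threshold down the ranking, each recovered true edge contributes the
precision at its rank.  Candidate edges absent from the ranking are treated
as one tied block at the bottom, whose precision is the prevalence floor.
AUROC equals the tie-corrected (midrank) Mann-Whitney statistic of
true-versus-false score separation.

Enrichment of a gene class among selected (e.g. causal) genes is a 2x2
contingency table scored with the sample odds ratio (a*d)/(b*c) and a
two-sided Fisher exact p-value, Benjamini-Hochberg adjusted across a batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GoldStandard",
    "EnrichmentTable",
    "aupr",
    "auroc",
    "class_enrichment",
    "adjust_enrichment_batch",
    "read_gold_standard",
    "write_gold_standard",
]


@dataclass(frozen=True)
class GoldStandard:
    """Ground-truth directed edges over a declared gene universe."""

    universe: tuple[str, ...]
    true_edges: frozenset  # of (cause, effect)

    def __post_init__(self) -> None:
        object.__setattr__(self, "universe", tuple(self.universe))
        object.__setattr__(self, "true_edges", frozenset(self.true_edges))
        uni = set(self.universe)
        for c, e in self.true_edges:
            if c == e:
                raise ValueError(f"gold standard contains self-edge {c!r}")
            if c not in uni or e not in uni:
                raise ValueError(f"edge ({c!r}, {e!r}) outside the gene universe")

    def all_candidates(self) -> list:
        """Every ordered pair excluding self-edges, in deterministic order."""
        return [(c, e) for c in self.universe for e in self.universe if c != e]

    @property
    def prevalence(self) -> float:
        n = len(self.universe)
        return len(self.true_edges) / (n * (n - 1))


def _scores_and_labels(ranked_edges, gold: GoldStandard):
    """Scores over the full candidate universe; unranked edges tie at the bottom."""
    if not gold.true_edges:
        raise ValueError("gold standard has no true edges; metrics are undefined")
    seen = set()
    for edge in ranked_edges:
        if edge in seen:
            raise ValueError(f"duplicate edge {edge!r} in ranking")
        if edge[0] == edge[1]:
            raise ValueError(f"self-edge {edge!r} in ranking")
        seen.add(edge)
    candidates = gold.all_candidates()
    rank = {edge: i for i, edge in enumerate(ranked_edges)}
    n_ranked = len(rank)
    # ranked edges get descending positive scores; everything unranked ties at 0
    scores = np.array([n_ranked - rank.get(e, n_ranked) for e in candidates], dtype=float)
    labels = np.array([e in gold.true_edges for e in candidates], dtype=bool)
    return scores, labels


def _aupr_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    P = int(y.sum())
    area = 0.0
    tp = fp = 0
    i = 0
    n = s.size
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        block_tp = int(y[i:j].sum())
        tp += block_tp
        fp += (j - i) - block_tp
        if block_tp:
            precision = tp / (tp + fp)
            area += precision * (block_tp / P)
        i = j
    return float(area)


def aupr(ranked_edges, gold: GoldStandard) -> float:
    """Area under the precision-recall step curve of a ranked edge list."""
    scores, labels = _scores_and_labels(list(ranked_edges), gold)
    return _aupr_from_scores(scores, labels)


def auroc(ranked_edges, gold: GoldStandard) -> float:
    """Midrank AUROC; equals the Mann-Whitney statistic of the ranking."""
    scores, labels = _scores_and_labels(list(ranked_edges), gold)
    return auroc_from_scores(scores, labels)


def auroc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC of arbitrary scores with midrank tie handling."""
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative candidates")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass(frozen=True)
class EnrichmentTable:
    """2x2 contingency table for one gene class against a selected set."""

    class_name: str
    a: int  # selected and in class
    b: int  # selected, not in class
    c: int  # in class, not selected
    d: int  # neither
    odds_ratio: float
    p_value: float
    p_adjusted: float = float("nan")


def class_enrichment(
    universe_size: int,
    class_size: int,
    selected_size: int,
    overlap: int,
    class_name: str = "",
) -> EnrichmentTable:
    """Fisher-exact enrichment of a gene class among a selected gene set.

    The sample odds ratio (a*d)/(b*c) is reported (infinite when b*c = 0
    and a*d > 0); the p-value is the two-sided Fisher exact test.
    """
    a = overlap
    b = selected_size - overlap
    c = class_size - overlap
    d = universe_size - selected_size - c
    if min(a, b, c, d) < 0 or overlap > min(class_size, selected_size):
        raise ValueError(
            f"inconsistent counts: universe={universe_size}, class={class_size}, "
            f"selected={selected_size}, overlap={overlap}"
        )
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    # p-value from the conditional exact test; the reported OR stays the sample OR
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentTable(class_name, a, b, c, d, odds, float(p))


def adjust_enrichment_batch(tables: list[EnrichmentTable]) -> list[EnrichmentTable]:
    """Benjamini-Hochberg adjustment across a batch of enrichment tests."""
    if not tables:
        return []
    _, p_adj, _, _ = multipletests([t.p_value for t in tables], method="fdr_bh")
    return [
        EnrichmentTable(t.class_name, t.a, t.b, t.c, t.d, t.odds_ratio, t.p_value, float(q))
        for t, q in zip(tables, p_adj)
    ]


def read_gold_standard(path) -> GoldStandard:
    """Read a DREAM-style gold standard: ``cause<TAB>effect<TAB>{0|1}`` lines.

    Flag-1 lines are true edges; flag-0 lines are explicit negatives.  The
    universe is the set of genes mentioned on any line.
    """
    true_edges = set()
    genes: dict[str, None] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[2] not in ("0", "1"):
                raise ValueError(f"malformed gold-standard line {lineno}: {line!r}")
            cause, effect, flag = parts
            genes.setdefault(cause)
            genes.setdefault(effect)
            if flag == "1":
                true_edges.add((cause, effect))
    return GoldStandard(tuple(sorted(genes)), frozenset(true_edges))


def write_gold_standard(gold: GoldStandard, path) -> None:
    """Write every candidate pair with its 0/1 truth flag (round-trippable)."""
    with open(path, "w", encoding="utf-8") as fh:
        for c, e in gold.all_candidates():
            flag = 1 if (c, e) in gold.true_edges else 0
            fh.write(f"{c}\t{e}\t{flag}\n")


def metrics_report(entries: list[tuple[str, float, float]]) -> pd.DataFrame:
    """Tabulate (network, AUPR, AUROC) rows for export."""
    return pd.DataFrame(entries, columns=["network", "AUPR", "AUROC"])
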