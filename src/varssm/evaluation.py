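"""Benchmark metrics: confusion counts, confidence aggregation, ROC/PR curves.

Edges are directed gene->gene pairs; self-regulation and exogenous-input
edges are excluded from the tallies by default, matching how network
inference benchmarks are usually scored.  For methods that only recover
undirected association, the directed truth can be projected to undirected
pairs before counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionResult",
    "ConfidenceMatrix",
    "confusion",
    "aggregate_confidence",
    "roc_pr",
    "report_table",
]


@dataclass
class ConfusionResult:
    tp: int
    fp: int
    fn: int
    tn: int
    pr: float
    rr: float
    f1: float


def _normalize_edges(edges, genes: list[str], directed: bool) -> set[tuple[str, str]]:
    gset = set(genes)
    out = set()
    for a, b in edges:
        if a not in gset or b not in gset:
            raise ValueError(f"edge ({a}, {b}) references unknown gene")
        if a == b:
            continue  # self-regulation is never counted
        out.add((a, b) if directed else (min(a, b), max(a, b)))
    return out


def confusion(truth, estimate, genes, directed: bool = True) -> ConfusionResult:
    """Confusion counts over all non-self gene pairs.

    ``directed=False`` projects both edge sets onto unordered pairs (how an
    undirected-output method is scored against a directed truth).  Exogenous
    edges should be filtered out by the caller (estimate edge lists from the
    search already flag them).
    """
    genes = list(genes)
    t = _normalize_edges(truth, genes, directed)
    e = _normalize_edges(estimate, genes, directed)
    n = len(genes)
    n_pairs = n * (n - 1) if directed else n * (n - 1) // 2
    tp = len(t & e)
    fp = len(e - t)
    fn = len(t - e)
    tn = n_pairs - tp - fp - fn
    pr = tp / (tp + fp) if tp + fp > 0 else 0.0
    rr = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * pr * rr / (pr + rr) if pr + rr > 0 else 0.0
    return ConfusionResult(tp, fp, fn, tn, pr, rr, f1)


@dataclass
class ConfidenceMatrix:
    """w[i, j] counts the runs in which gene j -> gene i was estimated."""

    w: np.ndarray
    genes: list[str]
    n_runs: int


def aggregate_confidence(estimates, genes) -> ConfidenceMatrix:
    """Sum edge indicator matrices over runs: the count is the confidence level."""
    genes = list(genes)
    if not estimates:
        raise ValueError("need at least one estimate")
    gi = {g: i for i, g in enumerate(genes)}
    w = np.zeros((len(genes), len(genes)), dtype=int)
    for est in estimates:
        for a, b in est:
            if a not in gi or b not in gi:
                raise ValueError(f"edge ({a}, {b}) references unknown gene")
            if a != b:
                w[gi[b], gi[a]] += 1
    return ConfidenceMatrix(w, genes, len(estimates))


def roc_pr(conf: ConfidenceMatrix, truth, directed: bool = True):
    """ROC and PR curves from a confidence ranking over non-self gene pairs.

    Sweeps the distinct confidence values as thresholds ("estimate every pair
    with confidence >= c"), anchors the ROC at (0,0) and (1,1), and computes
    trapezoidal areas.  When every pair carries the same confidence the
    ranking is uninformative and AUROC is 0.5 by convention.

    Returns ``(roc_points, pr_points, auroc, aupr)`` where points are
    (FPR, TPR) and (recall, precision) arrays.
    """
    genes = conf.genes
    gi = {g: i for i, g in enumerate(genes)}
    t = _normalize_edges(truth, genes, directed)
    if not t:
        raise ValueError("truth edge set is empty")
    n = len(genes)
    scores, labels = [], []
    if directed:
        pairs = [(a, b) for a in range(n) for b in range(n) if a != b]
    else:
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    for a, b in pairs:
        s = conf.w[b, a] if directed else max(conf.w[b, a], conf.w[a, b])
        key = (genes[a], genes[b]) if directed else tuple(sorted((genes[a], genes[b])))
        scores.append(s)
        labels.append(key in t)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    P = int(labels.sum())
    Nn = labels.size - P

    if np.all(scores == scores[0]):
        warnings.warn("all confidence values identical; curves are degenerate",
                      UserWarning, stacklevel=2)
        roc = np.array([[0.0, 0.0], [1.0, 1.0]])
        pr = np.array([[0.0, P / labels.size], [1.0, P / labels.size]])
        return roc, pr, 0.5, P / labels.size

    thresholds = np.sort(np.unique(scores))[::-1]
    roc_pts = [(0.0, 0.0)]
    pr_pts = []
    for c in thresholds:
        sel = scores >= c
        tp = int(np.sum(sel & labels))
        fp = int(np.sum(sel & ~labels))
        tpr = tp / P
        fpr = fp / Nn if Nn else 0.0
        roc_pts.append((fpr, tpr))
        if tp + fp > 0:
            pr_pts.append((tpr, tp / (tp + fp)))
    if roc_pts[-1] != (1.0, 1.0):
        roc_pts.append((1.0, 1.0))
    # PR endpoint at zero recall: carry the first attained precision flat
    pr_pts = sorted(pr_pts)
    if pr_pts and pr_pts[0][0] > 0.0:
        pr_pts.insert(0, (0.0, pr_pts[0][1]))
    roc = np.asarray(roc_pts)
    pr = np.asarray(pr_pts)
    auroc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    aupr = float(np.trapezoid(pr[:, 1], pr[:, 0]))
    return roc, pr, auroc, aupr


def report_table(rows: dict[str, ConfusionResult]) -> str:
    """Benchmark-style tabular report (PR, RR, TP, FP, TN, FN per method)."""
    lines = ["method\tPR\tRR\tTP\tFP\tTN\tFN"]
    for name, c in rows.items():
        lines.append(f"{name}\t{c.pr:.3f}\t{c.rr:.3f}\t{c.tp}\t{c.fp}\t{c.tn}\t{c.fn}")
    return "\n".join(lines) + "\n"
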