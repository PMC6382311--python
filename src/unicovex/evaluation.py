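"""Evaluation against a reference cancer-gene list.

Precision is the fraction of predicted genes (the union over consensus
modules) that appear in the reference list; recall is the fraction of
reference genes *mutated in the cohort* that were predicted. Threshold-
swept precision–recall and ROC curves over a full gene ranking give
AUPR (average-precision convention) and AUC (trapezoid).

The ranking rule: every cohort-mutated gene is scored by the maximum
composite score of any catalog module containing it (0 when none);
unranked genes are appended with score 0 in lexicographic order so the
sweep is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

from .discovery import ModuleCatalog

__all__ = [
    "EvaluationReport",
    "precision_recall",
    "ranked_curves",
    "rank_genes_by_module_score",
    "read_gene_list",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Precision/recall plus swept curves and their areas."""

    n_predicted: int
    n_hits: int
    precision: float | None  # None flags an empty prediction set
    recall: float | None  # None when no reference gene is mutated in cohort
    pr_points: tuple[tuple[float, float], ...] = ()  # (recall, precision)
    roc_points: tuple[tuple[float, float], ...] = ()  # (fpr, tpr)
    aupr: float | None = None
    auc: float | None = None


def read_gene_list(path: str | Path) -> set[str]:
    """Plain-text reference list, one gene symbol per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def precision_recall(
    predicted: Iterable[str],
    reference: Iterable[str],
    cohort_mutated: Iterable[str],
) -> tuple[float | None, float | None]:
    """Cohort-level precision and recall of a predicted gene set.

    recall's denominator is the reference genes mutated in the cohort;
    precision is None (flagged) for an empty prediction, recall None
    when the reference does not intersect the cohort.
    """
    predicted = set(predicted)
    reference = set(reference)
    cohort = set(cohort_mutated)
    if not predicted <= cohort:
        warnings.warn(
            f"{len(predicted - cohort)} predicted gene(s) not in the cohort-mutated set",
            stacklevel=2,
        )
    hits = predicted & reference
    precision = len(hits) / len(predicted) if predicted else None
    denom = reference & cohort
    recall = len(hits) / len(denom) if denom else None
    return precision, recall


def rank_genes_by_module_score(
    catalog: ModuleCatalog, cohort_mutated: Iterable[str]
) -> list[tuple[str, float]]:
    """Score each cohort-mutated gene by the best composite of any
    catalog module containing it; genes in no module score 0."""
    best: dict[str, float] = {}
    for mod in catalog.all_modules():
        c = mod.score.composite if mod.score else 0.0
        for g in mod.genes:
            if c > best.get(g, -1.0):
                best[g] = c
    return sorted(
        ((g, best.get(g, 0.0)) for g in set(cohort_mutated)),
        key=lambda t: (-t[1], t[0]),
    )


def ranked_curves(
    gene_ranking: Sequence[tuple[str, float]],
    reference: Iterable[str],
    cohort_mutated: Iterable[str],
) -> EvaluationReport:
    """Sweep a gene ranking into PR and ROC curves with areas.

    The ranking is completed with any missing cohort-mutated genes at
    score 0 (lexicographic tail). AUPR follows the step-wise
    average-precision convention; AUC is the trapezoid under the ROC.
    """
    reference = set(reference)
    cohort = set(cohort_mutated)
    positives = reference & cohort
    if not positives:
        raise ValueError("reference genes are disjoint from the cohort; curves undefined")
    ranked = [g for g, _ in gene_ranking if g in cohort]
    ranked += sorted(cohort - set(ranked))
    n_pos = len(positives)
    n_neg = len(ranked) - n_pos

    pr_points: list[tuple[float, float]] = []
    roc_points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    aupr = 0.0
    prev_recall = 0.0
    for g in ranked:
        if g in positives:
            tp += 1
        else:
            fp += 1
        rec = tp / n_pos
        prec = tp / (tp + fp)
        pr_points.append((rec, prec))
        aupr += (rec - prev_recall) * prec
        prev_recall = rec
        roc_points.append((fp / n_neg if n_neg else 0.0, rec))
    auc = _trapezoid(roc_points) if n_neg else None

    top = [g for g, s in gene_ranking if s > 0]
    hits = set(top) & positives
    return EvaluationReport(
        n_predicted=len(top),
        n_hits=len(hits),
        precision=len(hits) / len(top) if top else None,
        recall=len(hits) / n_pos,
        pr_points=tuple(pr_points),
        roc_points=tuple(roc_points),
        aupr=aupr,
        auc=auc,
    )


def _trapezoid(points: Sequence[tuple[float, float]]) -> float:
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def plot_curves(report: EvaluationReport, path: str | Path) -> None:
    """Export a PR + ROC figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    if report.pr_points:
        ax1.plot(*zip(*report.pr_points), drawstyle="steps-post")
    ax1.set_xlabel("recall")
    ax1.set_ylabel("precision")
    ax1.set_title(f"PR (AUPR={report.aupr:.3f})" if report.aupr is not None else "PR")
    if report.roc_points:
        ax2.plot(*zip(*report.roc_points))
    ax2.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax2.set_xlabel("FPR")
    ax2.set_ylabel("TPR")
    ax2.set_title(f"ROC (AUC={report.auc:.3f})" if report.auc is not None else "ROC")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
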