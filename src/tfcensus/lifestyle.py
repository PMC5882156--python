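"""Lifestyle-stratified TF content: proportions, rank test, family clustering."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .io_model import LIFESTYLES, GenomeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LifestyleSummary:
    """Box-plot summary of per-genome TF proportions for one lifestyle."""

    lifestyle: str
    n_genomes: int
    proportions: np.ndarray
    median: float
    minimum: float
    maximum: float
    outliers: tuple[float, ...] = field(default_factory=tuple)


def tf_proportions(
    counts: pd.DataFrame, genomes: Sequence[GenomeRecord]
) -> dict[str, LifestyleSummary]:
    """Per-genome TF proportion (total TFs / ORFs), grouped by lifestyle.

    Outliers are values beyond 1.5*IQR from the quartiles, as in a standard
    box plot.  A genome with a label outside the closed vocabulary raises.
    """
    by_label: dict[str, list[float]] = {}
    totals = counts.sum(axis=0)
    for g in genomes:
        if g.lifestyle not in LIFESTYLES:
            raise ValueError(
                f"genome {g.genome_id}: unknown lifestyle {g.lifestyle!r}"
            )
        prop = float(totals.get(g.genome_id, 0)) / g.n_orfs
        by_label.setdefault(g.lifestyle, []).append(prop)

    out: dict[str, LifestyleSummary] = {}
    for label, vals in by_label.items():
        a = np.asarray(vals, dtype=float)
        q1, q3 = np.percentile(a, [25, 75])
        iqr = q3 - q1
        outliers = tuple(
            float(v) for v in a if v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr
        )
        out[label] = LifestyleSummary(
            lifestyle=label,
            n_genomes=a.size,
            proportions=a,
            median=float(np.median(a)),
            minimum=float(a.min()),
            maximum=float(a.max()),
            outliers=outliers,
        )
    return out


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    All-identical observations give (H=0, p=1) rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)


def family_lifestyle_rates(
    counts: pd.DataFrame, genomes: Sequence[GenomeRecord]
) -> pd.DataFrame:
    """Family x lifestyle rate matrix.

    rate[f, L] = (sum of family-f counts over genomes of lifestyle L)
    divided by the total ORFs of those genomes.  Lifestyles with zero
    genomes are dropped with a warning.
    """
    cols = {}
    for label in LIFESTYLES:
        members = [g for g in genomes if g.lifestyle == label]
        if not members:
            logger.warning("lifestyle %r has zero genomes; column dropped", label)
            continue
        ids = [g.genome_id for g in members if g.genome_id in counts.columns]
        total_orfs = sum(g.n_orfs for g in members)
        cols[label] = counts[ids].sum(axis=1) / total_orfs
    return pd.DataFrame(cols)


def uncentered_correlation_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - uncentered Pearson similarity (no mean subtraction)."""
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return 0.0
    return float(1.0 - (x * y).sum() / denom)


@dataclass(frozen=True)
class ClusterResult:
    labels: tuple[str, ...]          # row labels in input order
    linkage: np.ndarray              # scipy linkage matrix
    merge_heights: tuple[float, ...]
    flat_groups: dict[str, int]      # label -> group id for the k-group cut
    newick: str


def _to_newick(node: sch.ClusterNode, labels: Sequence[str]) -> str:
    if node.is_leaf():
        return labels[node.id].replace(" ", "_").replace(",", "_")
    left = _to_newick(node.left, labels)
    right = _to_newick(node.right, labels)
    dl = max(node.dist - node.left.dist, 0.0)
    dr = max(node.dist - node.right.dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_families(
    rates: pd.DataFrame,
    metric: str = "manhattan",
    normalize_rows: bool = True,
    n_groups: int = 4,
) -> ClusterResult:
    """Average-linkage (UPGMA) clustering of the family rate rows.

    Primary metric is Manhattan (L1); ``metric="uncentered"`` uses
    1 - uncentered correlation instead.  Rows are optionally scaled by
    their maximum first (relative-abundance view).  Rows are ordered
    lexicographically before linkage so results are independent of input
    row order.
    """
    if rates.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    ordered = rates.sort_index()
    x = ordered.to_numpy(dtype=float)
    if normalize_rows:
        row_max = x.max(axis=1, keepdims=True)
        row_max[row_max == 0] = 1.0
        x = x / row_max
    if metric == "manhattan":
        z = sch.linkage(x, method="average", metric="cityblock")
    elif metric == "uncentered":
        from scipy.spatial.distance import pdist

        d = pdist(x, metric=lambda a, b: uncentered_correlation_distance(a, b))
        z = sch.linkage(d, method="average")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    labels = tuple(ordered.index)
    k = min(n_groups, len(labels))
    flat = sch.fcluster(z, t=k, criterion="maxclust")
    tree = sch.to_tree(z)
    return ClusterResult(
        labels=labels,
        linkage=z,
        merge_heights=tuple(float(h) for h in z[:, 2]),
        flat_groups={lab: int(g) for lab, g in zip(labels, flat)},
        newick=_to_newick(tree, labels) + ";",
    )


__all__ = [
    "LifestyleSummary", "ClusterResult",
    "tf_proportions", "kruskal_wallis", "family_lifestyle_rates",
    "cluster_families", "uncentered_correlation_distance",
]
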