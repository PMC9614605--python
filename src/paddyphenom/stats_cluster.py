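"""Descriptive statistics, correlations, detection evaluation, clustering.

Covers the analysis layer of the pipeline: per-trait Min/Max/Mean/STD/CV
summary rows, Pearson trait correlations, point-detection evaluation
(greedy center matching with precision/recall and a count-accuracy
metric), and hierarchical genotype clustering with Newick export.

"Detection accuracy" for point counting is defined here as

    count_accuracy = 100 * (1 - |NL_pred - NL_true| / NL_true)

i.e. 100% minus the relative counting error; precision and recall over
center-matched pairs are reported alongside so either reading of
accuracy is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist

from .plantseg_tips import TipSet


def coefficient_of_variation(mean: float, std: float) -> float:
    """CV% = 100 * std / mean; NaN-flagged for a zero mean."""
    if mean == 0:
        return float("nan")
    return 100.0 * std / mean


def descriptive_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Min/Max/Mean/STD/CV summary per trait column (sample std, n-1).

    Returns a DataFrame indexed by trait name with columns
    ``min, max, mean, std, cv_percent``; full precision is retained (any
    rounding for export is the caller's concern).
    """
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] == 0:
        raise ValueError("no numeric trait columns")
    if (num.count() < 2).any():
        raise ValueError("each trait column needs at least 2 observations")
    mean = num.mean()
    std = num.std(ddof=1)
    cv = pd.Series(
        [coefficient_of_variation(m, s) for m, s in zip(mean, std)], index=mean.index
    )
    out = pd.DataFrame(
        {"min": num.min(), "max": num.max(), "mean": mean, "std": std, "cv_percent": cv}
    )
    out.index.name = "trait_name"
    return out


def pearson_corr(table: pd.DataFrame, pairs: list[tuple[str, str]] | None = None):
    """Pearson product-moment correlations.

    With ``pairs`` given, returns a Series keyed by pair; otherwise the
    full correlation matrix. Zero-variance columns yield NaN.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("correlation needs at least 3 paired observations")
    corr = num.corr(method="pearson")
    if pairs is None:
        return corr
    return pd.Series({(a, b): corr.loc[a, b] for a, b in pairs})


@dataclass
class MatchReport:
    """Point-detection evaluation for one image."""

    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    count_accuracy_percent: float   # NaN when there is no ground truth


def count_accuracy(n_pred: int, n_true: int) -> float:
    """100 * (1 - relative counting error); NaN when the truth is empty."""
    if n_true == 0:
        return float("nan")
    return 100.0 * (1.0 - abs(n_pred - n_true) / n_true)


def match_detections(
    pred: TipSet, gt: TipSet, tau_px: float = 16.0, optimal: bool = False
) -> MatchReport:
    """Match predicted to ground-truth tip centers within ``tau_px``.

    Default matching is greedy in ascending center distance, each
    prediction and each ground-truth tip used at most once; ``optimal``
    switches to a Hungarian maximum-cardinality assignment for audits.
    """
    p = pred.centers()
    g = gt.centers()
    tp = 0
    if len(p) and len(g):
        d = np.hypot(p[:, 0, None] - g[None, :, 0], p[:, 1, None] - g[None, :, 1])
        if optimal:
            cost = np.where(d <= tau_px, d, 1e9)
            ri, ci = linear_sum_assignment(cost)
            tp = int(np.sum(d[ri, ci] <= tau_px))
        else:
            order = np.argsort(d, axis=None, kind="stable")
            used_p: set[int] = set()
            used_g: set[int] = set()
            for flat in order:
                i, j = divmod(int(flat), d.shape[1])
                if d[i, j] > tau_px:
                    break
                if i in used_p or j in used_g:
                    continue
                used_p.add(i)
                used_g.add(j)
                tp += 1
    fp = len(p) - tp
    fn = len(g) - tp
    precision = tp / len(p) if len(p) else 0.0
    recall = tp / len(g) if len(g) else 0.0
    return MatchReport(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=precision,
        recall=recall,
        count_accuracy_percent=count_accuracy(len(p), len(g)),
    )


@dataclass
class GenotypeTree:
    """Agglomerative merge history over genotype trait vectors."""

    labels: list[str]
    linkage: np.ndarray | None      # scipy linkage matrix; None for a singleton
    method: str

    def cut(self, k: int) -> dict[str, int]:
        """Cut the tree into ``k`` groups; returns genotype -> group id (1-based)."""
        n = len(self.labels)
        if not 1 <= k <= n:
            raise ValueError(f"k must lie in 1..{n}")
        if self.linkage is None:
            return {self.labels[0]: 1}
        assignments = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))

    def newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        if self.linkage is None:
            return f"({self.labels[0]});"
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_dist: float) -> str:
            bl = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{bl:.6g}"
            return f"({fmt(node.left, node.dist)},{fmt(node.right, node.dist)}):{bl:.6g}"

        return f"({fmt(root.left, root.dist)},{fmt(root.right, root.dist)});"


def cluster_genotypes(
    matrix: pd.DataFrame, linkage: str = "average", k: int | None = None
) -> GenotypeTree | tuple[GenotypeTree, dict[str, int]]:
    """Hierarchical clustering of a genotype x trait matrix.

    Trait columns are standardised (zero mean, unit variance; constant
    columns are left at zero) before Euclidean distances and
    agglomeration with the chosen linkage. Deterministic for a fixed
    input (scipy breaks distance ties by lowest pair index). With ``k``
    given, also returns the cut assignments.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    num = matrix.select_dtypes(include=[np.number])
    if num.isna().any().any():
        raise ValueError("trait matrix contains missing values; impute first")
    labels = [str(i) for i in matrix.index]
    if len(labels) != len(set(labels)):
        raise ValueError("genotype ids must be unique")
    if len(labels) == 1:
        tree = GenotypeTree(labels=labels, linkage=None, method=linkage)
        return (tree, tree.cut(k)) if k is not None else tree
    x = num.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    lk = hierarchy.linkage(pdist(z, metric="euclidean"), method=linkage)
    tree = GenotypeTree(labels=labels, linkage=lk, method=linkage)
    if k is not None:
        return tree, tree.cut(k)
    return tree


def export_newick(tree: GenotypeTree, path: str | Path) -> Path:
    """Write the dendrogram as a Newick file."""
    path = Path(path)
    path.write_text(tree.newick() + "\n")
    return path


def plot_dendrogram(tree: GenotypeTree, path: str | Path) -> Path:
    """Basic dendrogram plot (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, max(3, 0.25 * len(tree.labels))))
    if tree.linkage is not None:
        hierarchy.dendrogram(tree.linkage, labels=tree.labels, orientation="right", ax=ax)
    ax.set_xlabel("merge height (standardised Euclidean)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
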