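"""Correlation-based hierarchical clustering with multiscale-bootstrap support.

Compounds are clustered on the dissimilarity ``d(i, j) = 1 - cor(x_i, x_j)``
of their feature profiles (similarity columns, docking-score profiles, or
network-effect profiles).  Cluster confidence is assessed by multiscale
bootstrap resampling of the feature columns: for a grid of scales ``r`` the
features are resampled with replacement to size ``round(r * n_features)``,
the tree is rebuilt, and for every observed cluster the fraction of
replicates in which its exact leaf set reappears is recorded
(``BP_r``).  Writing ``sigma = 1 / sqrt(r)``, the probit-transformed
bootstrap probabilities follow, to good approximation,

    Phi^{-1}(1 - BP_r) = v / sigma + c * sigma  =  v * sqrt(r) + c / sqrt(r)

where ``v`` measures the signed distance of the data from the cluster's
decision boundary and ``c`` the boundary's curvature.  A weighted
least-squares fit of ``(v, c)`` across scales yields the approximately
unbiased p-value ``AU = 1 - Phi(v - c)`` and the smoothed bootstrap
probability ``BP = 1 - Phi(v + c)``.  ``AU`` corrects the downward bias of
the ordinary bootstrap probability at scale 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import norm, pearsonr
from sklearn.metrics import adjusted_rand_score, fowlkes_mallows_score

logger = logging.getLogger(__name__)

__all__ = [
    "DissimilarityMatrix",
    "ClusterTree",
    "ClusterSupport",
    "TreeComparison",
    "correlation_dissimilarity",
    "hierarchical_cluster",
    "multiscale_bootstrap",
    "fit_au",
    "compare_trees",
    "to_newick",
    "support_table",
    "plot_dendrogram",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.41, 0.1), 1))
LINKAGES = {"average", "complete", "single", "ward"}


@dataclass
class DissimilarityMatrix:
    """Symmetric 1 - Pearson-correlation dissimilarity; diagonal 0, entries in [0, 2]."""

    labels: list[str]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _corr_dissimilarity_values(x: np.ndarray) -> np.ndarray:
    """1 - rowwise Pearson correlation; rows with zero variance correlate 0."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc * xc).sum(axis=1))
    safe = norms.copy()
    safe[safe == 0] = 1.0  # zero-variance rows -> correlation treated as 0
    xn = xc / safe[:, None]
    corr = xn @ xn.T
    np.clip(corr, -1.0, 1.0, out=corr)
    d = 1.0 - corr
    np.clip(d, 0.0, 2.0, out=d)  # clamp rounding-level negatives
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def correlation_dissimilarity(features: pd.DataFrame) -> DissimilarityMatrix:
    """``d(i, j) = 1 - cor(row_i, row_j)`` over item feature profiles.

    Requires >= 2 items, >= 3 features per item and nonzero per-item feature
    variance (a flat profile has no defined correlation and is an error
    naming the item).
    """
    if features.shape[0] < 2:
        raise ValueError("need at least 2 items to compute dissimilarities")
    if features.shape[1] < 3:
        raise ValueError("need at least 3 features per item")
    x = features.to_numpy(dtype=float)
    if np.isnan(x).any():
        bad = features.index[np.isnan(x).any(axis=1)].tolist()
        raise ValueError(f"missing feature values for items: {bad}")
    variances = x.var(axis=1)
    if (variances == 0).any():
        flat = features.index[variances == 0].tolist()
        raise ValueError(f"zero feature variance for items: {flat}")
    return DissimilarityMatrix(
        labels=[str(i) for i in features.index],
        values=_corr_dissimilarity_values(x),
    )


@dataclass
class ClusterTree:
    """Agglomerative merge tree over labelled leaves.

    ``linkage_matrix`` is in scipy ``(L-1) x 4`` form: child ids, merge
    height, cluster size.  Leaf order in ``labels`` matches the dissimilarity
    input; exactly ``L - 1`` merges for ``L`` leaves.
    """

    labels: list[str]
    linkage_matrix: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if self.linkage_matrix.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage matrix shape inconsistent with leaf count")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cluster_index_sets(self) -> list[frozenset[int]]:
        """Leaf-index set of each internal node, in merge order (root last)."""
        return _merge_leafsets(self.linkage_matrix, self.n_leaves)

    def cluster_leafsets(self) -> list[frozenset[str]]:
        """Leaf-label set of each internal node, in merge order (root last)."""
        return [
            frozenset(self.labels[i] for i in s) for s in self.cluster_index_sets()
        ]

    def cut(self, k: int) -> pd.Series:
        """Flat partition into (at most) k clusters; labels -> cluster id."""
        if not 2 <= k <= self.n_leaves:
            raise ValueError(f"k must be in [2, {self.n_leaves}], got {k}")
        assign = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(assign, index=self.labels, name="cluster")

    def cophenetic_matrix(self) -> pd.DataFrame:
        dvec = hierarchy.cophenet(self.linkage_matrix)
        return pd.DataFrame(squareform(dvec), index=self.labels, columns=self.labels)


def _merge_leafsets(z: np.ndarray, n: int) -> list[frozenset[int]]:
    sets: list[frozenset[int]] = []
    by_id: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    for m, (a, b, _h, _c) in enumerate(z):
        s = by_id[int(a)] | by_id[int(b)]
        by_id[n + m] = s
        sets.append(s)
    return sets


def _validated_square(d: DissimilarityMatrix | pd.DataFrame) -> tuple[list[str], np.ndarray]:
    if isinstance(d, DissimilarityMatrix):
        labels, values = d.labels, d.values
    else:
        labels, values = [str(i) for i in d.index], d.to_numpy(dtype=float)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("dissimilarity matrix must be symmetric")
    return labels, 0.5 * (values + values.T)


def hierarchical_cluster(
    d: DissimilarityMatrix | pd.DataFrame, linkage: str = "average"
) -> ClusterTree:
    """Agglomerative clustering of a precomputed dissimilarity matrix.

    Deterministic for fixed input (scipy's nearest-neighbor-chain merge
    order, which breaks exact ties reproducibly).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {sorted(LINKAGES)}")
    labels, values = _validated_square(d)
    z = hierarchy.linkage(squareform(values, checks=False), method=linkage)
    return ClusterTree(labels=labels, linkage_matrix=z, method=linkage)


@dataclass
class ClusterSupport:
    """Bootstrap support for every internal cluster of an observed tree.

    ``table`` rows follow merge order (root last) with columns
    ``au, bp, v, c, se_v, se_c, bp_raw, degenerate``; ``bp_raw`` is the
    unsmoothed bootstrap probability at the scale closest to 1.
    ``counts[r]`` holds (hits per cluster, replicates) at scale ``r``.
    """

    clusters: list[frozenset[str]]
    table: pd.DataFrame
    counts: dict[float, tuple[np.ndarray, int]]
    scales: tuple[float, ...]
    n_boot_per_scale: int
    seed: int

    @property
    def au(self) -> np.ndarray:
        return self.table["au"].to_numpy()

    @property
    def bp(self) -> np.ndarray:
        return self.table["bp"].to_numpy()


def fit_au(
    scales: Sequence[float], bp_by_scale: Sequence[float], n_boot: int
) -> dict[str, float]:
    """Weighted probit fit of multiscale bootstrap probabilities.

    Fits ``Phi^{-1}(1 - BP_r) = v * sqrt(r) + c / sqrt(r)`` (signed distance
    ``v`` on the shrinking-variance axis, curvature ``c`` on its inverse) by
    least squares weighted with the delta-method variance of the
    probit-transformed binomial BP.  BP values are clipped to
    ``[1/(2B), 1 - 1/(2B)]`` before transformation, so boundary scales get
    near-zero weight.  Returns au, bp (smoothed), v, c, se_v, se_c,
    degenerate flag.
    """
    scales = np.asarray(scales, dtype=float)
    bp = np.asarray(bp_by_scale, dtype=float)
    if scales.shape != bp.shape:
        raise ValueError("scales and bp_by_scale must align")
    nan = float("nan")

    if len(scales) == 1:
        # classical bootstrap: no scale information, AU degenerates to BP
        return {
            "au": float(bp[0]), "bp": float(bp[0]), "v": nan, "c": nan,
            "se_v": nan, "se_c": nan, "degenerate": True,
        }

    boundary = (bp <= 0.0) | (bp >= 1.0)
    if boundary.all():
        # no information for the fit; report the boundary value at the scale
        # nearest 1 (all-0 -> 0, all-1 -> 1, mixed -> nearest-scale value)
        ref = float(bp[np.argmin(np.abs(scales - 1.0))])
        return {
            "au": ref, "bp": ref, "v": nan, "c": nan,
            "se_v": nan, "se_c": nan, "degenerate": True,
        }

    eps = 1.0 / (2.0 * n_boot)
    bp_c = np.clip(bp, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bp_c)
    sqrt_r = np.sqrt(scales)
    design = np.column_stack([sqrt_r, 1.0 / sqrt_r])
    # Var[z] ~= BP(1-BP) / (B * phi(z)^2) by the delta method
    var_z = bp_c * (1.0 - bp_c) / (n_boot * norm.pdf(z) ** 2)
    w = 1.0 / var_z
    xtwx = design.T @ (design * w[:, None])
    xtwz = design.T @ (w * z)
    try:
        cov = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        ref = float(bp_c[np.argmin(np.abs(scales - 1.0))])
        return {
            "au": ref, "bp": ref, "v": nan, "c": nan,
            "se_v": nan, "se_c": nan, "degenerate": True,
        }
    v, c = cov @ xtwz
    se_v, se_c = np.sqrt(np.diag(cov))
    return {
        "au": float(1.0 - norm.cdf(v - c)),
        "bp": float(1.0 - norm.cdf(v + c)),
        "v": float(v), "c": float(c),
        "se_v": float(se_v), "se_c": float(se_c),
        "degenerate": False,
    }


def multiscale_bootstrap(
    features: pd.DataFrame,
    linkage: str = "average",
    scales: Sequence[float] = DEFAULT_SCALES,
    n_boot_per_scale: int = 1000,
    seed: int = 0,
) -> tuple[ClusterTree, ClusterSupport]:
    """Observed tree plus AU/BP support from multiscale column resampling.

    For each scale ``r``, ``n_boot_per_scale`` replicates resample
    ``round(r * n_features)`` feature columns with replacement, recluster,
    and count for every observed internal cluster whether its exact leaf set
    reappears.  Per-scale, per-replicate RNG streams are spawned
    deterministically from ``seed``, so results do not depend on execution
    order.  The root cluster always reappears and so carries support 1.
    """
    scales = tuple(float(s) for s in scales)
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    if n_boot_per_scale < 1:
        raise ValueError("n_boot_per_scale must be >= 1")
    n_items, n_feat = features.shape
    sizes = {r: int(round(r * n_feat)) for r in scales}
    too_small = {r: m for r, m in sizes.items() if m < 3}
    if too_small:
        raise ValueError(
            f"scales {sorted(too_small)} resample fewer than 3 of the "
            f"{n_feat} features; use larger scales or more features"
        )

    diss = correlation_dissimilarity(features)
    tree = hierarchical_cluster(diss, linkage=linkage)
    observed = tree.cluster_index_sets()
    x = features.to_numpy(dtype=float)

    root_ss = np.random.SeedSequence(seed)
    counts: dict[float, tuple[np.ndarray, int]] = {}
    for scale, scale_ss in zip(scales, root_ss.spawn(len(scales))):
        m = sizes[scale]
        hits = np.zeros(len(observed), dtype=np.int64)
        for rep_ss in scale_ss.spawn(n_boot_per_scale):
            rng = np.random.default_rng(rep_ss)
            cols = rng.integers(0, n_feat, size=m)
            d = _corr_dissimilarity_values(x[:, cols])
            z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
            rep_sets = set(_merge_leafsets(z, n_items))
            for ci, s in enumerate(observed):
                if s in rep_sets:
                    hits[ci] += 1
        counts[scale] = (hits, n_boot_per_scale)

    rows = []
    for ci in range(len(observed)):
        bp_by_scale = [counts[r][0][ci] / counts[r][1] for r in scales]
        fit = fit_au(scales, bp_by_scale, n_boot_per_scale)
        fit["bp_raw"] = float(
            bp_by_scale[int(np.argmin(np.abs(np.asarray(scales) - 1.0)))]
        )
        rows.append(fit)
    table = pd.DataFrame(
        rows, columns=["au", "bp", "v", "c", "se_v", "se_c", "degenerate", "bp_raw"]
    )
    support = ClusterSupport(
        clusters=tree.cluster_leafsets(),
        table=table,
        counts=counts,
        scales=scales,
        n_boot_per_scale=n_boot_per_scale,
        seed=seed,
    )
    return tree, support


@dataclass(frozen=True)
class TreeComparison:
    """Agreement between two trees over the same leaves at a flat k-cut."""

    k: int
    adjusted_rand: float
    fowlkes_mallows: float
    cophenetic_correlation: float


def compare_trees(a: ClusterTree, b: ClusterTree, k: int) -> TreeComparison:
    """Partition agreement (ARI, Fowlkes-Mallows) at a k-cut plus cophenetic
    correlation of the two trees' distance structures."""
    if set(a.labels) != set(b.labels):
        raise ValueError(
            "trees have different leaf sets; symmetric difference: "
            f"{sorted(set(a.labels) ^ set(b.labels))}"
        )
    cut_a = a.cut(k)
    cut_b = b.cut(k).reindex(cut_a.index)
    ari = adjusted_rand_score(cut_a.to_numpy(), cut_b.to_numpy())
    fm = fowlkes_mallows_score(cut_a.to_numpy(), cut_b.to_numpy())
    coph_a = a.cophenetic_matrix()
    coph_b = b.cophenetic_matrix().reindex(index=coph_a.index, columns=coph_a.columns)
    va = squareform(coph_a.to_numpy(), checks=False)
    vb = squareform(coph_b.to_numpy(), checks=False)
    if np.std(va) == 0 or np.std(vb) == 0:
        coph = 1.0 if np.allclose(va, vb) else float("nan")
    else:
        coph = float(pearsonr(va, vb).statistic)
    return TreeComparison(
        k=k, adjusted_rand=float(ari), fowlkes_mallows=float(fm),
        cophenetic_correlation=coph,
    )


def to_newick(t: ClusterTree, support: ClusterSupport | None = None) -> str:
    """Serialise a tree as Newick with ultrametric branch lengths.

    Each internal node sits at half its merge height (so two leaves merged at
    0.4 give ``(A:0.2,B:0.2);``); AU values become internal node labels when
    support is given.  Non-monotone child heights (possible for non-monotone
    linkages) are clamped to non-negative branch lengths.
    """
    z = t.linkage_matrix
    n = t.n_leaves
    au = support.table["au"].to_numpy() if support is not None else None

    def height(node: int) -> float:
        return 0.0 if node < n else z[node - n, 2] / 2.0

    def render(node: int, parent_h: float) -> str:
        bl = max(parent_h - height(node), 0.0)
        if node < n:
            return f"{_quote(t.labels[node])}:{bl:.10g}"
        i = node - n
        left, right = int(z[i, 0]), int(z[i, 1])
        h = height(node)
        inner = f"({render(left, h)},{render(right, h)})"
        label = f"{au[i]:.4g}" if au is not None else ""
        return f"{inner}{label}:{bl:.10g}"

    root = n + len(z) - 1
    i = root - n
    h = height(root)
    left, right = int(z[i, 0]), int(z[i, 1])
    label = f"{au[i]:.4g}" if au is not None else ""
    return f"({render(left, h)},{render(right, h)}){label};"


def _quote(label: str) -> str:
    if any(ch in label for ch in " \t()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def support_table(tree: ClusterTree, support: ClusterSupport) -> pd.DataFrame:
    """Per-cluster support as a flat table (members joined by ';')."""
    df = support.table.copy()
    df.insert(0, "cluster", [f"c{i + 1}" for i in range(len(df))])
    df.insert(1, "members", [";".join(sorted(s)) for s in support.clusters])
    df.insert(2, "size", [len(s) for s in support.clusters])
    return df


def plot_dendrogram(
    tree: ClusterTree,
    support: ClusterSupport | None,
    path: str | Path,
    title: str = "",
) -> None:
    """Dendrogram with AU percentages annotated at internal nodes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6.0, 0.6 * tree.n_leaves), 4.5))
    dd = hierarchy.dendrogram(
        tree.linkage_matrix, labels=tree.labels, ax=ax, color_threshold=0.0,
        above_threshold_color="0.3",
    )
    if support is not None:
        # map each internal node's merge to its x midpoint in the plot
        coords: dict[float, tuple[float, float]] = {}
        for xs, ys in zip(dd["icoord"], dd["dcoord"]):
            coords[round(ys[1], 9)] = ((xs[1] + xs[2]) / 2.0, ys[1])
        for i, h in enumerate(tree.linkage_matrix[:, 2]):
            key = round(h, 9)
            if key in coords:
                x, y = coords[key]
                ax.annotate(
                    f"{100 * support.table['au'].iloc[i]:.0f}",
                    (x, y), textcoords="offset points", xytext=(0, 2),
                    ha="center", fontsize=7, color="firebrick",
                )
    ax.set_ylabel("1 - correlation (merge height)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
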