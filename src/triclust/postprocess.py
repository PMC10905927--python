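"""Diagnostics for a fitted partition.

Separation in the transformed space is measured by the density-based
silhouette information (dbsi): the log-ratio of each observation's top two
posterior probabilities, normalised by the largest absolute log-ratio in
the dataset, so values lie in [-1, 1].  Compactness in the original
(profile) space is measured by the Euclidean distance of each profile to
its component's mean mapped back through the inverse ALR transform, scaled
by the maximum such distance so values lie in [0, 1].  The cluster map
plots dbsi against this distance, faceted by cluster with convex hulls;
an ideal cluster sits in the top-left corner (separated and compact).
External comparisons use the adjusted Rand index and contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compositional import alr_inverse
from .matnorm_mixture import MatrixMixtureModel, map_assign

__all__ = [
    "DbsiResult",
    "ClusterMapPoint",
    "dbsi",
    "silhouette",
    "center_distance",
    "dbsi_plot_data",
    "cluster_map_data",
    "adjusted_rand_index",
    "contingency",
    "render_dbsi_plot",
    "render_cluster_map",
    "render_cluster_profiles",
    "diagnostics_table",
]

# posterior clamp per the workflow's numerical-stability convention
WINSOR_LOW = 1e-5
WINSOR_HIGH = 1.0 - 1e-5


@dataclass
class DbsiResult:
    """Per-observation dbsi values with MAP labels and the winsor bounds."""

    values: np.ndarray
    labels: np.ndarray
    winsor_bounds: tuple[float, float] = (WINSOR_LOW, WINSOR_HIGH)


@dataclass
class ClusterMapPoint:
    dbsi: float
    distance: float
    cluster: int


def dbsi(posteriors: np.ndarray,
         winsor_bounds: tuple[float, float] = (WINSOR_LOW, WINSOR_HIGH)) -> DbsiResult:
    """Density-based silhouette information from a posterior matrix.

    dbsi(y_i) = log(tau_k0 / tau_k1) / max_iota |log(tau_k0 / tau_k1)|,
    where k0, k1 index the largest and second-largest posterior of y_i and
    posteriors are winsorized into ``winsor_bounds`` before the ratio.
    """
    tau = np.asarray(posteriors, dtype=float)
    if tau.ndim != 2 or tau.shape[1] < 2:
        raise ValueError("dbsi needs a posterior matrix with at least 2 components")
    if not np.allclose(tau.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1")
    labels = map_assign(tau)
    clamped = np.clip(tau, winsor_bounds[0], winsor_bounds[1])
    order = np.sort(clamped, axis=1)
    top, second = order[:, -1], order[:, -2]
    log_ratio = np.log(top) - np.log(second)
    denom = np.max(np.abs(log_ratio))
    values = log_ratio / denom if denom > 0 else np.zeros_like(log_ratio)
    return DbsiResult(values=values, labels=labels,
                      winsor_bounds=tuple(winsor_bounds))


def silhouette(data: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Classic Euclidean silhouette widths s = (b - a) / max(a, b).

    Singleton clusters receive the value 0 (convention).
    """
    from sklearn.metrics import silhouette_samples

    data = np.asarray(data, dtype=float)
    labels = np.asarray(labels)
    if data.ndim != 2:
        data = data.reshape(data.shape[0], -1)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    return silhouette_samples(data, labels, metric="euclidean")


def center_distance(profiles, model: MatrixMixtureModel, labels: np.ndarray,
                    ref_position: int = 0) -> np.ndarray:
    """Scaled Euclidean distance of each profile to its cluster centre.

    The centre of component k is its mean matrix M_k mapped row-wise
    (experiment-wise) through the inverse ALR transform back to profile
    space; the distance sums over all T original time points and all J
    experiments, then is divided by the maximum distance over observations
    so that values lie in [0, 1] with the global maximiser at exactly 1.
    """
    p = np.asarray(profiles.profiles if hasattr(profiles, "profiles") else profiles,
                   dtype=float)  # (n, T, J)
    labels = np.asarray(labels)
    n, t, j = p.shape
    jm, tm = model.shape
    if (jm, tm + 1) != (j, t):
        raise ValueError(
            f"model dimensions (J={jm}, Tc={tm}) do not match profiles (J={j}, T={t})")
    centres = np.stack(
        [np.transpose(alr_inverse(c.M, ref=ref_position), (1, 0))
         for c in model.components])  # (K, T, J)
    diffs = p - centres[labels]
    dist = np.sqrt(np.sum(diffs ** 2, axis=(1, 2)))
    m = dist.max()
    return dist / m if m > 0 else dist


def dbsi_plot_data(result: DbsiResult,
                   order_values: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cluster descending-sorted dbsi series plus averages.

    Returns a tidy frame (cluster, display_order, rank, dbsi, cluster_avg,
    overall_avg).  Clusters are ordered by decreasing average width of
    ``order_values`` (e.g. classic silhouette widths); by default the dbsi
    values themselves are used as the ordering statistic.
    """
    values, labels = result.values, result.labels
    overall = float(values.mean())
    rows = []
    ordering = values if order_values is None else np.asarray(order_values, dtype=float)
    if len(ordering) != len(values):
        raise ValueError("order_values must be index-aligned with the dbsi values")
    cluster_avgs = {c: float(values[labels == c].mean()) for c in np.unique(labels)}
    order_stats = {c: float(ordering[labels == c].mean()) for c in np.unique(labels)}
    ordered = sorted(order_stats, key=order_stats.get, reverse=True)
    for position, c in enumerate(ordered):
        vals = np.sort(values[labels == c])[::-1]
        for rank, v in enumerate(vals):
            rows.append({"cluster": c, "display_order": position, "rank": rank,
                         "dbsi": v, "cluster_avg": cluster_avgs[c],
                         "overall_avg": overall})
    return pd.DataFrame(rows)


def cluster_map_data(result: DbsiResult, distances: np.ndarray,
                     labels: np.ndarray | None = None):
    """Cluster-map points and per-cluster convex hulls.

    Returns (points, hulls): ``points`` is a list of ClusterMapPoint, one
    per observation; ``hulls`` maps cluster -> (m, 2) array of hull vertices
    in the (distance, dbsi) plane.  Clusters with fewer than 3 distinct
    points degenerate to a segment or single point.
    """
    from scipy.spatial import ConvexHull, QhullError

    labels = result.labels if labels is None else np.asarray(labels)
    distances = np.asarray(distances, dtype=float)
    if len(distances) != len(result.values):
        raise ValueError("distances and dbsi values must be index-aligned")
    points = [ClusterMapPoint(dbsi=float(v), distance=float(d), cluster=int(c))
              for v, d, c in zip(result.values, distances, labels)]
    hulls: dict[int, np.ndarray] = {}
    for c in np.unique(labels):
        xy = np.column_stack([distances[labels == c], result.values[labels == c]])
        unique_xy = np.unique(xy, axis=0)
        if len(unique_xy) < 3:
            hulls[int(c)] = unique_xy
            continue
        try:
            hull = ConvexHull(unique_xy)
            hulls[int(c)] = unique_xy[hull.vertices]
        except QhullError:  # collinear points
            order = np.lexsort(unique_xy.T)
            hulls[int(c)] = unique_xy[[order[0], order[-1]]]
    return points, hulls


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Permutation-model-adjusted Rand index between two partitions.

    1 for identical partitions up to relabelling; ~0 at chance level.  When
    both partitions consist of a single cluster the index is defined as 1
    (the partitions are identical; the adjustment formula is 0/0 there).
    """
    from sklearn.metrics import adjusted_rand_score

    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return float(adjusted_rand_score(a, b))


def contingency(labels_a, labels_b) -> pd.DataFrame:
    """Cross-tabulation of two label vectors; entries sum to n."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return pd.crosstab(pd.Series(a, name="partition_a"),
                       pd.Series(b, name="partition_b"))


def diagnostics_table(gene_ids, result: DbsiResult, distances: np.ndarray,
                      posteriors: np.ndarray) -> pd.DataFrame:
    """Tidy per-gene diagnostics (gene, cluster, posterior_max, dbsi, distance)."""
    return pd.DataFrame({
        "gene": list(gene_ids),
        "cluster": result.labels,
        "posterior_max": np.max(posteriors, axis=1),
        "dbsi": result.values,
        "distance": np.asarray(distances, dtype=float),
    })


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _import_pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def render_dbsi_plot(result: DbsiResult, path) -> None:
    """Bar-style dbsi information plot, clusters ordered by average width."""
    plt = _import_pyplot()
    df = dbsi_plot_data(result)
    fig, ax = plt.subplots(figsize=(8, 4))
    x = 0
    cmap = plt.get_cmap("tab10")
    for pos, (c, sub) in enumerate(
            df.sort_values(["display_order", "rank"]).groupby("display_order", sort=True)):
        vals = sub["dbsi"].to_numpy()
        ax.bar(np.arange(x, x + len(vals)), vals, width=1.0,
               color=cmap(pos % 10), label=f"cluster {sub['cluster'].iloc[0]}")
        x += len(vals) + 2
    ax.axhline(df["overall_avg"].iloc[0], color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("genes (grouped by cluster)")
    ax.set_ylabel("dbsi")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_cluster_map(result: DbsiResult, distances: np.ndarray, path) -> None:
    """Faceted scatter of dbsi versus scaled centre distance with hulls."""
    plt = _import_pyplot()
    points, hulls = cluster_map_data(result, distances)
    clusters = sorted(hulls)
    ncol = min(5, max(1, len(clusters)))
    nrow = int(np.ceil(len(clusters) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.2 * nrow),
                             squeeze=False, sharex=True, sharey=True)
    dist = np.asarray(distances, dtype=float)
    for idx, c in enumerate(clusters):
        ax = axes[idx // ncol][idx % ncol]
        mask = result.labels == c
        if not mask.any():
            ax.set_visible(False)
            continue
        ax.scatter(dist[mask], result.values[mask], s=6)
        hull = hulls[c]
        if len(hull) >= 3:
            closed = np.vstack([hull, hull[:1]])
            ax.plot(closed[:, 0], closed[:, 1], color="k", linewidth=0.8)
        elif len(hull) == 2:
            ax.plot(hull[:, 0], hull[:, 1], color="k", linewidth=0.8)
        ax.set_title(f"cluster {c}", fontsize=8)
        ax.set_xlim(-0.05, 1.05)
        ax.set_ylim(-1.05, 1.05)
    for idx in range(len(clusters), nrow * ncol):
        axes[idx // ncol][idx % ncol].set_visible(False)
    fig.supxlabel("scaled distance to cluster centre (original space)")
    fig.supylabel("dbsi (transformed space)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def render_cluster_profiles(tensor, labels: np.ndarray, path,
                            value_name: str = "value") -> None:
    """Per-cluster line panels with the experiments side by side on the x-axis.

    ``tensor`` may be a LogRatioTensor (J x Tc per gene) or a ProfileTensor
    (T x J per gene); each experiment's time series is drawn in its own
    segment of the shared x-axis.
    """
    import warnings

    plt = _import_pyplot()
    if hasattr(tensor, "profiles"):
        arr = np.transpose(np.asarray(tensor.profiles), (0, 2, 1))  # (n, J, T)
        times = list(tensor.time_labels)
    else:
        arr = np.asarray(tensor.data)
        times = list(tensor.time_labels)
    experiments = list(tensor.experiment_labels)
    labels = np.asarray(labels)
    clusters = sorted(np.unique(labels))
    fig, axes = plt.subplots(1, len(clusters), figsize=(3 * len(clusters), 2.6),
                             squeeze=False, sharey=True)
    n_t = arr.shape[2]
    for idx, c in enumerate(clusters):
        ax = axes[0][idx]
        mask = labels == c
        if not mask.any():
            warnings.warn(f"cluster {c} is empty; panel skipped", stacklevel=2)
            ax.set_visible(False)
            continue
        for jj in range(arr.shape[1]):
            xs = np.arange(jj * (n_t + 1), jj * (n_t + 1) + n_t)
            for row in arr[mask]:
                ax.plot(xs, row[jj], color="steelblue", alpha=0.25, linewidth=0.6)
        ticks = [jj * (n_t + 1) + (n_t - 1) / 2 for jj in range(arr.shape[1])]
        ax.set_xticks(ticks)
        ax.set_xticklabels(experiments, fontsize=7)
        ax.set_title(f"cluster {c} (n={mask.sum()})", fontsize=8)
    axes[0][0].set_ylabel(value_name)
    fig.suptitle(f"time within experiment: {', '.join(map(str, times))}", fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
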