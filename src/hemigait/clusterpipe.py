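"""Overall-gait-behavior analysis: scaling, k-means phenotyping, cluster
separation, permutation variable importance, PCA projection, cross-condition
composition, and clinical contrasts.

Participants are clustered on their seven z-scored gait metrics within each
speed condition (self-selected or fast) separately; the number of clusters is
chosen by the mean-silhouette method; cluster distance is quantified by the
within/between sum-of-squares decomposition; and the metrics driving the
assignment are ranked by random-forest out-of-bag permutation importance
(mean decrease in accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import silhouette_score

METRIC_COLUMNS = ("sla", "dlsta", "slsta", "knee_flex_deg", "tla_deg", "circumduction_m", "hip_hike_deg")


class ClusterError(ValueError):
    pass


@dataclass
class ClusterResult:
    condition: str
    participant_ids: list[str]
    labels: np.ndarray  # canonical ids, 0 = largest cluster
    centroids: np.ndarray  # (k, 7) in scaled space
    wss_per_cluster: np.ndarray
    total_wss: float
    bss: float
    silhouette_by_k: dict[int, float]
    chosen_k: int
    importance: pd.Series  # metric -> mean decrease in OOB accuracy
    pca_scores: np.ndarray  # (n, 2)
    pca_explained: np.ndarray
    scaling_mean: pd.Series
    scaling_sd: pd.Series
    scaled: pd.DataFrame = field(repr=False, default=None)

    def label_of(self) -> pd.Series:
        return pd.Series(self.labels, index=self.participant_ids, name="cluster")


# ---------------------------------------------------------------------------


def zscore_scale(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise (x - mean)/sd with sample sd (n-1 denominator).

    Rows must be complete: participants with any missing metric are excluded
    before clustering (per speed condition), not silently imputed here.
    """
    if len(table) < 2:
        raise ClusterError("need >= 2 participants to scale")
    if table.isna().any().any():
        raise ClusterError("missing cells: exclude incomplete participants first")
    mean = table.mean()
    sd = table.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ClusterError(f"zero-variance column(s): {bad}")
    return (table - mean) / sd, mean, sd


def kmeans_fit(
    scaled: np.ndarray | pd.DataFrame, k: int, seed: int, n_init: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's k-means with k-means++ starts, best of ``n_init`` restarts.

    Label ids are canonicalized by descending cluster size (ties broken by
    first occurrence), so results are invariant to k-means' arbitrary
    labelling.
    """
    X = np.asarray(scaled, dtype=float)
    if k >= len(X):
        raise ClusterError(f"k={k} must be < n={len(X)}")
    if len(np.unique(X, axis=0)) < k:
        raise ClusterError("fewer distinct points than clusters (empty-cluster collapse)")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, algorithm="lloyd", random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw]
    centroids = km.cluster_centers_[order]
    return labels, centroids


def select_k_silhouette(
    scaled: np.ndarray | pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    n_init: int = 25,
) -> tuple[int, dict[int, float]]:
    """Choose k maximizing mean silhouette width (ties toward smaller k)."""
    X = np.asarray(scaled, dtype=float)
    lo, hi = k_range
    if len(X) <= hi:
        hi = len(X) - 1
    profile: dict[int, float] = {}
    for k in range(lo, hi + 1):
        labels, _ = kmeans_fit(X, k, seed=seed, n_init=n_init)
        profile[k] = float(silhouette_score(X, labels, metric="euclidean"))
    chosen = max(profile, key=lambda k: (profile[k], -k))
    return chosen, profile


def cluster_ss(
    scaled: np.ndarray | pd.DataFrame, labels: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """(WSS per cluster, total WSS, BSS).

    WSS_c = sum of squared distances to the cluster centroid; BSS = size-
    weighted squared distances of centroids to the grand mean.  By the ANOVA
    decomposition WSS + BSS equals the total sum of squares about the grand
    mean.
    """
    X = np.asarray(scaled, dtype=float)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    grand = X.mean(axis=0)
    wss, bss = [], 0.0
    for c in ks:
        pts = X[labels == c]
        if len(pts) == 0:
            raise ClusterError(f"empty cluster {c}")
        cen = pts.mean(axis=0)
        wss.append(float(((pts - cen) ** 2).sum()))
        bss += len(pts) * float(((cen - grand) ** 2).sum())
    return np.asarray(wss), float(np.sum(wss)), bss


# ---------------------------------------------------------------------------
# variable importance


def _bootstrap_oob_mask(tree_seed: int, n: int) -> np.ndarray:
    """Out-of-bag mask for one tree, regenerating sklearn's bootstrap draw."""
    sampled = np.random.RandomState(tree_seed).randint(0, n, n)
    mask = np.ones(n, dtype=bool)
    mask[sampled] = False
    return mask


def rf_importance(
    scaled: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.Series:
    """Permutation variable importance: mean decrease in OOB accuracy.

    A random forest is trained to predict the cluster assignment from the
    seven metrics; per tree, the accuracy on its out-of-bag samples is
    compared with the accuracy after permuting one predictor's OOB values,
    and the drop is averaged over trees.  Higher values mean the metric is
    more important to the cluster structure.
    """
    X = np.asarray(scaled, dtype=float)
    names = (
        list(scaled.columns) if isinstance(scaled, pd.DataFrame)
        else [f"x{j}" for j in range(X.shape[1])]
    )
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ClusterError("need >= 2 clusters for importance")
    if counts.min() < 3:
        raise ClusterError("every cluster needs >= 3 members for importance")
    n = len(X)
    forest = RandomForestClassifier(
        n_estimators=n_trees, bootstrap=True, random_state=seed
    ).fit(X, labels)
    rng = np.random.default_rng(seed)
    drops = np.zeros((len(forest.estimators_), X.shape[1]))
    used = np.zeros(len(forest.estimators_), dtype=bool)
    for t, tree in enumerate(forest.estimators_):
        oob = _bootstrap_oob_mask(tree.random_state, n)
        if oob.sum() < 2:
            continue
        used[t] = True
        Xo, yo = X[oob], labels[oob]
        acc = np.mean(tree.predict(Xo) == yo)
        for j in range(X.shape[1]):
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[t, j] = acc - np.mean(tree.predict(Xp) == yo)
    if not used.any():
        raise ClusterError("no out-of-bag samples available")
    imp = pd.Series(drops[used].mean(axis=0), index=names, name="mean_decrease_accuracy")
    return imp.sort_values(ascending=False)


def pca_project(scaled: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First two principal-component scores of the scaled table (SVD PCA).

    Sign convention: the largest-magnitude loading of each component is made
    positive.  Visualization only — clustering never runs in PC space.
    """
    X = np.asarray(scaled, dtype=float)
    if len(X) <= 2:
        raise ClusterError("need > 2 participants for PCA")
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(scores.shape[1]):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
            pca.components_[j] = -load
    return scores[:, :2], pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# condition-level driver


def cluster_condition(
    metrics_wide: pd.DataFrame,
    condition: str,
    seed: int = 0,
    k_range: tuple[int, int] = (2, 8),
    n_init: int = 25,
    n_trees: int = 500,
) -> ClusterResult:
    """Full clustering analysis for one speed condition.

    ``metrics_wide`` is indexed by participant_id with the seven metric
    columns; rows with any missing metric are excluded (per-condition
    exclusion) before z-scaling.
    """
    table = metrics_wide[list(METRIC_COLUMNS)]
    complete = table.dropna()
    scaled, mean, sd = zscore_scale(complete)
    chosen_k, profile = select_k_silhouette(scaled, k_range=k_range, seed=seed, n_init=n_init)
    labels, centroids = kmeans_fit(scaled, chosen_k, seed=seed, n_init=n_init)
    wss, total_wss, bss = cluster_ss(scaled, labels)
    importance = rf_importance(scaled, labels, n_trees=n_trees, seed=seed)
    scores, explained = pca_project(scaled)
    return ClusterResult(
        condition=condition,
        participant_ids=list(complete.index),
        labels=labels,
        centroids=centroids,
        wss_per_cluster=wss,
        total_wss=total_wss,
        bss=bss,
        silhouette_by_k=profile,
        chosen_k=chosen_k,
        importance=importance,
        pca_scores=scores,
        pca_explained=explained,
        scaling_mean=mean,
        scaling_sd=sd,
        scaled=scaled,
    )


def compare_conditions(result_a: ClusterResult, result_b: ClusterResult) -> dict:
    """Cross-condition composition report.

    Cluster identities are matched across conditions by nearest centroids in
    scaled space (k-means labels are arbitrary); the report lists per-participant
    assignments, switchers, per-cluster WSS change and BSS change.
    """
    ids_a, ids_b = set(result_a.participant_ids), set(result_b.participant_ids)
    common = sorted(ids_a & ids_b)
    note = ""
    if ids_a != ids_b:
        note = f"participant sets differ; restricted to {len(common)} common participants"
    la = result_a.label_of().loc[common]
    lb = result_b.label_of().loc[common]

    # match b's clusters to a's by centroid nearest-neighbour assignment
    from scipy.optimize import linear_sum_assignment

    ka, kb = len(result_a.centroids), len(result_b.centroids)
    dist = np.linalg.norm(
        result_a.centroids[:, None, :] - result_b.centroids[None, :, :], axis=2
    )
    rows, cols = linear_sum_assignment(dist[: min(ka, kb), : min(ka, kb)])
    mapping = {int(b): int(a) for a, b in zip(rows, cols)}
    lb_mapped = lb.map(lambda c: mapping.get(int(c), int(c)))

    assignments = pd.DataFrame(
        {result_a.condition: la, result_b.condition: lb_mapped}, index=common
    )
    switchers = assignments[assignments.iloc[:, 0] != assignments.iloc[:, 1]]
    return {
        "assignments": assignments,
        "switchers": list(switchers.index),
        "n_switchers": len(switchers),
        "cluster_mapping": mapping,
        "wss_change": {
            int(a): float(result_b.wss_per_cluster[b] - result_a.wss_per_cluster[a])
            for a, b in zip(rows, cols)
        },
        "bss_change": result_b.bss - result_a.bss,
        "note": note,
    }


def clinical_contrast(
    labels: pd.Series,
    metas,
    variable: str = "le_fugl_meyer",
    stroke_only: bool = True,
    exact_n_threshold: int = 20,
) -> dict:
    """Mann-Whitney U contrast of a clinical variable between cluster members.

    Two-sided; exact null enumeration when the combined sample is small
    (n <= 20) and tie-free, normal approximation with tie correction
    otherwise.  ``variable`` is "le_fugl_meyer" or "speed" (self-selected =
    slowest listed speed).
    """
    by_id = {m.participant_id: m for m in metas}
    groups: dict[int, list[float]] = {}
    for pid, lab in labels.items():
        m = by_id.get(pid)
        if m is None or (stroke_only and m.group != "stroke"):
            continue
        if variable == "le_fugl_meyer":
            val = m.le_fugl_meyer
        elif variable == "speed":
            val = min(m.speeds)
        else:
            raise ClusterError(f"unknown clinical variable {variable!r}")
        if val is not None:
            groups.setdefault(int(lab), []).append(float(val))
    if len(groups) != 2 or any(len(v) == 0 for v in groups.values()):
        raise ClusterError("both cluster subgroups must be nonempty")
    (ka, va), (kb, vb) = sorted(groups.items())
    pooled = np.concatenate([va, vb])
    if np.ptp(pooled) == 0:
        raise ClusterError("all clinical values identical")
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_n_threshold and not ties) else "asymptotic"
    res = stats.mannwhitneyu(va, vb, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "method": method,
        "n": (len(va), len(vb)),
        "medians": (float(np.median(va)), float(np.median(vb))),
        "clusters": (ka, kb),
    }
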