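"""Echo-type library construction and echo-class training.

The semi-supervised training path: rectangular regions of interest (ROIs) are
drawn on RGB composite echograms around visually coherent layers; the ΔSv
triplets inside each ROI are refined by K-means, of which one cluster — the
echo-type — is retained to represent a single coherent acoustic structure.
The library of echo-type mean triplets is then clustered hierarchically into
K echo-classes (Ward linkage on the 3-D means), the cluster count is selected
by a majority vote of cluster-validity indices, and the labelling is
validated with an out-of-bag random-forest error rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .multifreq import AXIS_NAMES, DeltaSvGrid

__all__ = [
    "Roi",
    "EchoType",
    "EchoTypeLibrary",
    "ClusterSelectionReport",
    "RfValidationReport",
    "extract_roi_cells",
    "kmeans_refine",
    "build_library",
    "hierarchical_classify",
    "select_k",
    "rf_validate",
    "dominant_frequency",
    "read_roi_csv",
]

MAX_ROI_DEPTH_M = 250.0


@dataclass
class Roi:
    """Rectangular echogram region: ping index range [start, end) and depth
    range [top, bottom) in metres, restricted to the upper 250 m (the usable
    range of the 120 kHz channel)."""

    id: str
    ping_start: int
    ping_end: int
    depth_top: float
    depth_bottom: float
    triple: str = "38/70/120"
    retain: int | None = None  # K-means cluster to retain (None = largest)

    def __post_init__(self):
        if self.ping_end <= self.ping_start:
            raise ValueError(f"ROI {self.id}: empty ping range")
        if self.depth_bottom <= self.depth_top:
            raise ValueError(f"ROI {self.id}: empty depth range")
        if self.depth_bottom > MAX_ROI_DEPTH_M:
            raise ValueError(
                f"ROI {self.id}: extends below {MAX_ROI_DEPTH_M:g} m"
            )


@dataclass
class EchoType:
    """One coherent acoustic structure: the retained K-means cluster of one
    ROI, summarized by the mean ΔSv triplet of its member cells."""

    id: str
    member_coords: np.ndarray  # (m, 2) (ping index, bin index)
    mean_triplet: np.ndarray  # (3,) dB
    source_roi: str

    def __post_init__(self):
        self.member_coords = np.asarray(self.member_coords, dtype=int)
        self.mean_triplet = np.asarray(self.mean_triplet, dtype=float)
        if len(self.member_coords) < 1:
            raise ValueError("echo-type must have at least one member cell")
        if not np.all(np.isfinite(self.mean_triplet)):
            raise ValueError("echo-type mean triplet must be finite")


@dataclass
class EchoTypeLibrary:
    """The training library: all echo-types, optionally labelled 1..K."""

    echo_types: list[EchoType]
    labels: np.ndarray | None = None  # (n,) ints in 1..K, or None

    def __post_init__(self):
        if not self.echo_types:
            raise ValueError("library must contain at least one echo-type")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.echo_types):
                raise ValueError("labels length mismatch")
            k = self.labels.max()
            if sorted(set(self.labels)) != list(range(1, k + 1)):
                raise ValueError("labels must cover 1..K with no empty class")

    def __len__(self) -> int:
        return len(self.echo_types)

    @property
    def mean_triplets(self) -> np.ndarray:
        return np.array([et.mean_triplet for et in self.echo_types])

    def to_json(self, path) -> None:
        payload = {
            "axes": list(AXIS_NAMES),
            "echo_types": [
                {
                    "id": et.id,
                    "mean_triplet": [round(float(v), 6) for v in et.mean_triplet],
                    "n_members": int(len(et.member_coords)),
                    "source_roi": et.source_roi,
                    "label": None
                    if self.labels is None
                    else int(self.labels[i]),
                }
                for i, et in enumerate(self.echo_types)
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class ClusterSelectionReport:
    """Per-validity-index optimal cluster count and the majority-vote winner."""

    k_candidates: list[int]
    chosen_k_by_index: dict[str, int]
    winning_k: int

    def vote_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for k in self.chosen_k_by_index.values():
            counts[k] = counts.get(k, 0) + 1
        return counts


@dataclass
class RfValidationReport:
    """Out-of-bag random-forest validation of the echo-class labelling."""

    overall_correct_pct: float
    per_class_error_pct: dict[int, float]
    n_trees: int
    seed: int
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------

def extract_roi_cells(grid: DeltaSvGrid, roi: Roi) -> tuple[np.ndarray, np.ndarray]:
    """All non-MISSING ΔSv triplets inside the ROI rectangle.

    Returns ``(coords, triplets)`` where coords are (ping, bin) lattice
    indices.  Raises if the selection is empty (fully MISSING or out of
    range).
    """
    tops = grid.depth_edges[:-1]
    bin_sel = (tops >= roi.depth_top) & (tops < roi.depth_bottom)
    sub = grid.delta[roi.ping_start : roi.ping_end, bin_sel]
    ok = ~np.isnan(sub).any(axis=2)
    if not ok.any():
        raise ValueError(f"ROI {roi.id}: empty selection (no valid cells)")
    pings, bins = np.nonzero(ok)
    bin_idx = np.nonzero(bin_sel)[0]
    coords = np.column_stack([pings + roi.ping_start, bin_idx[bins]])
    return coords, sub[ok]


def kmeans_refine(
    coords: np.ndarray,
    triplets: np.ndarray,
    k_roi: int = 3,
    seed: int = 0,
    retain: int | None = None,
    echo_type_id: str = "et",
    source_roi: str = "",
) -> EchoType:
    """Refine one ROI into one echo-type by K-means on its ΔSv triplets.

    K-means (multiple restarts, fixed seed) partitions the ROI's cells into
    ``k_roi`` clusters; the retained cluster — by default the largest, or an
    explicit ``retain`` index (clusters numbered 0..k-1 by descending size) —
    becomes the echo-type, whose mean triplet is the mean of the retained
    members.
    """
    triplets = np.asarray(triplets, dtype=float)
    n = len(triplets)
    if k_roi < 1:
        raise ValueError("k_roi must be >= 1")
    if k_roi > n:
        raise ValueError(f"k_roi={k_roi} exceeds the {n} ROI cells")
    if k_roi == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k_roi, n_init=10, random_state=seed)
        labels = km.fit_predict(triplets)
    sizes = np.bincount(labels, minlength=k_roi)
    order = np.argsort(-sizes, kind="stable")  # descending size, stable ties
    pick = order[0 if retain is None else retain]
    mask = labels == pick
    return EchoType(
        id=echo_type_id,
        member_coords=np.asarray(coords)[mask],
        mean_triplet=triplets[mask].mean(axis=0),
        source_roi=source_roi,
    )


def build_library(echo_types: list[EchoType]) -> EchoTypeLibrary:
    """Assemble the (unlabelled) echo-type library."""
    return EchoTypeLibrary(echo_types=list(echo_types))


def _relabel_by_centroid(x: np.ndarray, raw_labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..K by ascending centroid ΔSv(18-38), so the
    class numbering is deterministic rather than an artifact of merge order."""
    uniq = np.unique(raw_labels)
    centroids = np.array([x[raw_labels == u].mean(axis=0) for u in uniq])
    order = np.argsort(centroids[:, 0], kind="stable")
    remap = {int(uniq[o]): i + 1 for i, o in enumerate(order)}
    return np.array([remap[int(l)] for l in raw_labels])


def hierarchical_classify(library: EchoTypeLibrary, k: int) -> EchoTypeLibrary:
    """Cluster the library's mean triplets into ``k`` echo-classes.

    Agglomerative clustering with Ward linkage on Euclidean distances,
    dendrogram cut at ``k``; classes are renumbered 1..k by ascending
    centroid ΔSv(18-38).
    """
    n = len(library)
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    x = library.mean_triplets
    if k == 1:
        labels = np.ones(n, dtype=int)
    elif k == n:
        labels = _relabel_by_centroid(x, np.arange(n))
    else:
        z = linkage(x, method="ward")
        labels = _relabel_by_centroid(x, fcluster(z, t=k, criterion="maxclust"))
    return EchoTypeLibrary(echo_types=library.echo_types, labels=labels)


# --- cluster-count selection ------------------------------------------------

def _dunn_index(x: np.ndarray, labels: np.ndarray) -> float:
    """Dunn index: min between-cluster distance / max within-cluster diameter."""
    d = squareform(pdist(x))
    uniq = np.unique(labels)
    min_between = np.inf
    max_diam = 0.0
    for i, a in enumerate(uniq):
        ia = labels == a
        da = d[np.ix_(ia, ia)]
        if da.size > 1:
            max_diam = max(max_diam, da.max())
        for b in uniq[i + 1 :]:
            ib = labels == b
            min_between = min(min_between, d[np.ix_(ia, ib)].min())
    if max_diam == 0.0:
        return np.inf
    return min_between / max_diam


def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    """Pooled within-cluster sum of squared distances to centroids (W_k)."""
    w = 0.0
    for u in np.unique(labels):
        sub = x[labels == u]
        w += ((sub - sub.mean(axis=0)) ** 2).sum()
    return w


def _ward_labels(x: np.ndarray, k: int) -> np.ndarray:
    z = linkage(x, method="ward")
    return fcluster(z, t=k, criterion="maxclust")


def _gap_statistic(
    x: np.ndarray, k_candidates: list[int], b: int = 20, seed: int = 0
) -> int:
    """Gap statistic (uniform reference over the bounding box); the chosen k
    is the smallest candidate with gap(k) >= gap(k+1) - s(k+1), falling back
    to the max-gap candidate."""
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    ks = sorted(set(k_candidates) | {max(k_candidates) + 1})
    logw = {k: np.log(_within_dispersion(x, _ward_labels(x, k))) for k in ks}
    ref_logw = {k: np.empty(b) for k in ks}
    for ib in range(b):
        ref = rng.uniform(lo, hi, size=x.shape)
        for k in ks:
            ref_logw[k][ib] = np.log(_within_dispersion(ref, _ward_labels(ref, k)))
    gap = {k: ref_logw[k].mean() - logw[k] for k in ks}
    sk = {k: ref_logw[k].std(ddof=1) * np.sqrt(1 + 1.0 / b) for k in ks}
    for k in sorted(k_candidates):
        if (k + 1) in gap and gap[k] >= gap[k + 1] - sk[k + 1]:
            return k
    return max(sorted(k_candidates), key=lambda k: gap[k])


def select_k(
    library: EchoTypeLibrary,
    k_candidates: list[int],
    seed: int = 0,
) -> ClusterSelectionReport:
    """Select the echo-class count by majority vote of validity indices.

    Five indices are implemented — silhouette, Calinski-Harabasz,
    Davies-Bouldin, Dunn, and the gap statistic — each evaluated on Ward
    clusterings at every candidate k.  The winner is the modal choice, ties
    broken toward the smaller k.
    """
    x = library.mean_triplets
    n = len(library)
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if len(k_candidates) < 2:
        raise ValueError("need at least 2 candidate cluster counts")
    if any(k < 2 or k > n - 1 for k in k_candidates):
        raise ValueError("candidates must lie in [2, n-1]")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate library: all echo-type means identical")

    labels_by_k = {k: _ward_labels(x, k) for k in k_candidates}
    chosen: dict[str, int] = {}
    chosen["silhouette"] = max(
        k_candidates, key=lambda k: (silhouette_score(x, labels_by_k[k]), -k)
    )
    chosen["calinski_harabasz"] = max(
        k_candidates, key=lambda k: (calinski_harabasz_score(x, labels_by_k[k]), -k)
    )
    chosen["davies_bouldin"] = min(
        k_candidates, key=lambda k: (davies_bouldin_score(x, labels_by_k[k]), k)
    )
    chosen["dunn"] = max(
        k_candidates, key=lambda k: (_dunn_index(x, labels_by_k[k]), -k)
    )
    chosen["gap"] = _gap_statistic(x, k_candidates, seed=seed)

    counts: dict[int, int] = {}
    for k in chosen.values():
        counts[k] = counts.get(k, 0) + 1
    winning = min(
        counts, key=lambda k: (-counts[k], k)
    )  # majority, ties to smaller k
    return ClusterSelectionReport(
        k_candidates=k_candidates, chosen_k_by_index=chosen, winning_k=winning
    )


def rf_validate(
    library: EchoTypeLibrary, n_trees: int = 500, seed: int = 0
) -> RfValidationReport:
    """Validate the labelling with a random forest's out-of-bag error.

    A forest (default 500 trees, 1 feature tried per split = round(sqrt(3)))
    is fit on the 3 ΔSv features; the overall out-of-bag correct-classification
    rate and per-class error rates are reported.
    """
    if library.labels is None:
        raise ValueError("library must be labelled before validation")
    y = library.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 echo-classes")
    warnings = [
        f"echo-class {int(c)} has a single member; its error rate is unreliable"
        for c, n in zip(classes, counts)
        if n == 1
    ]
    x = library.mean_triplets
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=1,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
    )
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # tiny classes may lack OOB coverage
        rf.fit(x, y)
        proba = rf.oob_decision_function_
    covered = ~np.isnan(proba).any(axis=1) & (proba.sum(axis=1) > 0)
    pred = np.full(len(y), -1)
    pred[covered] = rf.classes_[np.argmax(proba[covered], axis=1)]
    overall = 100.0 * np.mean(pred[covered] == y[covered])
    per_class = {}
    for c in classes:
        m = (y == c) & covered
        per_class[int(c)] = (
            100.0 * np.mean(pred[m] != c) if m.any() else float("nan")
        )
    return RfValidationReport(
        overall_correct_pct=float(overall),
        per_class_error_pct=per_class,
        n_trees=n_trees,
        seed=seed,
        warnings=warnings,
    )


def dominant_frequency(library: EchoTypeLibrary, eset) -> dict[int, float]:
    """Assign each echo-class the frequency with dominant mean backscatter.

    Per class, the member cells of all member echo-types are pooled and the
    mean Sv per frequency is computed in the linear domain (the frequency-
    response curve); the dominant frequency is the argmax, ties going to the
    lower frequency.
    """
    if library.labels is None:
        raise ValueError("library must be labelled")
    freqs = sorted(eset.sv)
    out: dict[int, float] = {}
    for c in np.unique(library.labels):
        coords = np.vstack(
            [
                et.member_coords
                for et, lab in zip(library.echo_types, library.labels)
                if lab == c
            ]
        )
        p, b = coords[:, 0], coords[:, 1]
        best_f, best_v = None, -np.inf
        for f in freqs:
            vals = eset.sv[f][p, b]
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                continue
            mean_db = 10.0 * np.log10(np.mean(10.0 ** (vals / 10.0)))
            if mean_db > best_v + 1e-12:  # strict improvement: ties -> lower f
                best_f, best_v = f, mean_db
        out[int(c)] = best_f
    return out


def read_roi_csv(path) -> list[Roi]:
    """Read ROI definitions: CSV with columns
    ``roi_id,ping_start,ping_end,depth_top,depth_bottom,triple,retain``
    (indices 0-based half-open, depths in metres, empty retain = largest)."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["roi_id", "ping_start", "ping_end", "depth_top", "depth_bottom"]
    for c in required:
        if c not in df.columns:
            raise ValueError(f"ROI file missing column {c!r}")
    rois = []
    for _, row in df.iterrows():
        retain = row.get("retain", "")
        rois.append(
            Roi(
                id=row["roi_id"],
                ping_start=int(row["ping_start"]),
                ping_end=int(row["ping_end"]),
                depth_top=float(row["depth_top"]),
                depth_bottom=float(row["depth_bottom"]),
                triple=row.get("triple", "38/70/120") or "38/70/120",
                retain=int(retain) if str(retain).strip() else None,
            )
        )
    return rois
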