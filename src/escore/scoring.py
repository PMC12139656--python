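"""Ellipsoid-score classification of echo-integration cells.

Each echo-class k is summarized by an axis-aligned ellipsoid in ΔSv space:
a centroid mu_k and per-axis standard deviations sigma_k fitted to the class's
echo-type mean triplets.  The score of cell i against class k is

    Escore(i, k) = sum_j ((dSv_ij - mu_kj) / sigma_kj)^2 ,   j = 1..3

a sum of squared z-scores, chi-square distributed with 3 degrees of freedom
when the cell is drawn from the class's Gaussian.  A cell is assigned to the
class with the minimum score unless that minimum is at or above the
ellipsoid threshold (default 25), in which case it is left unclassified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .echogrid import MISSING, Echogram, EchogramSet
from .multifreq import DeltaSvGrid
from .training import EchoTypeLibrary

__all__ = [
    "UNCLASSIFIED",
    "MISSING_LABEL",
    "EchoClassModel",
    "ClassifiedGrid",
    "fit_ellipsoids",
    "escore",
    "escore_matrix",
    "classify_cells",
    "classify_triplets",
    "sensitivity_sweep",
    "per_class_echograms",
]

#: Label for evaluable cells whose minimum Escore is >= the threshold.
UNCLASSIFIED = -1
#: Label for cells with a MISSING input triplet.
MISSING_LABEL = 0

DEFAULT_THRESHOLD = 25.0
SIGMA_FLOOR_DB = 0.1


@dataclass
class EchoClassModel:
    """Fitted per-class ellipsoids (centroid + per-axis SDs, dB).

    ``mu`` and ``sigma`` have shape (K, 3) on the (18-38, 70-38, 120-38)
    axes; class ids are 1..K.  ``dominant_khz`` optionally records each
    class's dominant-backscatter frequency.
    """

    mu: np.ndarray
    sigma: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    dominant_khz: dict[int, float] | None = None
    member_ids: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if self.mu.shape != self.sigma.shape or self.mu.shape[1] != 3:
            raise ValueError("mu and sigma must both be (K, 3)")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive (floored at fit time)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def n_classes(self) -> int:
        return self.mu.shape[0]

    @property
    def class_ids(self) -> np.ndarray:
        return np.arange(1, self.n_classes + 1)

    def to_json(self, path) -> None:
        payload = {
            "classes": [
                {
                    "id": int(cid),
                    "mu": [round(float(v), 6) for v in self.mu[i]],
                    "sigma": [round(float(v), 6) for v in self.sigma[i]],
                    "dominant_khz": None
                    if self.dominant_khz is None
                    else self.dominant_khz.get(int(cid)),
                    "members": self.member_ids.get(int(cid), []),
                }
                for i, cid in enumerate(self.class_ids)
            ],
            "threshold": self.threshold,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "EchoClassModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        classes = sorted(payload["classes"], key=lambda c: c["id"])
        dom = {
            c["id"]: c.get("dominant_khz")
            for c in classes
            if c.get("dominant_khz") is not None
        }
        return cls(
            mu=np.array([c["mu"] for c in classes]),
            sigma=np.array([c["sigma"] for c in classes]),
            threshold=float(payload.get("threshold", DEFAULT_THRESHOLD)),
            dominant_khz=dom or None,
            member_ids={c["id"]: c.get("members", []) for c in classes},
        )


@dataclass
class ClassifiedGrid:
    """Per-cell echo-class labels with the winning Escore.

    ``labels``: 1..K for classified cells, ``UNCLASSIFIED`` (-1) where the
    minimum Escore was at or above the threshold, ``MISSING_LABEL`` (0) where
    the input triplet was MISSING.  ``min_escore`` is NaN for MISSING cells.
    """

    ping_times: np.ndarray
    depth_edges: np.ndarray
    labels: np.ndarray
    min_escore: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.min_escore = np.asarray(self.min_escore, dtype=float)
        if self.labels.shape != self.min_escore.shape:
            raise ValueError("labels and min_escore shapes differ")

    def to_csv(self, path) -> None:
        """Serialize labels in the Sv CSV dialect (-1 = unclassified, empty
        field = MISSING)."""
        edges = np.asarray(self.depth_edges, dtype=float)
        cols = [
            f"d_{edges[i]:.1f}_{edges[i + 1]:.1f}" for i in range(len(edges) - 1)
        ]
        times = pd.DatetimeIndex(self.ping_times).strftime("%Y-%m-%dT%H:%M:%SZ")
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("ping_time," + ",".join(cols) + "\n")
            for i in range(self.labels.shape[0]):
                row = [times[i]] + [
                    "" if l == MISSING_LABEL else str(int(l))
                    for l in self.labels[i]
                ]
                fh.write(",".join(row) + "\n")


def fit_ellipsoids(
    library: EchoTypeLibrary,
    threshold: float = DEFAULT_THRESHOLD,
    sigma_floor_db: float = SIGMA_FLOOR_DB,
    dominant_khz: dict[int, float] | None = None,
) -> EchoClassModel:
    """Fit per-class ellipsoids from a labelled echo-type library.

    mu_kj is the mean and sigma_kj the sample SD (ddof=1) of the class's
    echo-type mean triplets on axis j; SDs are floored at
    ``sigma_floor_db`` so tiny or degenerate classes never collapse the
    ellipsoid.
    """
    if library.labels is None:
        raise ValueError("library must be labelled")
    x = library.mean_triplets
    ids = np.unique(library.labels)
    mu = np.zeros((len(ids), 3))
    sigma = np.zeros((len(ids), 3))
    members: dict[int, list[str]] = {}
    for i, c in enumerate(ids):
        sub = x[library.labels == c]
        if len(sub) == 0:
            raise ValueError(f"echo-class {c} is empty")
        mu[i] = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1) if len(sub) > 1 else np.zeros(3)
        sigma[i] = np.maximum(sd, sigma_floor_db)
        members[int(c)] = [
            et.id for et, lab in zip(library.echo_types, library.labels) if lab == c
        ]
    return EchoClassModel(
        mu=mu,
        sigma=sigma,
        threshold=threshold,
        dominant_khz=dominant_khz,
        member_ids=members,
    )


def escore(triplet, class_id: int, model: EchoClassModel) -> float:
    """Escore of one ΔSv triplet against one echo-class (1-based id)."""
    t = np.asarray(triplet, dtype=float)
    i = int(class_id) - 1
    z = (t - model.mu[i]) / model.sigma[i]
    return float(np.sum(z * z))


def escore_matrix(triplets: np.ndarray, model: EchoClassModel) -> np.ndarray:
    """(N, K) matrix of Escores for N triplets against all K classes."""
    t = np.atleast_2d(np.asarray(triplets, dtype=float))
    z = (t[:, None, :] - model.mu[None, :, :]) / model.sigma[None, :, :]
    return np.sum(z * z, axis=2)


def classify_triplets(
    triplets: np.ndarray, model: EchoClassModel
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and minimum Escores for an (N, 3) triplet array.

    Label = argmin_k Escore if the minimum is strictly below the threshold,
    else UNCLASSIFIED; ties at the minimum go to the lowest class index.
    Rows containing NaN are MISSING.
    """
    t = np.atleast_2d(np.asarray(triplets, dtype=float))
    labels = np.full(len(t), MISSING_LABEL, dtype=int)
    mins = np.full(len(t), np.nan)
    ok = ~np.isnan(t).any(axis=1)
    if ok.any():
        s = escore_matrix(t[ok], model)
        best = np.argmin(s, axis=1)  # first minimum -> lowest class index
        mn = s[np.arange(len(s)), best]
        lab = np.where(mn < model.threshold, best + 1, UNCLASSIFIED)
        labels[ok] = lab
        mins[ok] = mn
    return labels, mins


def classify_cells(grid: DeltaSvGrid, model: EchoClassModel) -> ClassifiedGrid:
    """Classify every cell of a ΔSv grid (MISSING propagates)."""
    flat = grid.delta.reshape(-1, 3)
    labels, mins = classify_triplets(flat, model)
    shape = grid.delta.shape[:2]
    return ClassifiedGrid(
        ping_times=grid.ping_times,
        depth_edges=grid.depth_edges,
        labels=labels.reshape(shape),
        min_escore=mins.reshape(shape),
    )


def sensitivity_sweep(
    grid: DeltaSvGrid,
    truth_labels: np.ndarray,
    model: EchoClassModel,
    thresholds=None,
    sa_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Threshold sensitivity table on a truth-labelled training grid.

    For each threshold, each evaluable cell (truth label > 0, triplet not
    MISSING) is *well classified* (assigned its truth class), *mis-classified*
    (assigned another class) or *not classified*.  Percentages are reported
    per class and overall, by cell count and — when ``sa_weights`` (per-cell
    linear-domain sA) is given — by backscatter share.  The default sweep is
    1..100 in steps of 1 and always contains the working threshold 25.
    """
    if thresholds is None:
        thresholds = np.arange(1, 101, dtype=float)
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    truth = np.asarray(truth_labels, dtype=int)
    if truth.shape != grid.delta.shape[:2]:
        raise ValueError("truth labels do not match the lattice")
    evaluable = (truth > 0) & ~grid.missing_mask
    if not evaluable.any():
        raise ValueError("empty truth set")
    flat = grid.delta[evaluable]
    tr = truth[evaluable]
    scores = escore_matrix(flat, model)
    best = np.argmin(scores, axis=1)
    mn = scores[np.arange(len(scores)), best]
    assigned = best + 1
    w = (
        np.ones(len(tr))
        if sa_weights is None
        else np.asarray(sa_weights, dtype=float)[evaluable]
    )

    rows = []
    for thr in thresholds:
        classified = mn < thr
        well = classified & (assigned == tr)
        mis = classified & (assigned != tr)
        for c in list(np.unique(tr)) + ["all"]:
            m = np.ones(len(tr), bool) if c == "all" else tr == c
            n = m.sum()
            wsum = w[m].sum()
            rows.append(
                {
                    "threshold": thr,
                    "echo_class": c,
                    "pct_well": 100.0 * well[m].sum() / n,
                    "pct_mis": 100.0 * mis[m].sum() / n,
                    "pct_not": 100.0 * (~classified[m]).sum() / n,
                    "pct_sa_well": 100.0 * w[m][well[m]].sum() / wsum,
                    "pct_sa_mis": 100.0 * w[m][mis[m]].sum() / wsum,
                    "pct_sa_not": 100.0 * w[m][~classified[m]].sum() / wsum,
                }
            )
    return pd.DataFrame(rows)


def per_class_echograms(
    classified: ClassifiedGrid,
    eset: EchogramSet,
    frequency_khz: float,
    depth_from: float = 15.0,
    depth_to: float = 250.0,
) -> dict[int, Echogram]:
    """Per-class masked echograms over the 15-250 m window.

    For each class (and for UNCLASSIFIED), an Echogram at the requested
    frequency with Sv retained only in that class's cells; everything else is
    MISSING.  Together with the unclassified echogram these partition the
    evaluable backscatter exactly in the linear domain.
    """
    sv = eset.sv[float(frequency_khz)]
    tops = eset.depth_edges[:-1]
    window = (tops >= depth_from) & (tops < depth_to)
    edges = np.append(eset.depth_edges[:-1][window], eset.depth_edges[1:][window][-1])
    out: dict[int, Echogram] = {}
    present = [int(c) for c in np.unique(classified.labels) if c != MISSING_LABEL]
    for c in present:
        masked = np.where(classified.labels == c, sv, MISSING)[:, window]
        out[c] = Echogram(
            frequency_khz=frequency_khz,
            ping_times=eset.ping_times,
            positions=eset.positions,
            depth_edges=edges,
            sv=masked,
        )
    return out
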