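"""Whole-brain coactivation-pattern (CAP) clustering.

A CAP is a k-means centroid over individual BOLD frames: the scan is
treated as a bag of N-voxel vectors, each frame is assigned to one of k
recurring whole-brain states, and the centroid (mean of member frames) is
the state's spatial map. The procedure here is the two-stage variant used
for whole-brain (non-seed) CAP analysis:

1. Per subject, *exemplar* frames are picked at interior local maxima of
   the frame-wise spatial variance (10-15 per subject), the frames where a
   coactivation event is most clearly expressed.
2. k-means with many random restarts is fit on the pooled exemplars; the
   winning centroids seed a single k-means pass over *all* frames.

Model selection scans k over a range and keeps the k with maximal mean
silhouette on the exemplar frames. CAPs are finally renumbered so that
CAP 1 has the highest occurrence among control subjects, the publication
convention, and each centroid is summarized by a z-scored map thresholded
at |z| > 1.5 across voxels.

Frames are z-scored across voxels before clustering (``frame_norm=
"zscore"``), which makes squared Euclidean distance a monotone function of
1 minus the spatial Pearson correlation between frames.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .types import (
    BoldRun,
    ExemplarSet,
    FrameMatrix,
    StateSequence,
    ValidationError,
)

__all__ = [
    "build_frame_matrix",
    "select_exemplars",
    "fit_kmeans",
    "fit_cap_model",
    "select_k",
    "zscore_map",
    "order_caps",
    "CapClustering",
    "assignments_to_sequences",
]


def build_frame_matrix(
    runs: list[BoldRun],
    mask: np.ndarray | None = None,
    *,
    frame_norm: str = "zscore",
) -> FrameMatrix:
    """Stack all subjects' frames into one (total_frames, n_voxels) matrix.

    Each row is one frame; with ``frame_norm="zscore"`` (default) every row
    is standardized across voxels (mean 0, sample sd 1). Rows remain
    traceable to (subject, 1-based frame) through ``frame_index``.
    """
    if not runs:
        raise ValidationError("need at least one run")
    if frame_norm not in ("zscore", "none"):
        raise ValidationError(f"bad frame_norm {frame_norm!r}")
    band = runs[0].band_tag
    blocks = []
    idx_sid: list[str] = []
    idx_frame: list[int] = []
    n_vox = None
    for run in runs:
        data = run.data
        if mask is not None:
            m = np.asarray(mask, dtype=bool).ravel()
            if m.size != run.n_voxels:
                raise ValidationError(
                    f"mask has {m.size} voxels but run {run.subject_id} has "
                    f"{run.n_voxels}"
                )
            data = data[m]
        if run.band_tag != band:
            raise ValidationError(
                f"mixed band tags: {band!r} vs {run.band_tag!r} "
                f"({run.subject_id})"
            )
        if n_vox is None:
            n_vox = data.shape[0]
        elif data.shape[0] != n_vox:
            raise ValidationError(
                f"run {run.subject_id} has {data.shape[0]} voxels, expected {n_vox}"
            )
        frames = data.T.copy()  # (T, N)
        if frame_norm == "zscore":
            sd = frames.std(axis=1, ddof=1)
            zero = np.flatnonzero(sd == 0)
            if zero.size:
                t_bad = int(zero[0]) + 1
                raise ValidationError(
                    f"zero-variance frame: subject {run.subject_id}, frame {t_bad}"
                )
            frames = (frames - frames.mean(axis=1, keepdims=True)) / sd[:, None]
        blocks.append(frames)
        idx_sid.extend([run.subject_id] * run.n_frames)
        idx_frame.extend(range(1, run.n_frames + 1))
    frame_index = pd.DataFrame({"subject_id": idx_sid, "frame": idx_frame})
    return FrameMatrix(frames=np.vstack(blocks), frame_index=frame_index, band_tag=band)


def select_exemplars(run: BoldRun, min_n: int = 10, max_n: int = 15) -> ExemplarSet:
    """Pick a subject's exemplar frames at variance local maxima.

    The spatial variance of each frame is computed across voxels; frames at
    interior local maxima (``v[t-1] < v[t] >= v[t+1]``, endpoints excluded
    and plateaus broken leftward) are exemplars. If more than ``max_n``
    qualify, the ``max_n`` with the largest variance are kept; if fewer
    than ``min_n``, the highest-variance non-selected frames are added and
    flagged as padding.
    """
    if run.n_frames < 3:
        raise ValidationError("exemplar selection needs at least 3 frames")
    if not (1 <= min_n <= max_n):
        raise ValidationError("need 1 <= min_n <= max_n")
    v = run.data.var(axis=0, ddof=1)
    t = np.arange(1, run.n_frames - 1)
    is_max = (v[t - 1] < v[t]) & (v[t] >= v[t + 1])
    maxima = t[is_max]  # 0-based interior indices
    if maxima.size > max_n:
        keep = maxima[np.argsort(v[maxima], kind="stable")[::-1][:max_n]]
        maxima = np.sort(keep)
    pad: np.ndarray = np.array([], dtype=int)
    if maxima.size < min_n:
        n_pad = min(min_n, run.n_frames) - maxima.size
        others = np.setdiff1d(np.arange(run.n_frames), maxima)
        pad = others[np.argsort(v[others], kind="stable")[::-1][:n_pad]]
    chosen = np.sort(np.concatenate([maxima, pad]))
    is_padding = np.isin(chosen, pad)
    return ExemplarSet(
        subject_id=run.subject_id,
        frame_numbers=chosen + 1,
        is_padding=is_padding,
        variance_series=v,
    )


#: Exact enumeration is used instead of Lloyd restarts whenever the
#: assignment space k**n is at most this size: restarted local search can
#: miss the global optimum even on a handful of points, and at this scale
#: exhaustive search is cheap and deterministic.
_EXACT_SEARCH_LIMIT = 20_000


def _exact_kmeans(x: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Globally optimal k-means on a tiny instance.

    Enumerates set partitions of the rows into at most k blocks via
    restricted growth strings and keeps the minimal within-cluster SSE.
    """
    n, d = x.shape
    best_sse = np.inf
    best_labels = np.zeros(n, dtype=int)
    labels = np.zeros(n, dtype=int)

    def recurse(i: int, n_blocks: int) -> None:
        nonlocal best_sse, best_labels
        if i == n:
            sse = 0.0
            for c in range(n_blocks):
                pts = x[labels[:n] == c]
                sse += ((pts - pts.mean(axis=0)) ** 2).sum()
                if sse >= best_sse:
                    return
            best_sse = sse
            best_labels = labels.copy()
            return
        for c in range(min(n_blocks + 1, k)):
            labels[i] = c
            recurse(i + 1, max(n_blocks, c + 1))

    recurse(0, 0)
    centroids = np.empty((k, d))
    for c in range(k):
        members = x[best_labels == c]
        # clusters beyond the optimal block count stay empty; park their
        # centroid on the overall mean so the array keeps shape (k, d)
        centroids[c] = members.mean(axis=0) if members.size else x.mean(axis=0)
    return centroids, best_labels, float(best_sse)


def fit_kmeans(
    x: np.ndarray,
    k: int,
    n_restarts: int = 500,
    seed: int | None = 0,
    init_centroids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means; returns (centroids, labels, inertia).

    Labels are 0-based internal cluster ids (public CAP numbers are
    assigned later by :func:`order_caps`). With ``init_centroids`` given, a
    single Lloyd run from that initialization is performed. Otherwise, tiny
    instances (``k**n`` assignments below a fixed bound) are solved exactly
    by partition enumeration, and larger ones by the best of ``n_restarts``
    k-means++-seeded Lloyd runs (minimal within-cluster sum of squares).
    Empty clusters are re-seeded from the points farthest from their
    centroid, the standard Lloyd repair.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValidationError("X must be 2-D (frames x voxels)")
    n = x.shape[0]
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if k > n:
        raise ValidationError(f"k={k} exceeds number of frames {n}")
    if init_centroids is not None:
        init = np.asarray(init_centroids, dtype=float)
        if init.shape != (k, x.shape[1]):
            raise ValidationError(
                f"init_centroids must be ({k}, {x.shape[1]}), got {init.shape}"
            )
        km = KMeans(
            n_clusters=k, init=init, n_init=1, max_iter=300, tol=1e-6,
            algorithm="lloyd", random_state=seed,
        )
    else:
        if k > 1 and n * math.log(k) <= math.log(_EXACT_SEARCH_LIMIT):
            return _exact_kmeans(x, k)
        km = KMeans(
            n_clusters=k, init="k-means++", n_init=n_restarts, max_iter=300,
            tol=1e-6, algorithm="lloyd", random_state=seed,
        )
    km.fit(x)
    labels = km.labels_.astype(int)
    # recompute centroids as exact member means so the centroid-mean
    # invariant holds to machine precision
    centroids = np.vstack(
        [
            x[labels == c].mean(axis=0) if np.any(labels == c) else km.cluster_centers_[c]
            for c in range(k)
        ]
    )
    inertia = float(((x - centroids[labels]) ** 2).sum())
    return centroids, labels, inertia


def zscore_map(centroid: np.ndarray, z_threshold: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Z-score a CAP map across voxels and threshold it.

    Returns ``(zmap, ternary)`` where ``ternary`` is +1 where
    ``z > z_threshold``, -1 where ``z < -z_threshold``, else 0. Sample
    standard deviation (ddof=1) is used.
    """
    c = np.asarray(centroid, dtype=float).ravel()
    if c.size < 2:
        raise ValidationError("centroid needs at least 2 voxels")
    sd = c.std(ddof=1)
    if sd == 0:
        raise ValidationError("centroid has zero variance across voxels")
    z = (c - c.mean()) / sd
    ternary = np.zeros_like(z)
    ternary[z > z_threshold] = 1.0
    ternary[z < -z_threshold] = -1.0
    return z, ternary


class CapClustering(BaseEstimator, ClusterMixin):
    """Two-stage exemplar-seeded k-means over BOLD frames.

    Parameters
    ----------
    k : int
        Number of CAPs.
    n_restarts : int
        Random restarts of the exemplar-stage k-means (the full-data stage
        is a single pass seeded by the exemplar centroids).
    random_state : int
        Seed for all clustering randomness.
    z_threshold : float
        |z| cutoff for the ternary CAP maps (default 1.5 SD).

    Attributes (after :meth:`fit`)
    ------------------------------
    centroids_ : (k, n_voxels) ndarray
        Mean of member frames per CAP, rows in published CAP order.
    zmaps_, thresholded_maps_ : (k, n_voxels) ndarrays
        Voxel-z-scored centroids and their +1/0/-1 thresholded versions.
    labels_ : ndarray
        Per-frame CAP number (1-based), aligned with the fitted frame
        matrix rows.
    assignments_ : DataFrame
        Columns ``subject_id``, ``frame``, ``cap``.
    cap_order_ : ndarray
        Permutation mapping published CAP number (position) to internal
        cluster id.
    stage1_inertia_, inertia_ : float
        Within-cluster sums of squares of the exemplar stage and the final
        full-data solution.
    """

    def __init__(
        self,
        k: int = 7,
        n_restarts: int = 500,
        random_state: int = 0,
        z_threshold: float = 1.5,
    ) -> None:
        self.k = k
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.z_threshold = z_threshold

    def fit(self, X, y=None, *, exemplar_rows=None, frame_index=None, band_tag="unfiltered"):
        """Fit the CAP model.

        ``X`` may be a :class:`FrameMatrix` or a plain (frames x voxels)
        array; in the latter case ``frame_index`` (DataFrame with
        subject_id / frame) is optional and ``exemplar_rows`` gives the
        global row indices of the exemplar frames. With ``exemplar_rows``
        omitted, all rows seed stage 1.
        """
        if isinstance(X, FrameMatrix):
            frames = X.frames
            frame_index = X.frame_index
            band_tag = X.band_tag
        else:
            frames = np.asarray(X, dtype=float)
            if frame_index is None:
                frame_index = pd.DataFrame(
                    {"subject_id": ["all"] * frames.shape[0],
                     "frame": np.arange(1, frames.shape[0] + 1)}
                )
        rows = (
            np.arange(frames.shape[0])
            if exemplar_rows is None
            else np.asarray(exemplar_rows, dtype=int)
        )
        if rows.size < self.k:
            raise ValidationError(
                f"k={self.k} exceeds exemplar count {rows.size}"
            )
        stage1_c, _, self.stage1_inertia_ = fit_kmeans(
            frames[rows], self.k, n_restarts=self.n_restarts, seed=self.random_state
        )
        centroids, labels0, self.inertia_ = fit_kmeans(
            frames, self.k, seed=self.random_state, init_centroids=stage1_c
        )
        self.band_tag_ = band_tag
        self.frame_index_ = frame_index.reset_index(drop=True)
        self._internal_centroids = centroids
        self._internal_labels = labels0
        self.cap_order_ = np.arange(self.k)  # identity until order_caps
        self._publish()
        self.silhouette_by_k_: dict[int, float] = {}
        return self

    def _publish(self) -> None:
        """Materialize published-order outputs from the internal solution."""
        order = self.cap_order_
        self.centroids_ = self._internal_centroids[order]
        zm, tm = zip(*(zscore_map(c, self.z_threshold) for c in self.centroids_))
        self.zmaps_ = np.vstack(zm)
        self.thresholded_maps_ = np.vstack(tm)
        # internal id -> published CAP number (1-based)
        to_published = np.empty(self.k, dtype=int)
        to_published[order] = np.arange(1, self.k + 1)
        self.labels_ = to_published[self._internal_labels]
        self.assignments_ = self.frame_index_.assign(cap=self.labels_)

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, y, **kwargs).labels_

    def predict(self, X) -> np.ndarray:
        """Assign new frames to the nearest published CAP (1-based)."""
        frames = X.frames if isinstance(X, FrameMatrix) else np.asarray(X, dtype=float)
        d2 = ((frames[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1) + 1


def fit_cap_model(
    fm: FrameMatrix,
    exemplars: list[ExemplarSet],
    k: int,
    n_restarts: int = 500,
    seed: int = 0,
    z_threshold: float = 1.5,
) -> CapClustering:
    """Fit the two-stage CAP model on a frame matrix. Thin wrapper around
    :class:`CapClustering` resolving exemplar (subject, frame) pairs to
    global rows."""
    rows = np.concatenate(
        [fm.rows_for(e.subject_id, e.frame_numbers) for e in exemplars]
    )
    est = CapClustering(
        k=k, n_restarts=n_restarts, random_state=seed, z_threshold=z_threshold
    )
    return est.fit(fm, exemplar_rows=rows)


def select_k(
    fm: FrameMatrix,
    exemplars: list[ExemplarSet],
    k_range: range | list[int] = range(2, 21),
    n_restarts: int = 100,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Silhouette scan over candidate k on the exemplar frames.

    For each k the exemplar frames are clustered (``n_restarts`` restarts)
    and the mean Euclidean silhouette over those frames recorded; the k
    with the maximal silhouette wins, ties going to the smaller k.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValidationError("empty k_range")
    rows = np.concatenate(
        [fm.rows_for(e.subject_id, e.frame_numbers) for e in exemplars]
    )
    x = fm.frames[rows]
    if ks[0] < 2 or ks[-1] > x.shape[0] - 1:
        raise ValidationError(
            f"k_range must lie within [2, {x.shape[0] - 1}] for {x.shape[0]} exemplars"
        )
    scores: dict[int, float] = {}
    for k in ks:
        _, labels, _ = fit_kmeans(x, k, n_restarts=n_restarts, seed=seed)
        if np.unique(labels).size < 2:  # degenerate; silhouette undefined
            scores[k] = -1.0
        else:
            scores[k] = float(silhouette_score(x, labels, metric="euclidean"))
    best = max(ks, key=lambda k: (scores[k], -k))
    return best, scores


def order_caps(model: CapClustering, nc_subject_ids) -> CapClustering:
    """Renumber CAPs in decreasing order of control-group occurrence.

    ``nc_subject_ids`` lists the control subjects; CAP 1 becomes the
    cluster with the largest fraction of control frames, ties broken by
    internal cluster id ascending. The model is updated in place (and
    returned) with all published outputs renumbered.
    """
    nc = set(nc_subject_ids)
    in_nc = model.frame_index_["subject_id"].isin(nc).to_numpy()
    if not in_nc.any():
        raise ValidationError("no control (NC) frames present in assignments")
    labels = model._internal_labels[in_nc]
    occ = np.bincount(labels, minlength=model.k) / labels.size
    # sort by occurrence descending, stable in internal id
    order = np.argsort(-occ, kind="stable")
    model.cap_order_ = order
    model.nc_occurrence_ = occ[order]
    model._publish()
    return model


def assignments_to_sequences(model: CapClustering, tr: float = 3.0) -> list[StateSequence]:
    """Split the fitted per-frame assignments into per-subject sequences."""
    seqs = []
    for sid, grp in model.assignments_.groupby("subject_id", sort=False):
        grp = grp.sort_values("frame")
        seqs.append(
            StateSequence(
                subject_id=str(sid),
                labels=grp["cap"].to_numpy(),
                tr=tr,
                band_tag=model.band_tag_,
            )
        )
    return seqs
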