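"""Dynamic functional network connectivity (dFNC).

Tapered sliding-window correlation of component timecourses, k-means
clustering of window connectivity vectors into recurring brain states,
cluster-number diagnostics (silhouette and gap statistic), and the
three per-subject temporal metrics: fractional windows, mean dwell
time, and number of transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from .sfnc import ComponentTimecourses, fisher_z

__all__ = [
    "WindowSpec",
    "WindowedFnc",
    "StateModel",
    "build_taper",
    "window_count",
    "windowed_fnc",
    "pool_windows",
    "select_k",
    "cluster_states",
    "temporal_metrics",
    "subject_state_fnc",
    "window_truth_labels",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: length, Gaussian taper sigma, step (TRs)."""

    length: int = 22
    sigma: float = 3.0
    step: int = 1

    def __post_init__(self) -> None:
        if self.length < 3:
            raise ValueError("window length must be >= 3 TRs")
        if self.sigma <= 0:
            raise ValueError("taper sigma must be positive")
        if self.step < 1:
            raise ValueError("step must be >= 1 TR")


def window_count(n_timepoints: int, spec: WindowSpec) -> int:
    """Number of windows: floor((T - length)/step) + 1."""
    if n_timepoints < spec.length:
        raise ValueError(
            f"need at least {spec.length} timepoints, got {n_timepoints}"
        )
    return (n_timepoints - spec.length) // spec.step + 1


def build_taper(spec: WindowSpec) -> np.ndarray:
    """Tapered window weights: rectangle convolved with a Gaussian.

    A rectangle of ones (length L) is convolved with a unit-area
    discrete Gaussian (support +/- 4 sigma), the central L samples are
    kept, and the result is renormalised to sum to one. The weights are
    symmetric.
    """
    half = int(np.ceil(4 * spec.sigma))
    t = np.arange(-half, half + 1, dtype=float)
    gauss = np.exp(-0.5 * (t / spec.sigma) ** 2)
    gauss /= gauss.sum()
    full = np.convolve(np.ones(spec.length), gauss, mode="full")
    start = (full.size - spec.length) // 2
    w = full[start:start + spec.length]
    w = (w + w[::-1]) / 2.0  # enforce exact symmetry
    return w / w.sum()


@dataclass
class WindowedFnc:
    """Per-subject windows-by-edges Fisher-z connectivity.

    Edges follow the fixed (i<j) row-major ordering of
    :func:`dfnckit.sfnc.edge_index_pairs`.
    """

    subject_id: str
    values: np.ndarray  # (windows, edges)
    window_starts: np.ndarray
    spec: WindowSpec
    n_components: int
    scale: str = "z"

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]


def windowed_fnc(
    tc: ComponentTimecourses,
    spec: WindowSpec = WindowSpec(),
    fisher: bool = True,
    taper: np.ndarray | None = None,
) -> WindowedFnc:
    """Tapered sliding-window correlation per component pair.

    Each window computes a weighted Pearson correlation (weighted means,
    covariances and variances under the taper), optionally Fisher
    z-transformed. A window in which some component has zero weighted
    variance gets its affected edges set to 0 with a warning.
    """
    w = build_taper(spec) if taper is None else np.asarray(taper, float)
    n_win = window_count(tc.n_timepoints, spec)
    c = tc.n_components
    iu = np.triu_indices(c, k=1)
    starts = np.arange(n_win) * spec.step
    out = np.empty((n_win, iu[0].size))
    flagged = []
    for wi, s in enumerate(starts):
        x = tc.data[:, s:s + spec.length]
        mu = x @ w
        xc = x - mu[:, None]
        cov = (xc * w) @ xc.T
        var = np.diag(cov).copy()
        dead = var <= 1e-12 * (np.abs(x).max(axis=1) + 1.0) ** 2
        if dead.any():
            flagged.append(wi)
            var[dead] = 1.0
        denom = np.sqrt(np.outer(var, var))
        r = cov / denom
        if dead.any():
            r[dead, :] = 0.0
            r[:, dead] = 0.0
        r = np.clip(r, -1.0, 1.0)
        out[wi] = fisher_z(r[iu]) if fisher else r[iu]
    if flagged:
        warnings.warn(
            f"zero weighted variance in windows {flagged}; affected edges "
            "set to 0", UserWarning, stacklevel=2,
        )
    return WindowedFnc(
        subject_id=tc.subject_id, values=out, window_starts=starts,
        spec=spec, n_components=c, scale="z" if fisher else "r",
    )


def pool_windows(wfncs: list[WindowedFnc]) -> tuple[np.ndarray, np.ndarray]:
    """Stack all subjects' windows; returns (matrix, subject index per row)."""
    mats = [w.values for w in wfncs]
    idx = np.concatenate(
        [np.full(w.n_windows, i) for i, w in enumerate(wfncs)]
    )
    return np.vstack(mats), idx


# ---------------------------------------------------------------------------
# k-means under a configurable distance
# ---------------------------------------------------------------------------

def _centroid(points: np.ndarray, metric: str) -> np.ndarray:
    return (np.median(points, axis=0) if metric == "cityblock"
            else points.mean(axis=0))


def _kmeans_pp_init(
    x: np.ndarray, k: int, metric: str, rng: np.random.Generator
) -> np.ndarray:
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d = cdist(x, centers[:1], metric=metric).ravel()
    for j in range(1, k):
        prob = d / d.sum() if d.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = x[rng.choice(n, p=prob)]
        d = np.minimum(d, cdist(x, centers[j:j + 1], metric=metric).ravel())
    return centers


def _lloyd(
    x: np.ndarray,
    k: int,
    metric: str,
    rng: np.random.Generator,
    init: np.ndarray | None = None,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run; centroid update is the componentwise median for
    cityblock and the mean for euclidean. Returns (labels, centroids,
    within-cluster distance total)."""
    centers = (_kmeans_pp_init(x, k, metric, rng) if init is None
               else init.copy())
    labels = np.full(x.shape[0], -1)
    for _ in range(max_iter):
        d = cdist(x, centers, metric=metric)
        new_labels = d.argmin(axis=1)
        # re-seed empty clusters from the farthest point
        for j in range(k):
            if not np.any(new_labels == j):
                far = d[np.arange(len(new_labels)), new_labels].argmax()
                centers[j] = x[far]
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centers[j] = _centroid(x[labels == j], metric)
    d = cdist(x, centers, metric=metric)
    labels = d.argmin(axis=1)
    inertia = float(d[np.arange(len(labels)), labels].sum())
    return labels, centers, inertia


@dataclass
class StateModel:
    """Fitted brain-state model: centroids, assignments, diagnostics.

    States are ordered by descending pooled occurrence (ties broken by
    original cluster index), so state 0 is the most visited.
    """

    k: int
    centroids: np.ndarray  # (k, edges)
    assignments: dict[str, np.ndarray]
    occurrence: np.ndarray  # (k,), sums to 1
    metric: str
    seed: int
    inertia: float
    diagnostics: pd.DataFrame | None = None

    def pooled_labels(self, order: list[str] | None = None) -> np.ndarray:
        ids = order or list(self.assignments)
        return np.concatenate([self.assignments[s] for s in ids])


def _exemplar_rows(wfnc: WindowedFnc) -> np.ndarray:
    """Windows at local maxima of across-edge variance (exemplars)."""
    v = wfnc.values.var(axis=1)
    if v.size < 3:
        return np.arange(v.size)
    mid = (v[1:-1] >= v[:-2]) & (v[1:-1] >= v[2:])
    idx = np.flatnonzero(mid) + 1
    return idx if idx.size else np.array([int(v.argmax())])


def cluster_states(
    wfncs: list[WindowedFnc],
    k: int,
    distance: str = "cityblock",
    n_init: int = 20,
    seed: int = 0,
    exemplar_subsampling: bool = False,
) -> StateModel:
    """Cluster pooled windows into k recurring connectivity states.

    k-means under ``distance`` ("cityblock", the dFNC convention, or
    "euclidean"), best of ``n_init`` restarts by total within-cluster
    distance. With ``exemplar_subsampling`` the per-subject windows at
    local maxima of across-edge variance are clustered first and their
    centroids initialise the full clustering (a single polished run).
    """
    if distance not in ("cityblock", "euclidean"):
        raise ValueError("distance must be 'cityblock' or 'euclidean'")
    x, _ = pool_windows(wfncs)
    if k < 1 or k > x.shape[0]:
        raise ValueError(f"k must lie in [1, {x.shape[0]}]")
    rng = np.random.default_rng(seed)
    if exemplar_subsampling:
        ex = np.vstack([w.values[_exemplar_rows(w)] for w in wfncs])
        best = None
        for _ in range(n_init):
            res = _lloyd(ex, k, distance, rng)
            if best is None or res[2] < best[2]:
                best = res
        labels, centers, inertia = _lloyd(x, k, distance, rng,
                                          init=best[1])
    else:
        best = None
        for _ in range(n_init):
            res = _lloyd(x, k, distance, rng)
            if best is None or res[2] < best[2]:
                best = res
        labels, centers, inertia = best

    counts = np.bincount(labels, minlength=k)
    order = np.lexsort((np.arange(k), -counts))  # descending, index tie-break
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    centers = centers[order]
    occurrence = counts[order] / counts.sum()

    assignments: dict[str, np.ndarray] = {}
    pos = 0
    for w in wfncs:
        assignments[w.subject_id] = labels[pos:pos + w.n_windows]
        pos += w.n_windows
    return StateModel(
        k=k, centroids=centers, assignments=assignments,
        occurrence=occurrence, metric=distance, seed=seed, inertia=inertia,
    )


# ---------------------------------------------------------------------------
# cluster-number selection
# ---------------------------------------------------------------------------

def _within_dispersion(x, labels, centers, metric) -> float:
    d = cdist(x, centers, metric=metric)
    per = d[np.arange(len(labels)), labels]
    return float((per ** 2).sum()) if metric == "euclidean" else float(per.sum())


def select_k(
    x: np.ndarray,
    k_range: range | tuple[int, int] = (2, 8),
    seed: int = 0,
    n_gap_refs: int = 10,
    distance: str = "cityblock",
    n_init: int = 5,
    silhouette_subsample: int = 2000,
    criterion: str = "silhouette",
) -> tuple[int, pd.DataFrame]:
    """Choose the number of states, reporting silhouette and gap curves.

    For each k the pooled window matrix is clustered and (a) the mean
    silhouette under the clustering distance and (b) the gap statistic
    against ``n_gap_refs`` uniform references drawn in the PCA-aligned
    bounding box are computed. ``criterion="silhouette"`` (default)
    chooses the k maximising the mean silhouette; ``"gap"`` chooses the
    smallest k whose gap is within one reference standard error of the
    next k's gap (the classical rule — the only criterion defined when
    k=1 is in range, but unreliable on large pools, where the reference
    spread of log W collapses). Large pools are subsampled for the
    silhouette (O(n^2) pairwise distances).
    """
    x = np.asarray(x, dtype=float)
    if isinstance(k_range, tuple):
        ks = list(range(k_range[0], k_range[1] + 1))
    else:
        ks = list(k_range)
    if max(ks) > x.shape[0]:
        raise ValueError("k_range exceeds the number of windows")
    rng = np.random.default_rng(seed)

    # PCA-aligned bounding box for the reference distribution
    mu = x.mean(axis=0)
    xc = x - mu
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    proj = xc @ vt.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)

    rows = []
    gaps, sks = {}, {}
    for k in ks:
        labels, centers, _ = min(
            (_lloyd(x, k, distance, rng) for _ in range(n_init)),
            key=lambda r: r[2],
        )
        logw = np.log(_within_dispersion(x, labels, centers, distance))
        ref_logw = []
        for _ in range(n_gap_refs):
            ref = rng.uniform(lo, hi, size=proj.shape) @ vt + mu
            rl, rc, _ = _lloyd(ref, k, distance, rng)
            ref_logw.append(np.log(_within_dispersion(ref, rl, rc, distance)))
        ref_logw = np.asarray(ref_logw)
        gap = float(ref_logw.mean() - logw)
        sk = float(ref_logw.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_gap_refs))
        gaps[k], sks[k] = gap, sk
        if k >= 2 and x.shape[0] > 2:
            if x.shape[0] > silhouette_subsample:
                sub = rng.choice(x.shape[0], silhouette_subsample,
                                 replace=False)
                sil = silhouette_score(x[sub], labels[sub], metric=distance)
            else:
                sil = silhouette_score(x, labels, metric=distance)
        else:
            sil = np.nan
        rows.append({"k": k, "gap": gap, "gap_se": sk, "silhouette": sil})

    diag = pd.DataFrame(rows)
    if criterion == "gap":
        chosen = ks[-1]
        for k in ks[:-1]:
            if gaps[k] >= gaps[k + 1] - sks[k + 1]:
                chosen = k
                break
    elif criterion == "silhouette":
        if diag["silhouette"].notna().any():
            chosen = int(diag.loc[diag["silhouette"].idxmax(), "k"])
        else:
            chosen = ks[0]
    else:
        raise ValueError("criterion must be 'silhouette' or 'gap'")
    return chosen, diag


# ---------------------------------------------------------------------------
# temporal metrics
# ---------------------------------------------------------------------------

def _runs(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(state of each maximal run, its length)."""
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [seq.size - 1]])
    return seq[starts], ends - starts + 1


def temporal_metrics(
    assignments: dict[str, np.ndarray],
    k: int,
    spec: WindowSpec = WindowSpec(),
    tr: float = 2.0,
    absent_state: str = "zero",
) -> pd.DataFrame:
    """Fractional windows, mean dwell time and transitions per subject.

    Fractional windows: share of the subject's windows in each state.
    Mean dwell: mean length (in windows) of maximal consecutive runs of
    a state; for a state the subject never visits the value is 0 under
    the default ``absent_state="zero"`` convention (keeping group n
    constant) or NaN under ``"missing"``. Transitions: number of
    consecutive-window state changes. ``dwell_seconds_factor`` in the
    attrs converts dwell windows to seconds (step x TR).
    """
    if absent_state not in ("zero", "missing"):
        raise ValueError("absent_state must be 'zero' or 'missing'")
    fill = 0.0 if absent_state == "zero" else np.nan
    rows = {}
    for sid, seq in assignments.items():
        seq = np.asarray(seq)
        if seq.size == 0:
            raise ValueError(f"empty assignment sequence for {sid}")
        if seq.min() < 0 or seq.max() >= k:
            raise ValueError(f"assignments for {sid} outside 0..{k - 1}")
        states, lengths = _runs(seq)
        row: dict[str, float] = {}
        for s in range(k):
            row[f"frac_{s + 1}"] = float(np.mean(seq == s))
            in_state = lengths[states == s]
            row[f"dwell_{s + 1}"] = (float(in_state.mean()) if in_state.size
                                     else fill)
        row["transitions"] = int(np.count_nonzero(np.diff(seq)))
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject"
    out.attrs["dwell_seconds_factor"] = spec.step * tr
    return out


def subject_state_fnc(
    wfncs: list[WindowedFnc], model: StateModel
) -> np.ndarray:
    """Per-subject per-state mean edge vector, NaN where a state is absent.

    Returns an array (subjects, k, edges) in the order of ``wfncs``.
    """
    k = model.k
    n_edges = wfncs[0].values.shape[1]
    out = np.full((len(wfncs), k, n_edges), np.nan)
    for i, w in enumerate(wfncs):
        a = model.assignments[w.subject_id]
        for s in range(k):
            sel = a == s
            if sel.any():
                out[i, s] = w.values[sel].mean(axis=0)
    return out


def window_truth_labels(
    sequence: np.ndarray, spec: WindowSpec = WindowSpec()
) -> np.ndarray:
    """Majority true state within each window (ground-truth view).

    Maps a per-timepoint truth sequence onto windows so recovered window
    assignments can be scored against the generative truth; ties go to
    the lower state index.
    """
    sequence = np.asarray(sequence)
    n_win = window_count(sequence.size, spec)
    k = int(sequence.max()) + 1
    out = np.empty(n_win, dtype=np.int64)
    for wi in range(n_win):
        s = wi * spec.step
        counts = np.bincount(sequence[s:s + spec.length], minlength=k)
        out[wi] = int(counts.argmax())
    return out
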