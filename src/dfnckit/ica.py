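"""Group spatial ICA with stability selection and back-reconstruction.

The decomposition follows the standard group-ICA recipe for multi-
subject resting-state fMRI: temporal PCA per subject, a second
(group-level) PCA of the concatenated reduced data, Infomax ICA on the
whitened group data repeated from several random starts, agglomerative
clustering of the pooled run-components into stable aggregate
components (an ICASSO-style stability analysis), and back-
reconstruction of subject-specific timecourses and spatial maps, by
dual (spatiotemporal) regression or by the PCA de-whitening route.
Components are then labelled against template maps using spatial
correlation, the low-frequency power fraction of their timecourses, and
a peak-in-mask check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import periodogram
from scipy.spatial.distance import squareform

__all__ = [
    "PcaReduction",
    "GroupPca",
    "IcaDecomposition",
    "IcassoResult",
    "ConvergenceError",
    "subject_pca",
    "group_reduce",
    "whiten_check",
    "infomax",
    "icasso",
    "back_reconstruct",
    "label_components",
    "match_components",
    "run_group_ica",
]


class ConvergenceError(RuntimeError):
    """Infomax failed to converge after exhausting annealing steps."""


# ---------------------------------------------------------------------------
# PCA reductions
# ---------------------------------------------------------------------------

@dataclass
class PcaReduction:
    """Temporal PCA of one subject's voxels-by-timepoints data.

    ``basis`` (timepoints x dim) holds the orthonormal principal
    directions of the temporal covariance; ``scores = centered_data @
    basis`` are the reduced data and ``scores @ basis.T`` reconstructs
    the retained subspace.
    """

    dim: int
    basis: np.ndarray  # (t, dim)
    scores: np.ndarray  # (v, dim)
    eigenvalues: np.ndarray  # (dim,)
    explained: np.ndarray  # fractions, non-increasing
    total_variance: float

    @property
    def dewhiten(self) -> np.ndarray:
        return self.basis.T

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.basis.T


def subject_pca(data: np.ndarray, dim: int) -> PcaReduction:
    """Reduce the temporal dimension of voxels-by-timepoints data.

    Keeps the top-``dim`` eigenvectors of the timepoint-by-timepoint
    covariance (each voxel timeseries is mean-centred first). The
    reconstruction error equals the sum of the discarded eigenvalues.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be voxels x timepoints")
    v, t = x.shape
    if not 1 <= dim <= min(v, t):
        raise ValueError(f"dim must lie in [1, {min(v, t)}], got {dim}")
    xc = x - x.mean(axis=1, keepdims=True)
    cov = xc.T @ xc
    w, vec = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    vec = vec[:, order]
    total = float(w.sum())
    keep = vec[:, :dim]
    return PcaReduction(
        dim=dim,
        basis=keep,
        scores=xc @ keep,
        eigenvalues=w[:dim],
        explained=(w[:dim] / total if total > 0 else np.zeros(dim)),
        total_variance=total,
    )


@dataclass
class GroupPca:
    """Second-level PCA of horizontally concatenated subject scores.

    ``whitened`` (dim x voxels) satisfies whitened @ whitened.T /
    n_voxels = I and is the input to spatial ICA. ``basis`` rows are
    partitioned per subject (``subject_blocks``), which the de-whitening
    back-reconstruction route uses.
    """

    dim: int
    basis: np.ndarray  # (m, dim) over stacked subject dimensions
    eigenvalues: np.ndarray
    explained: np.ndarray
    whitened: np.ndarray  # (dim, voxels)
    subject_dims: tuple[int, ...]
    n_voxels: int

    def subject_blocks(self) -> list[np.ndarray]:
        out, start = [], 0
        for d in self.subject_dims:
            out.append(self.basis[start:start + d])
            start += d
        return out


def _orthogonal_iteration(
    c: np.ndarray, dim: int, rng: np.random.Generator,
    tol: float = 1e-12, max_iter: int = 5000,
) -> tuple[np.ndarray, np.ndarray]:
    """EM/power-style subspace iteration for the top-dim eigenpairs."""
    q = np.linalg.qr(rng.standard_normal((c.shape[0], dim)))[0]
    prev = q
    for _ in range(max_iter):
        q, _ = np.linalg.qr(c @ q)
        # subspace change via projection residual
        resid = q - prev @ (prev.T @ q)
        if np.linalg.norm(resid) < tol:
            break
        prev = q
    small = q.T @ c @ q
    w, u = np.linalg.eigh(small)
    order = np.argsort(w)[::-1]
    return np.clip(w[order], 0.0, None), q @ u[:, order]


def group_reduce(
    reductions: list[PcaReduction],
    dim: int,
    method: str = "em",
    seed: int = 0,
) -> GroupPca:
    """Group-level PCA of temporally concatenated subject reductions.

    ``method="em"`` uses iterative subspace (power) iteration,
    ``"eig"`` a direct eigendecomposition; both span the same subspace.
    """
    if not reductions:
        raise ValueError("no subject reductions given")
    v = reductions[0].scores.shape[0]
    if any(r.scores.shape[0] != v for r in reductions):
        raise ValueError("subjects must share the voxel grid")
    m_mat = np.hstack([r.scores for r in reductions])  # (v, m)
    m = m_mat.shape[1]
    if not 1 <= dim <= min(v, m):
        raise ValueError(f"dim must lie in [1, {min(v, m)}], got {dim}")
    cov = m_mat.T @ m_mat
    if method == "eig":
        w, vec = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w = np.clip(w[order], 0.0, None)
        vec = vec[:, order]
        w, vec = w[:dim], vec[:, :dim]
    elif method == "em":
        w, vec = _orthogonal_iteration(cov, dim, np.random.default_rng(seed))
    else:
        raise ValueError("method must be 'em' or 'eig'")
    total = float(np.trace(cov))
    scale = np.sqrt(np.clip(w, 1e-300, None))
    whitened = np.sqrt(v) * (vec / scale).T @ m_mat.T  # (dim, v)
    return GroupPca(
        dim=dim, basis=vec, eigenvalues=w,
        explained=(w / total if total > 0 else np.zeros_like(w)),
        whitened=whitened,
        subject_dims=tuple(r.dim for r in reductions),
        n_voxels=v,
    )


def whiten_check(x: np.ndarray, atol: float = 1e-8) -> bool:
    """True when x @ x.T / n equals the identity within ``atol``."""
    g = x @ x.T / x.shape[1]
    return bool(np.allclose(g, np.eye(x.shape[0]), atol=atol))


# ---------------------------------------------------------------------------
# Infomax ICA
# ---------------------------------------------------------------------------

@dataclass
class IcaDecomposition:
    """An ICA of whitened data: sources = unmixing @ data."""

    unmixing: np.ndarray  # (k, k)
    mixing: np.ndarray  # (k, k), inverse of unmixing
    sources: np.ndarray  # (k, n) raw source estimates
    maps: np.ndarray  # (k, n) z-scored spatial maps
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        ident = self.unmixing @ self.mixing
        if not np.allclose(ident, np.eye(ident.shape[0]), atol=1e-6):
            raise ValueError("unmixing @ mixing must be the identity")


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def infomax(
    x: np.ndarray,
    n_components: int | None = None,
    learning_rate: float = 0.05,
    max_iter: int = 2000,
    tol: float = 1e-7,
    seed: int = 0,
    max_anneals: int = 20,
) -> IcaDecomposition:
    """Infomax ICA: natural-gradient entropy maximisation with a
    logistic nonlinearity.

    ``x`` must be whitened (k x n). The weight matrix starts at a random
    orthonormal matrix drawn from ``seed`` and follows the natural
    gradient ``dW = (I + (1 - 2g(u)) u^T / n) W`` with ``u = Wx`` and
    logistic ``g``; on divergence the learning rate is annealed (halved)
    and the last stable weights restored. Converges when the update
    norm drops below ``tol``.
    """
    x = np.asarray(x, dtype=float)
    k, n = x.shape
    if n_components is not None and n_components != k:
        raise ValueError("n_components must equal the whitened dimension")
    if not whiten_check(x, atol=1e-6):
        warnings.warn("input does not look whitened; Infomax assumes "
                      "identity covariance", UserWarning, stacklevel=2)
    rng = np.random.default_rng(seed)
    w = np.linalg.qr(rng.standard_normal((k, k)))[0]
    lr = learning_rate
    anneals = 0
    w_last = w.copy()
    delta_last: np.ndarray | None = None
    n_iter = 0
    converged = False
    eye = np.eye(k)
    for n_iter in range(1, max_iter + 1):
        u = w @ x
        with np.errstate(over="ignore"):
            g = 1.0 / (1.0 + np.exp(-u))
        grad = (eye + (1.0 - 2.0 * g) @ u.T / n) @ w
        delta = lr * grad
        change = np.linalg.norm(delta)
        if not np.isfinite(change) or change > 1e3:
            anneals += 1
            if anneals > max_anneals:
                raise ConvergenceError(
                    f"Infomax diverged after {anneals} annealing steps "
                    f"(iter {n_iter}, lr {lr:g})"
                )
            lr *= 0.5
            w = w_last.copy()
            delta_last = None
            continue
        # anneal when successive updates turn by more than 60 degrees
        if delta_last is not None:
            denom = np.linalg.norm(delta) * np.linalg.norm(delta_last)
            if denom > 0 and float(
                    np.sum(delta * delta_last)) / denom < 0.5:
                lr *= 0.9
        w_last = w.copy()
        delta_last = delta
        w = w + delta
        if change < tol:
            converged = True
            break
    sources = w @ x
    return IcaDecomposition(
        unmixing=w, mixing=np.linalg.inv(w), sources=sources,
        maps=_zscore_rows(sources), n_iter=n_iter, converged=converged,
    )


# ---------------------------------------------------------------------------
# ICASSO stability selection
# ---------------------------------------------------------------------------

@dataclass
class IcassoResult:
    """Aggregate components from repeated Infomax runs.

    ``maps`` holds the centrotype spatial maps (one per cluster);
    ``stability`` is the ICASSO cluster-quality index (mean intra-
    cluster similarity minus mean extra-cluster similarity, in [0, 1]
    for compact well-separated clusters).
    """

    maps: np.ndarray  # (k, n) centrotype maps (z-scored)
    mixing: np.ndarray  # (dim, k) least-squares mixing in whitened space
    stability: np.ndarray  # (k,) intra minus extra cluster similarity
    intra_similarity: np.ndarray  # (k,)
    extra_similarity: np.ndarray  # (k,)
    cluster_labels: np.ndarray  # cluster id per pooled run-component
    pooled_maps: np.ndarray  # (runs*k, n)
    centrotype_index: np.ndarray  # (k,) row into pooled_maps
    n_runs: int


def icasso(
    x: np.ndarray,
    n_components: int | None = None,
    n_runs: int = 10,
    seed: int = 0,
    run_seeds: list[int] | None = None,
    **infomax_kwargs,
) -> IcassoResult:
    """Stability-selected ICA: repeat Infomax, cluster the components.

    Infomax runs ``n_runs`` times from seeds spawned off ``seed``; all
    run-components are pooled and clustered by average-linkage
    agglomeration under dissimilarity 1 - |spatial correlation| into
    ``n_components`` clusters. Each cluster's centrotype (the member
    with the largest within-cluster similarity sum) becomes an
    aggregate map. Runs that fail to converge are excluded with a
    warning; if every run fails an error is raised.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    k = x.shape[0] if n_components is None else n_components
    if run_seeds is None:
        run_seeds = [int(s % (2 ** 31)) for s in
                     np.random.SeedSequence(seed).generate_state(n_runs)]
    elif len(run_seeds) != n_runs:
        raise ValueError("run_seeds must have n_runs entries")
    run_maps = []
    for s in run_seeds:
        try:
            dec = infomax(x, seed=int(s), **infomax_kwargs)
        except ConvergenceError as exc:
            warnings.warn(f"excluding non-converged run: {exc}",
                          UserWarning, stacklevel=2)
            continue
        run_maps.append(dec.maps)
    if not run_maps:
        raise ConvergenceError("all ICASSO runs failed to converge")
    pooled = np.vstack(run_maps)
    sim = np.abs(np.corrcoef(pooled))
    np.fill_diagonal(sim, 1.0)
    dissim = 1.0 - sim
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    uniq = np.unique(labels)
    if uniq.size != k:
        warnings.warn(
            f"requested {k} clusters but linkage cut produced {uniq.size}",
            UserWarning, stacklevel=2,
        )
    centro_rows, intra_sim, extra_sim = [], [], []
    for lab in uniq:
        members = np.flatnonzero(labels == lab)
        within = sim[np.ix_(members, members)]
        outside = sim[np.ix_(members,
                             np.flatnonzero(labels != lab))]
        sums = within.sum(axis=1)
        centro_rows.append(members[int(np.argmax(sums))])
        if members.size > 1:
            intra = (within.sum() - members.size) / (
                members.size * (members.size - 1))
        else:
            intra = 1.0
        extra = float(outside.mean()) if outside.size else 0.0
        intra_sim.append(intra)
        extra_sim.append(extra)
    centro_rows = np.asarray(centro_rows)
    intra_sim = np.asarray(intra_sim)
    extra_sim = np.asarray(extra_sim)
    maps = _zscore_rows(pooled[centro_rows])
    # least-squares mixing of the aggregate maps in whitened space
    mixing = x @ maps.T @ np.linalg.pinv(maps @ maps.T)
    return IcassoResult(
        maps=maps, mixing=mixing, stability=intra_sim - extra_sim,
        intra_similarity=intra_sim, extra_similarity=extra_sim,
        cluster_labels=labels, pooled_maps=pooled,
        centrotype_index=centro_rows, n_runs=len(run_maps),
    )


# ---------------------------------------------------------------------------
# back-reconstruction
# ---------------------------------------------------------------------------

def back_reconstruct(
    subject_data: list[np.ndarray],
    group_maps: np.ndarray,
    method: str = "dual_regression",
    reductions: list[PcaReduction] | None = None,
    group_pca: GroupPca | None = None,
    group_mixing: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-specific timecourses and maps from the group decomposition.

    ``"dual_regression"`` (default): regress each subject's data on the
    group maps to get timecourses, then regress on those timecourses to
    get subject maps. ``"gica"``: propagate the group mixing back
    through the subject and group PCA de-whitening transforms
    (requires ``reductions``, ``group_pca`` and ``group_mixing``).

    Returns one ``(timecourses (k x t), maps (k x voxels))`` pair per
    subject.
    """
    s = np.asarray(group_maps, dtype=float)
    k = s.shape[0]
    out = []
    if method == "dual_regression":
        design = s.T  # (v, k)
        gram = design.T @ design
        if np.linalg.matrix_rank(gram) < k:
            raise np.linalg.LinAlgError(
                "group maps are rank deficient; dual regression design "
                "is singular"
            )
        for y in subject_data:
            yc = y - y.mean(axis=1, keepdims=True)
            tc, *_ = np.linalg.lstsq(design, yc, rcond=None)  # (k, t)
            if np.linalg.matrix_rank(tc @ tc.T) < k:
                raise np.linalg.LinAlgError(
                    "subject timecourses are rank deficient; cannot "
                    "re-estimate maps"
                )
            maps_i, *_ = np.linalg.lstsq(tc.T, yc.T, rcond=None)  # (k, v)
            out.append((tc, maps_i))
        return out
    if method == "gica":
        if reductions is None or group_pca is None or group_mixing is None:
            raise ValueError(
                "gica back-reconstruction needs reductions, group_pca and "
                "group_mixing"
            )
        blocks = group_pca.subject_blocks()
        scale = np.sqrt(np.clip(group_pca.eigenvalues, 0.0, None))
        root_v = np.sqrt(group_pca.n_voxels)
        for y, red, e_i in zip(subject_data, reductions, blocks):
            yc = y - y.mean(axis=1, keepdims=True)
            # subject mixing: V_i E_i Lambda^{1/2} A / sqrt(v)
            a_i = red.basis @ e_i @ (scale[:, None] * group_mixing) / root_v
            tc = a_i.T  # (k, t)
            maps_i, *_ = np.linalg.lstsq(a_i, yc.T, rcond=None)
            out.append((tc, maps_i))
        return out
    raise ValueError("method must be 'dual_regression' or 'gica'")


# ---------------------------------------------------------------------------
# component labelling
# ---------------------------------------------------------------------------

def low_frequency_fraction(
    tc: np.ndarray, tr: float, cutoff: float = 0.1
) -> float:
    """Fraction of timecourse spectral power at or below ``cutoff`` Hz.

    Uses the periodogram at sampling rate 1/TR, excluding the DC bin.
    """
    freqs, power = periodogram(np.asarray(tc, float), fs=1.0 / tr)
    freqs, power = freqs[1:], power[1:]
    total = power.sum()
    if total <= 0:
        return 0.0
    return float(power[freqs <= cutoff].sum() / total)


def label_components(
    maps: np.ndarray,
    timecourses: np.ndarray,
    templates: np.ndarray,
    template_names: list[str],
    tr: float,
    r_threshold: float = 0.2,
    lf_cutoff: float = 0.1,
    lf_fraction_threshold: float = 0.5,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign each component to a network or flag it as artifact.

    A component gets its best-correlated template's network only when
    all three criteria pass: spatial correlation >= ``r_threshold``,
    low-frequency power fraction >= ``lf_fraction_threshold``, and the
    peak-|z| voxel lying inside ``mask`` (trivially true when no mask is
    given). Otherwise it is labelled ``"artifact"``.
    """
    maps = np.asarray(maps, float)
    templates = np.asarray(templates, float)
    if maps.shape[1] != templates.shape[1]:
        raise ValueError(
            f"template grid mismatch: maps have {maps.shape[1]} voxels, "
            f"templates {templates.shape[1]}"
        )
    if len(template_names) != templates.shape[0]:
        raise ValueError("one name per template required")
    rows = []
    for ci in range(maps.shape[0]):
        corrs = np.array([
            np.corrcoef(maps[ci], templates[ti])[0, 1]
            for ti in range(templates.shape[0])
        ])
        best = int(np.argmax(corrs))
        lf = low_frequency_fraction(timecourses[ci], tr, lf_cutoff)
        peak = int(np.argmax(np.abs(maps[ci])))
        in_mask = True if mask is None else bool(np.asarray(mask).ravel()[peak])
        ok = (corrs[best] >= r_threshold and lf >= lf_fraction_threshold
              and in_mask)
        rows.append({
            "component": ci,
            "network": template_names[best] if ok else "artifact",
            "template_correlation": float(corrs[best]),
            "lf_fraction": lf,
            "peak_in_mask": in_mask,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# convenience: full path, and permutation/sign invariant matching
# ---------------------------------------------------------------------------

def match_components(
    truth: np.ndarray, estimate: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal assignment of estimated to true components on |correlation|.

    Returns (column index per truth row, |correlation| per truth row);
    all recovery scoring is sign- and permutation-invariant.
    """
    from scipy.optimize import linear_sum_assignment

    t = np.asarray(truth, float)
    e = np.asarray(estimate, float)
    c = np.zeros((t.shape[0], e.shape[0]))
    for i in range(t.shape[0]):
        for j in range(e.shape[0]):
            c[i, j] = abs(np.corrcoef(t[i], e[j])[0, 1])
    rows, cols = linear_sum_assignment(-c)
    return cols, c[rows, cols]


def run_group_ica(
    subject_data: list[np.ndarray],
    subject_dim: int,
    group_dim: int,
    n_runs: int = 10,
    seed: int = 0,
    back_method: str = "dual_regression",
    **infomax_kwargs,
) -> tuple[IcassoResult, list[tuple[np.ndarray, np.ndarray]]]:
    """Full decomposition path: subject PCA, group PCA, ICASSO-stabilised
    Infomax, then back-reconstruction. Returns the stability result and
    the per-subject (timecourses, maps) pairs."""
    reductions = [subject_pca(y, subject_dim) for y in subject_data]
    gp = group_reduce(reductions, group_dim, seed=seed)
    res = icasso(gp.whitened, n_runs=n_runs, seed=seed, **infomax_kwargs)
    subs = back_reconstruct(
        subject_data, res.maps, method=back_method,
        reductions=reductions, group_pca=gp, group_mixing=res.mixing,
    )
    return res, subs
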