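"""Static functional network connectivity (sFNC).

Static FNC summarises the coupling between ICA-derived component
timecourses over a whole scan: one Pearson correlation per component
pair, Fisher z-transformed, then tested edgewise for a group difference
with a GLM that adjusts for nuisance covariates and controls the false
discovery rate across edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .stats import bh_fdr

__all__ = [
    "ComponentTimecourses",
    "FNCMatrix",
    "CollinearityError",
    "DegenerateComponentError",
    "FISHER_CLAMP",
    "condition_timecourses",
    "regress_confounds",
    "compute_sfnc",
    "fisher_z",
    "sfnc_group_glm",
    "edge_index_pairs",
]

#: correlations are clamped to +/-(1 - FISHER_CLAMP) before atanh
FISHER_CLAMP = 1e-6


class CollinearityError(ValueError):
    """Confound matrix is rank deficient after adding an intercept."""


class DegenerateComponentError(ValueError):
    """A component timecourse has zero variance."""


@dataclass
class ComponentTimecourses:
    """Per-subject component timecourses: the currency of the pipeline.

    Parameters
    ----------
    subject_id : str
        Identifier, unique within a cohort.
    data : ndarray, shape (components, timepoints)
    tr : float
        Repetition time in seconds; must be positive.
    labels : sequence of str, optional
        One label per component (e.g. network names).
    """

    subject_id: str
    data: np.ndarray
    tr: float = 2.0
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("data must be 2-D with at least 2 components")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite values in timecourses")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.labels is not None:
            self.labels = tuple(self.labels)
            if len(self.labels) != self.data.shape[0]:
                raise ValueError("labels length must equal component count")

    @property
    def n_components(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class FNCMatrix:
    """Symmetric component-by-component connectivity matrix.

    ``scale`` is ``"r"`` (Pearson correlation, unit diagonal) or ``"z"``
    (Fisher z, zero diagonal by convention).
    """

    values: np.ndarray
    scale: str = "r"
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if self.scale not in ("r", "z"):
            raise ValueError("scale must be 'r' or 'z'")
        if self.scale == "r" and np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    def vectorize(self) -> np.ndarray:
        """Unique off-diagonal edges in fixed (i<j) row-major order."""
        iu = np.triu_indices(self.n_components, k=1)
        return self.values[iu]


def edge_index_pairs(n_components: int) -> list[tuple[int, int]]:
    """The fixed (i<j) row-major edge ordering used for all edge vectors."""
    iu, ju = np.triu_indices(n_components, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


# ---------------------------------------------------------------------------
# timecourse conditioning and confound regression
# ---------------------------------------------------------------------------

def condition_timecourses(
    tc: ComponentTimecourses,
    detrend: bool = True,
    band: tuple[float, float] | None = None,
) -> ComponentTimecourses:
    """Linear detrend and optional zero-phase band-pass per component.

    ``band`` is (low, high) in Hz and must lie strictly inside
    (0, Nyquist) where Nyquist = 1/(2*TR). Length is preserved.
    """
    data = tc.data
    if detrend:
        data = signal.detrend(data, axis=1, type="linear")
    if band is not None:
        low, high = band
        nyq = 1.0 / (2.0 * tc.tr)
        if not (0.0 < low < high < nyq):
            raise ValueError(
                f"band {band} must satisfy 0 < low < high < Nyquist ({nyq:g} Hz)"
            )
        sos = signal.butter(4, [low, high], btype="bandpass", fs=1.0 / tc.tr,
                            output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
    return replace(tc, data=np.array(data, dtype=float))


def regress_confounds(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """OLS residualization of ``series`` on ``confounds`` plus an intercept.

    ``series`` is timepoints x channels, ``confounds`` timepoints x
    regressors. Residuals are orthogonal to every confound column. A
    rank-deficient design raises :class:`CollinearityError` naming the
    offending columns.
    """
    y = np.atleast_2d(np.asarray(series, dtype=float))
    if y.shape[0] == 1:
        y = y.T
    conf = np.asarray(confounds, dtype=float)
    if conf.ndim == 1:
        conf = conf[:, None]
    if conf.shape[0] != y.shape[0]:
        raise ValueError("series and confounds must share the timepoint axis")
    x = np.column_stack([np.ones(conf.shape[0]), conf])
    # QR with column pivoting exposes which columns are redundant
    r = np.linalg.qr(x, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * diag.max()
    if np.any(diag < tol):
        bad = []
        for j in range(1, x.shape[1]):
            sub = x[:, [c for c in range(x.shape[1]) if c != j]]
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(x):
                bad.append(j - 1)
        raise CollinearityError(
            f"confound columns {bad} are collinear with the rest of the design"
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


# ---------------------------------------------------------------------------
# static FNC
# ---------------------------------------------------------------------------

def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilising transform z = atanh(r), with |r| clamped."""
    r = np.clip(np.asarray(r, dtype=float), -(1 - FISHER_CLAMP), 1 - FISHER_CLAMP)
    return np.arctanh(r)


def compute_sfnc(tc: ComponentTimecourses, fisher: bool = False) -> FNCMatrix:
    """All-pairs Pearson correlation of the component timecourses.

    With ``fisher`` the matrix is returned on the Fisher-z scale with a
    zero diagonal. A zero-variance component raises
    :class:`DegenerateComponentError`.
    """
    if tc.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    sd = tc.data.std(axis=1)
    scale = np.abs(tc.data).max(axis=1) + 1.0
    dead = np.flatnonzero(sd <= 1e-12 * scale)
    if dead.size:
        raise DegenerateComponentError(
            f"components {dead.tolist()} have zero variance"
        )
    r = np.corrcoef(tc.data)
    r = (r + r.T) / 2.0
    if not fisher:
        np.fill_diagonal(r, 1.0)
        return FNCMatrix(r, scale="r", labels=tc.labels)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    return FNCMatrix(z, scale="z", labels=tc.labels)


def sfnc_group_glm(
    z_matrices: dict[str, FNCMatrix],
    covariates: pd.DataFrame,
    group_col: str = "group",
    nuisance: tuple[str, ...] = ("age", "education"),
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Edgewise GLM for a group difference in Fisher-z connectivity.

    Each unique edge is regressed on intercept + group indicator +
    nuisance covariates; the group coefficient's two-sided t/p are
    Benjamini-Hochberg adjusted across edges. ``covariates`` is indexed
    by subject id and must cover every subject in ``z_matrices``.

    Returns a table with one row per edge: ``edge_i, edge_j, estimate,
    t, df, p, q, significant`` (plus network labels when available).
    """
    subjects = list(z_matrices)
    missing = [s for s in subjects if s not in covariates.index]
    if missing:
        raise KeyError(f"subjects missing from the covariate table: {missing}")
    sub_cov = covariates.loc[subjects]
    for col in (group_col, *nuisance):
        if col not in sub_cov.columns:
            raise KeyError(f"covariate column {col!r} not found")
        if sub_cov[col].isna().any():
            bad = sub_cov.index[sub_cov[col].isna()].tolist()
            raise ValueError(f"missing {col!r} for subjects {bad}")
    groups = sub_cov[group_col]
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"group must be binary, got levels {levels}")
    gind = (groups == levels[1]).to_numpy(dtype=float)

    first = z_matrices[subjects[0]]
    n_comp = first.n_components
    y = np.vstack([z_matrices[s].vectorize() for s in subjects])  # n x edges
    x = np.column_stack(
        [np.ones(len(subjects)), gind]
        + [sub_cov[c].to_numpy(dtype=float) for c in nuisance]
    )
    n, p_dim = x.shape
    df = n - p_dim
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, 0.0)
    from scipy import stats as sps

    p = 2.0 * sps.t.sf(np.abs(t), df)
    q, rej = bh_fdr(p, q_level=alpha)

    pairs = edge_index_pairs(n_comp)
    out = pd.DataFrame(
        {
            "edge_i": [i for i, _ in pairs],
            "edge_j": [j for _, j in pairs],
            "estimate": beta[1],
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "significant": rej,
        }
    )
    if first.labels is not None:
        out.insert(2, "network_i", [first.labels[i] for i, _ in pairs])
        out.insert(3, "network_j", [first.labels[j] for _, j in pairs])
    return out
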