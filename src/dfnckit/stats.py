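"""Group comparisons and covariate correlations.

Two-sample t-tests (from raw values or printed summary statistics),
Pearson correlations with p-values, Benjamini-Hochberg FDR control, and
the two result grids of a state-based connectivity study: temporal
metrics vs clinical covariates, and per-state edgewise group tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "UndefinedStatisticError",
    "two_sample_t",
    "summary_t",
    "pearson_with_p",
    "bh_fdr",
    "metrics_vs_clinical",
    "per_state_edge_tests",
    "chi_square_counts",
]


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for the given input."""


@dataclass(frozen=True)
class GroupComparison:
    """A two-sample comparison of one variable between two groups."""

    variable: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: float
    p: float
    method: str  # "pooled" | "welch" | "summary-pooled" | "summary-welch"


def _check_summary(s1: float, n1: int, s2: float, n2: int,
                   m1: float, m2: float) -> None:
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0 and m1 == m2:
        raise UndefinedStatisticError(
            "t is undefined: zero variance in both groups with equal means"
        )


def summary_t(
    m1: float, s1: float, n1: int,
    m2: float, s2: float, n2: int,
    pooled: bool = True,
    variable: str = "",
) -> GroupComparison:
    """Two-sample t from group summary statistics (mean, sd, n).

    The pooled-variance Student form uses df = n1 + n2 - 2; the Welch
    form uses the Welch-Satterthwaite df. This is the estimator needed
    to recompute printed "Mean +/- SD" table rows.
    """
    _check_summary(s1, n1, s2, n2, m1, m2)
    t, p = sps.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=pooled
    )
    if pooled:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = s1 ** 2 / n1, s2 ** 2 / n2
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    return GroupComparison(
        variable, float(m1), float(s1), int(n1), float(m2), float(s2), int(n2),
        float(t), df, float(p), "summary-pooled" if pooled else "summary-welch",
    )


def two_sample_t(
    x: np.ndarray, y: np.ndarray, pooled: bool = True, variable: str = ""
) -> GroupComparison:
    """Two-sample t-test on raw values (pooled Student by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    comp = summary_t(
        float(np.mean(x)), float(np.std(x, ddof=1)), x.size,
        float(np.mean(y)), float(np.std(y, ddof=1)), y.size,
        pooled=pooled, variable=variable,
    )
    return GroupComparison(
        comp.variable, comp.mean1, comp.sd1, comp.n1, comp.mean2, comp.sd2,
        comp.n2, comp.t, comp.df, comp.p, "pooled" if pooled else "welch",
    )


def pearson_with_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Pearson r with a two-sided p-value, pairwise-complete.

    Missing entries (NaN) are dropped pairwise. The p-value comes from
    t = r*sqrt((n-2)/(1-r^2)) on n-2 df.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p), int(n)


def bh_fdr(p: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and rejection mask."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject


def chi_square_counts(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    chi2, p, _, _ = sps.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def metrics_vs_clinical(
    metrics: pd.DataFrame,
    clinical: pd.DataFrame,
    covariate_cols: tuple[str, ...],
    group_col: str = "group",
    patient_group: str | None = None,
    metric_cols: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Pearson r/p grid of temporal metrics against clinical covariates.

    Restricted to the patient group (the convention for clinical
    correlates of state dynamics). Rows are metric columns, one result
    row per (metric, covariate) cell, with significance flags at the
    0.05 and 0.01 levels.
    """
    joined = metrics.join(clinical, how="inner", rsuffix="_clin")
    if group_col not in joined.columns:
        raise KeyError(f"group column {group_col!r} not found")
    if patient_group is None:
        patient_group = sorted(pd.unique(joined[group_col]))[0]
    sub = joined[joined[group_col] == patient_group]
    if metric_cols is None:
        metric_cols = tuple(
            c for c in metrics.columns
            if c.startswith(("frac_", "dwell_")) or c == "transitions"
        )
    rows = []
    for mcol in metric_cols:
        for ccol in covariate_cols:
            if ccol not in sub.columns:
                raise KeyError(f"covariate column {ccol!r} not found")
            try:
                r, p, n = pearson_with_p(sub[mcol].to_numpy(),
                                         sub[ccol].to_numpy())
                err = ""
            except ValueError as exc:
                # degenerate cell (too few pairs / zero variance): keep
                # the grid shape, record the reason
                r = p = np.nan
                n = int(np.isfinite(sub[mcol].to_numpy()).sum())
                err = str(exc)
            rows.append(
                {"metric": mcol, "covariate": ccol, "r": r, "p": p, "n": n,
                 "sig_05": bool(p < 0.05) if np.isfinite(p) else False,
                 "sig_01": bool(p < 0.01) if np.isfinite(p) else False,
                 "error": err}
            )
    return pd.DataFrame(rows)


def per_state_edge_tests(
    state_vectors: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.01,
    pooled: bool = True,
) -> dict[int, pd.DataFrame]:
    """Per-state edgewise two-sample t-tests with BH correction per state.

    ``state_vectors`` is (subjects, states, edges) with NaN rows for
    subjects that never visited a state; such subjects are excluded from
    that state's tests. A state with fewer than 2 subjects in either
    group is skipped with a warning.
    """
    state_vectors = np.asarray(state_vectors, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    out: dict[int, pd.DataFrame] = {}
    n_sub, n_states, n_edges = state_vectors.shape
    for s in range(n_states):
        present = ~np.isnan(state_vectors[:, s, :]).any(axis=1)
        ga = present & (groups == levels[0])
        gb = present & (groups == levels[1])
        if ga.sum() < 2 or gb.sum() < 2:
            warnings.warn(
                f"state {s + 1}: fewer than 2 subjects with this state in a "
                "group; skipped", UserWarning, stacklevel=2,
            )
            continue
        xa = state_vectors[ga, s, :]
        xb = state_vectors[gb, s, :]
        t, p = sps.ttest_ind(xa, xb, axis=0, equal_var=pooled)
        q, rej = bh_fdr(p, q_level=alpha)
        out[s] = pd.DataFrame(
            {
                "edge": np.arange(n_edges),
                "t": t,
                "p": p,
                "q": q,
                "significant": rej,
                "direction": np.where(t > 0, f"{levels[0]}>{levels[1]}",
                                      f"{levels[0]}<{levels[1]}"),
                "n_a": ga.sum(),
                "n_b": gb.sum(),
            }
        )
    return out
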