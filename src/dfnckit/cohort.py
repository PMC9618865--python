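"""Synthetic two-group cohort generator with Markov state-covariance truth.

The generator emulates the study design the pipeline targets: two groups
of 19 subjects, 21 components in 7 resting-state networks, 230 retained
timepoints at TR = 2 s, and 4 recurring connectivity states. Each
subject follows a hidden Markov chain over states; at every timepoint
the component vector is drawn from a zero-mean multivariate normal with
the active state's covariance. Clinical covariates are statistically
coupled to the subject's true State-1 occupancy so that every
downstream stage (windowed connectivity, state clustering, temporal
metrics, group tests, clinical correlations) has a ground-truth
recovery test.

The Markov model is generative bookkeeping only — the analysis side
never fits an HMM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .sfnc import ComponentTimecourses

__all__ = [
    "NetworkPartition",
    "StateSpec",
    "StateCovarianceSet",
    "MarkovModel",
    "CohortConfig",
    "SimulatedCohort",
    "DEFAULT_PARTITION",
    "default_state_specs",
    "default_cohort_config",
    "make_state_covariances",
    "markov_from_occupancy",
    "sample_state_sequence",
    "simulate_subject",
    "simulate_cohort",
    "render_phantom_volumes",
]


@dataclass(frozen=True)
class NetworkPartition:
    """Ordered partition of components into named networks."""

    labels: tuple[str, ...]
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sizes):
            raise ValueError("labels and sizes must align")
        if any(s < 1 for s in self.sizes):
            raise ValueError("every network needs at least one component")

    @property
    def n_components(self) -> int:
        return int(sum(self.sizes))

    @property
    def slices(self) -> dict[str, slice]:
        out, start = {}, 0
        for lab, size in zip(self.labels, self.sizes):
            out[lab] = slice(start, start + size)
            start += size
        return out

    def component_labels(self) -> tuple[str, ...]:
        return tuple(
            lab for lab, size in zip(self.labels, self.sizes) for _ in range(size)
        )


#: the 21-component / 7-network layout of the target study
DEFAULT_PARTITION = NetworkPartition(
    labels=("AN", "DMN", "ECN", "LN", "SMN", "SN", "VN"),
    sizes=(1, 5, 5, 2, 2, 2, 4),
)


@dataclass(frozen=True)
class StateSpec:
    """Coupling levels defining one state's block correlation structure.

    ``within`` is either a single level for all networks or a mapping
    network -> level; ``between`` is the default cross-network level;
    ``pair_between`` optionally overrides specific unordered network
    pairs (e.g. a positively coupled DMN-VN block).
    """

    name: str
    archetype: str
    within: float | dict[str, float] = 0.1
    between: float = 0.05
    pair_between: dict[tuple[str, str], float] = field(default_factory=dict)


def default_state_specs(separation: str = "default") -> tuple[StateSpec, ...]:
    """The 4-state archetype: weak-global, two strong-within-network,
    and a DMN+VN-positive state.

    ``separation="high"`` strengthens the within/between contrast for
    clustering-recovery checks that need unambiguous states.
    """
    if separation == "default":
        hi, mid, lo, bt = 0.7, 0.4, 0.1, 0.2
        s1w, s1b = 0.1, 0.05
    elif separation == "high":
        hi, mid, lo, bt = 0.85, 0.5, 0.1, 0.45
        # State 1 keeps a clearly weaker but estimable pattern: at the
        # default 0.1/0.05 amplitude its centroid cannot be recovered to
        # high fidelity from ~230 timepoints of 22-TR windows.
        s1w, s1b = 0.25, 0.08
    else:
        raise ValueError("separation must be 'default' or 'high'")
    # The four archetypes are kept mutually non-collinear as edge
    # patterns: uniform two-level block matrices are all perfectly
    # correlated with one another, which would make correlation-based
    # truth matching ill-posed. State 2 is sensory-dominant and
    # globally integrated, State 3 association-dominant and segregated
    # between networks.
    sensory = {"AN": hi, "SMN": hi, "VN": hi, "DMN": mid, "ECN": mid,
               "LN": mid, "SN": mid}
    assoc = {"AN": mid, "SMN": mid, "VN": mid, "DMN": hi, "ECN": hi,
             "LN": hi, "SN": hi}
    return (
        StateSpec("State1", "weak-global", within=s1w, between=s1b),
        StateSpec("State2", "strong-within-network", within=sensory,
                  between=bt),
        StateSpec("State3", "strong-within-network", within=assoc,
                  between=-bt),
        StateSpec(
            "State4", "DMN+VN-positive",
            within={"DMN": hi, "VN": hi, "AN": lo, "ECN": lo, "LN": lo,
                    "SMN": lo, "SN": lo},
            between=lo / 2,
            pair_between={("DMN", "VN"): hi},
        ),
    )


@dataclass
class StateCovarianceSet:
    """K symmetric PSD unit-diagonal component covariance matrices."""

    labels: tuple[str, ...]
    matrices: np.ndarray  # (K, C, C)
    archetypes: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must be (K, C, C)")
        for k in range(m.shape[0]):
            if not np.allclose(m[k], m[k].T, atol=1e-10):
                raise ValueError(f"state {k} covariance not symmetric")
            if np.linalg.eigvalsh(m[k]).min() < -1e-10:
                raise ValueError(f"state {k} covariance not PSD")
            if not np.allclose(np.diag(m[k]), 1.0, atol=1e-8):
                raise ValueError(f"state {k} covariance not unit-diagonal")
        self.matrices = m

    @property
    def n_states(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_components(self) -> int:
        return self.matrices.shape[1]


def _psd_repair(mat: np.ndarray, max_rounds: int = 50) -> np.ndarray:
    """Clip negative eigenvalues, reconstruct, rescale to unit diagonal.

    Rescaling can re-introduce tiny negative eigenvalues, so alternate
    until both constraints hold.
    """
    out = mat.copy()
    for _ in range(max_rounds):
        w, v = np.linalg.eigh(out)
        if w.min() >= -1e-12:
            break
        out = (v * np.clip(w, 0.0, None)) @ v.T
        d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
        out = (out + out.T) / 2.0
    else:
        raise ArithmeticError("PSD repair did not converge")
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


def make_state_covariances(
    partition: NetworkPartition,
    state_specs: tuple[StateSpec, ...] | list[StateSpec],
) -> StateCovarianceSet:
    """Build unit-diagonal PSD block correlation matrices from coupling specs.

    Within-network blocks carry the within level, cross-network blocks
    the between level (with optional per-pair overrides). Non-PSD drafts
    are repaired by eigenvalue clipping and re-normalisation.
    """
    c = partition.n_components
    slc = partition.slices
    mats = []
    for spec in state_specs:
        levels = [spec.within, spec.between, *spec.pair_between.values()]
        flat = []
        for lv in levels:
            flat.extend(lv.values() if isinstance(lv, dict) else [lv])
        if any(abs(x) >= 1 for x in flat):
            raise ValueError(
                f"{spec.name}: coupling magnitudes must be < 1"
            )
        m = np.full((c, c), float(spec.between))
        for a in partition.labels:
            for b in partition.labels:
                if a == b:
                    w = (spec.within[a] if isinstance(spec.within, dict)
                         else spec.within)
                    m[slc[a], slc[b]] = w
                else:
                    key = (a, b) if (a, b) in spec.pair_between else (b, a)
                    if key in spec.pair_between:
                        m[slc[a], slc[b]] = spec.pair_between[key]
        np.fill_diagonal(m, 1.0)
        m = (m + m.T) / 2.0
        if np.linalg.eigvalsh(m).min() < 0:
            m = _psd_repair(m)
        mats.append(m)
    return StateCovarianceSet(
        labels=tuple(s.name for s in state_specs),
        matrices=np.stack(mats),
        archetypes=tuple(s.archetype for s in state_specs),
    )


# ---------------------------------------------------------------------------
# Markov machinery
# ---------------------------------------------------------------------------

@dataclass
class MarkovModel:
    """Row-stochastic transition matrix plus an initial distribution."""

    transition: np.ndarray  # (K, K)
    initial: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        p = np.asarray(self.transition, dtype=float)
        pi = np.asarray(self.initial, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("transition entries must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")
        if pi.shape != (p.shape[0],) or not np.isclose(pi.sum(), 1.0,
                                                       atol=1e-12):
            raise ValueError("initial distribution must sum to 1")
        self.transition, self.initial = p, pi

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left eigenvector of the transition)."""
        w, v = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def markov_from_occupancy(occupancy: np.ndarray, stickiness: float) -> MarkovModel:
    """Chain with exact stationary distribution ``occupancy``.

    P = s*I + (1-s) * 1 w^T: with probability ``stickiness`` stay put,
    otherwise redraw a state from ``occupancy``. The state-i
    self-transition probability is s + (1-s)*w_i and the mean dwell
    grows monotonically with s.
    """
    w = np.asarray(occupancy, dtype=float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-10):
        raise ValueError("occupancy must be a probability vector")
    if not (0.0 <= stickiness < 1.0):
        raise ValueError("stickiness must lie in [0, 1)")
    w = w / w.sum()
    k = w.size
    p = stickiness * np.eye(k) + (1.0 - stickiness) * np.ones((k, 1)) @ w[None, :]
    return MarkovModel(transition=p, initial=w.copy())


def sample_state_sequence(
    model: MarkovModel, n_timepoints: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw a state sequence of length ``n_timepoints`` from the chain."""
    if n_timepoints < 1:
        raise ValueError("need at least one timepoint")
    rng = np.random.default_rng(seed)
    cum_p = np.cumsum(model.transition, axis=1)
    seq = np.empty(n_timepoints, dtype=np.int64)
    u = rng.random(n_timepoints)
    seq[0] = np.searchsorted(np.cumsum(model.initial), u[0], side="right")
    for t in range(1, n_timepoints):
        seq[t] = np.searchsorted(cum_p[seq[t - 1]], u[t], side="right")
    return seq


def _run_lengths(seq: np.ndarray) -> np.ndarray:
    change = np.flatnonzero(np.diff(seq) != 0)
    bounds = np.concatenate([[-1], change, [seq.size - 1]])
    return np.diff(bounds)


def simulate_subject(
    covs: StateCovarianceSet,
    sequence: np.ndarray,
    seed: int | np.random.Generator,
    hrf_smoothing: float | None = None,
    subject_id: str = "sub",
    tr: float = 2.0,
    labels: tuple[str, ...] | None = None,
) -> ComponentTimecourses:
    """Draw component timecourses along a given state sequence.

    At each timepoint the component vector is multivariate normal with
    the active state's covariance. ``hrf_smoothing`` optionally applies
    a Gaussian temporal kernel (sigma in TRs) afterwards; smoothing
    mixes adjacent states and weakens instantaneous-covariance fidelity,
    so it is off by default.
    """
    sequence = np.asarray(sequence, dtype=np.int64)
    if sequence.min() < 0 or sequence.max() >= covs.n_states:
        raise ValueError("sequence states must index into the covariance set")
    if np.unique(sequence).size > 1 and np.median(_run_lengths(sequence)) <= 1:
        warnings.warn(
            "most state runs last a single timepoint; sliding windows "
            "cannot resolve states at this timescale", UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(
        covs.matrices + 1e-12 * np.eye(covs.n_components)
    )
    z = rng.standard_normal((sequence.size, covs.n_components))
    x = np.einsum("tij,tj->ti", chol[sequence], z).T  # (C, T)
    if hrf_smoothing is not None and hrf_smoothing > 0:
        x = gaussian_filter1d(x, sigma=hrf_smoothing, axis=1, mode="nearest")
    return ComponentTimecourses(subject_id=subject_id, data=x, tr=tr,
                                labels=labels)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

#: per-group clinical marginals: (patient mean, patient sd, control mean,
#: control sd), matching the demographic table of a stable-COPD cohort.
CLINICAL_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "age": (62.7, 5.9, 62.3, 6.3),
    "education": (5.5, 3.2, 6.2, 2.7),
    "FEV1": (46.1, 20.6, 97.1, 16.6),
    "FVC": (67.5, 19.9, 96.7, 15.4),
    "FEV1_FVC": (55.8, 16.3, 81.2, 8.3),
    "PaO2": (82.6, 16.5, 98.1, 19.6),
    "PaCO2": (49.3, 8.0, 38.5, 4.2),
    "SaO2": (95.5, 2.6, 98.2, 1.8),
    "pH": (7.39, 0.04, 7.41, 0.02),
    "CRP": (8.0, 6.0, 2.0, 1.5),
    "MMSE": (22.4, 3.6, 27.3, 2.2),
    "MoCA": (18.4, 4.3, 26.6, 3.2),
}

#: covariates coupled to true State-1 occupancy: column -> sign of the slope
DEFAULT_COUPLED_COVARIATES: dict[str, float] = {
    "FEV1": -1.0,
    "FEV1_FVC": -1.0,
    "CRP": +1.0,
}


@dataclass
class CohortConfig:
    """Study-condition parameters of the simulated cohort.

    Defaults mirror the target design: 19 subjects per group, 21
    components in 7 networks, 230 timepoints at TR = 2 s, 4 states with
    group-dependent occupancy (patients dwell longer in the weakly
    connected State 1), and clinical covariates linear in true State-1
    occupancy with a configurable R-squared.
    """

    n_per_group: int = 19
    n_timepoints: int = 230
    tr: float = 2.0
    partition: NetworkPartition = field(default_factory=lambda: DEFAULT_PARTITION)
    separation: str = "default"
    group_names: tuple[str, str] = ("COPD", "HC")
    occupancy: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "COPD": (0.55, 0.10, 0.07, 0.28),
            "HC": (0.26, 0.22, 0.16, 0.36),
        }
    )
    stickiness: dict[str, float] = field(
        default_factory=lambda: {"COPD": 0.97, "HC": 0.95}
    )
    coupled_covariates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLED_COVARIATES)
    )
    coupling_r2: float = 0.25
    hrf_smoothing: float | None = None
    seed: int = 0

    def state_specs(self) -> tuple[StateSpec, ...]:
        return default_state_specs(self.separation)

    def markov_models(self) -> dict[str, MarkovModel]:
        return {
            g: markov_from_occupancy(np.asarray(self.occupancy[g]),
                                     self.stickiness[g])
            for g in self.group_names
        }


@dataclass
class SimulatedCohort:
    """Simulated timecourses plus clinical table and generative truth."""

    subjects: list[ComponentTimecourses]
    groups: pd.Series  # subject id -> group label
    clinical: pd.DataFrame  # indexed by subject id
    true_sequences: dict[str, np.ndarray]
    state_covariances: StateCovarianceSet
    markov_models: dict[str, MarkovModel]
    config: CohortConfig
    seed: int

    def true_occupancy(self, state: int = 0) -> pd.Series:
        """Per-subject fraction of timepoints truly spent in ``state``."""
        return pd.Series(
            {
                tc.subject_id:
                    float(np.mean(self.true_sequences[tc.subject_id] == state))
                for tc in self.subjects
            },
            name=f"occ_{state + 1}",
        )


def simulate_cohort(config: CohortConfig | None = None) -> SimulatedCohort:
    """Generate a full two-group cohort with ground truth.

    Clinical covariates listed in ``config.coupled_covariates`` are
    linear in the subject's true State-1 occupancy (sign per config)
    plus Gaussian noise scaled so the within-cohort R-squared equals
    ``config.coupling_r2``; the remaining covariates are drawn from
    group-specific normal marginals. Fully deterministic given
    ``config.seed``.
    """
    config = config or CohortConfig()
    if not (0.0 <= config.coupling_r2 < 1.0):
        raise ValueError("coupling_r2 must lie in [0, 1)")
    for name in config.coupled_covariates:
        if name not in CLINICAL_MARGINALS:
            raise ValueError(f"unknown coupled covariate {name!r}")

    covset = make_state_covariances(config.partition, config.state_specs())
    models = config.markov_models()
    labels = config.partition.component_labels()

    root = np.random.SeedSequence(config.seed)
    seq_ss, noise_ss, clin_ss = root.spawn(3)
    n_total = 2 * config.n_per_group
    seq_children = seq_ss.spawn(n_total)
    noise_children = noise_ss.spawn(n_total)

    subjects: list[ComponentTimecourses] = []
    group_map: dict[str, str] = {}
    sequences: dict[str, np.ndarray] = {}
    i = 0
    for g in config.group_names:
        for j in range(config.n_per_group):
            sid = f"{g}_{j + 1:02d}"
            seq = sample_state_sequence(
                models[g], config.n_timepoints,
                np.random.default_rng(seq_children[i]),
            )
            tc = simulate_subject(
                covset, seq, np.random.default_rng(noise_children[i]),
                hrf_smoothing=config.hrf_smoothing, subject_id=sid,
                tr=config.tr, labels=labels,
            )
            subjects.append(tc)
            group_map[sid] = g
            sequences[sid] = seq
            i += 1

    groups = pd.Series(group_map, name="group")
    clinical = _make_clinical(config, groups, sequences, clin_ss)
    return SimulatedCohort(
        subjects=subjects, groups=groups, clinical=clinical,
        true_sequences=sequences, state_covariances=covset,
        markov_models=models, config=config, seed=config.seed,
    )


def _make_clinical(
    config: CohortConfig,
    groups: pd.Series,
    sequences: dict[str, np.ndarray],
    seed_seq: np.random.SeedSequence,
) -> pd.DataFrame:
    rng = np.random.default_rng(seed_seq)
    ids = list(groups.index)
    occ1 = np.array([np.mean(sequences[s] == 0) for s in ids])
    is_patient = (groups.loc[ids] == config.group_names[0]).to_numpy()

    # matched 14M/5F split per group, deterministic
    def sexes(n: int) -> list[str]:
        n_male = int(round(n * 14 / 19))
        return ["M"] * n_male + ["F"] * (n - n_male)

    sex = sexes(config.n_per_group) + sexes(config.n_per_group)

    data: dict[str, np.ndarray] = {}
    # centered occupancy within the whole cohort drives the coupling
    occ_c = occ1 - occ1.mean()
    occ_sd = occ_c.std()
    for name, (m1, s1, m2, s2) in CLINICAL_MARGINALS.items():
        mu = np.where(is_patient, m1, m2)
        sd = np.where(is_patient, s1, s2)
        if name in config.coupled_covariates and occ_sd > 0:
            sign = np.sign(config.coupled_covariates[name])
            r2 = config.coupling_r2
            slope = sign * np.sqrt(r2) * sd / occ_sd
            noise = rng.standard_normal(len(ids)) * sd * np.sqrt(1.0 - r2)
            data[name] = mu + slope * occ_c + noise
        else:
            data[name] = mu + sd * rng.standard_normal(len(ids))
    table = pd.DataFrame(data, index=pd.Index(ids, name="subject"))
    table.insert(0, "group", groups.loc[ids].to_numpy())
    table.insert(1, "sex", sex)
    return table


# ---------------------------------------------------------------------------
# phantom volumes (fixture source for the ICA path)
# ---------------------------------------------------------------------------

def render_phantom_volumes(
    maps: np.ndarray,
    tcs: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
):
    """Mix spatial maps with timecourses into a 4-D phantom volume.

    volume[..., t] = sum_c maps[c] * tcs[c, t] + Gaussian noise. Returns
    a ``nibabel.Nifti1Image`` with unit affine, float32 data.
    """
    import nibabel as nib

    maps = np.asarray(maps, dtype=float)
    tcs = np.asarray(tcs, dtype=float)
    if maps.ndim != 4:
        raise ValueError("maps must be (components, x, y, z)")
    if tcs.ndim != 2 or tcs.shape[0] != maps.shape[0]:
        raise ValueError(
            f"component mismatch: {maps.shape[0]} maps vs {tcs.shape[0]} "
            "timecourses"
        )
    rng = np.random.default_rng(seed)
    vol = np.einsum("cxyz,ct->xyzt", maps, tcs)
    if noise_sd > 0:
        vol = vol + noise_sd * rng.standard_normal(vol.shape)
    return nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))


def default_cohort_config(**overrides) -> CohortConfig:
    """The shipped study conditions, with keyword overrides.

    ``separation="high"`` also lengthens dwell times (stickier chains)
    unless an explicit ``stickiness`` override is given, so that state
    runs are long relative to a 22-TR analysis window.
    """
    if overrides.get("separation") == "high":
        # the high-separation fixture also needs long dwells relative to
        # the 22-TR analysis window for state runs to be resolvable
        overrides.setdefault("stickiness", {"COPD": 0.985, "HC": 0.98})
    return CohortConfig(**overrides)
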