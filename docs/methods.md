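# Methods

`dfnckit` implements the standard static/dynamic functional network
connectivity (sFNC/dFNC) pipeline for resting-state fMRI component
timecourses, together with a generative cohort simulator that provides
ground truth for every stage. This note records the models, the
parameters that matter, and the design decisions taken where the
methodology leaves genuine choices open.

## The analysis model

**Group spatial ICA.** Multi-subject 4-D data are reduced by temporal
PCA per subject (default 120 dimensions; desk-scale fixtures use ~10),
concatenated, reduced again at the group level (default 100; either by
direct eigendecomposition or by subspace/power iteration — both span
the same subspace and are cross-checked against each other), whitened,
and decomposed by Infomax ICA: natural-gradient entropy maximisation
with a logistic nonlinearity,

    dW = lr * (I + (1 - 2 g(WX)) (WX)^T / n) W,   g(u) = 1/(1+e^-u).

The learning rate is annealed when successive updates turn by more than
60 degrees and halved (with a rollback) on divergence; the run stops
when the update norm falls below `tol` (1e-7). Plain, not extended,
Infomax: only super-Gaussian sources (sparse spatial maps) are
recoverable, which is what this application needs; purely Gaussian
subspaces are non-identifiable and surface as low stability indices.

**Stability selection (ICASSO-style).** Infomax is repeated from
`n_runs = 10` random starts (seed randomisation only — no bootstrap
resampling), the pooled run-components are clustered by average-linkage
agglomeration under dissimilarity 1 − |spatial correlation|, and each
cluster is represented by its centrotype. The quality index is mean
intra-cluster similarity minus mean extra-cluster similarity. Note that
even ideally converged runs leave a small nonzero extra-cluster
similarity, so the index approaches but never exactly reaches 1; the
result object exposes the intra and extra terms separately.

**Back-reconstruction.** Subject timecourses and maps come from
spatiotemporal (dual) regression by default — regress the subject data
on the group maps, then regress on the resulting timecourses. The PCA
de-whitening route (propagating the group mixing back through the
subject and group PCA bases) is selectable; on noiseless mixtures both
recover the truth up to scale, and both are tested.

**Component labelling.** A component is assigned to the
best-correlated template network only when the spatial correlation is
at least `r_threshold` (default 0.2), the fraction of its timecourse
periodogram power below 0.1 Hz is at least 0.5, and its peak-|z| voxel
falls inside the supplied mask; otherwise it is an artifact. The two
thresholds are package defaults: the selection criteria are standard
but no canonical numeric values exist. The gray-matter check is
deliberately reduced to "peak voxel inside a user-supplied mask" — no
tissue segmentation is in scope.

**Static FNC.** Pearson correlation between all component pairs over
the full scan, Fisher z-transformed (z = atanh r, with |r| clamped at
1 − 1e−6) before any inference. Group differences are tested edgewise
by OLS of z on intercept + group + age + education (sex excluded by
default, configurable), with Benjamini–Hochberg correction across the
C(21,2) = 210 edges at q = 0.01. With no nuisance covariates the edge
t reduces exactly to the pooled two-sample t (tested to 1e−10).

**Dynamic FNC.** Sliding-window correlation with a tapered window:
a rectangle of length 22 TRs convolved with a unit-area Gaussian
(sigma = 3 TRs, support ±4 sigma), truncated to the central 22 samples
and renormalised; step 1 TR. With T = 230 timepoints this yields 209
windows. Within each window the weighted Pearson correlation per pair
(weighted means/variances/covariance under the taper) is Fisher
z-transformed. No sparse-precision (graphical-lasso) regularisation is
applied: the plain weighted correlation keeps the estimator exactly
testable, at the cost of noisier windows than shrinkage methods give.

**Brain states.** All subjects' window vectors are pooled (a single
centroid set describes both groups) and clustered by k-means under the
cityblock distance — the dFNC convention; the centroid update is then
the componentwise median (mean under the Euclidean option). Best of
`n_init = 20` restarts by total within-cluster distance; empty clusters
are re-seeded from the farthest point; states are relabelled by
descending pooled occurrence with index tie-breaks, so state 1 is the
most visited. An optional two-stage path first clusters exemplar
windows (local maxima of across-edge variance per subject) and
initialises the full clustering from those centroids.

**Choosing k.** `select_k` computes, for each k in 2..8, the mean
silhouette under the clustering distance (on a seeded subsample of at
most 2000 windows — silhouette is O(n²)) and the gap statistic against
uniform references drawn in the PCA-aligned bounding box. The default
chooser is silhouette-argmax, with the classical gap 1-SE rule
selectable: at pooled-window scale (n ≈ 8000) the spread of the
reference log-dispersion collapses to ~1e−3, so the 1-SE inequality
never fires and the gap rule degenerates to the largest k; the gap rule
remains the criterion of choice for small fixtures and is the only one
defined when k = 1 is in range. A known limitation: the four shipped
state archetypes are hierarchical (one weak-global state against
strong states), and on roughly one cohort realisation in eight the
silhouette prefers the top-level 2- or 3-way split to the planted
4-state structure.

**Temporal metrics.** Per subject: fractional windows (share of
windows per state), mean dwell time (mean length of maximal
single-state runs, in windows; a seconds view is windows × step × TR),
and number of transitions. A state the subject never visits
contributes dwell 0 by default — keeping n = 19 per group in every
test, which matches the degrees of freedom of the published group
comparisons — with an "exclude missing" convention available.

**Inference.** Pooled-variance Student t by default (df = n1+n2−2;
Welch selectable), from raw values or from printed summary statistics
(mean ± SD, n) — the latter reproduces published t columns. Pearson
correlations carry two-sided p from the t transform; the clinical
correlation grid is restricted to the patient group and reports
unadjusted p with 0.05/0.01 flags (no multiplicity correction by
default, mirroring the usual presentation; BH is available). Per-state
edgewise group tests use two-sample t on subject state-mean z vectors
with BH within each state at q = 0.01; subjects lacking a state are
excluded from that state's tests.

## The generative model (simulator)

Each subject follows a hidden Markov chain over K = 4 connectivity
states; at each timepoint the 21-component vector is drawn zero-mean
multivariate normal with the active state's covariance. The chain for
each group is `P = s·I + (1−s)·1 wᵀ`, which has stationary
distribution exactly `w` and mean dwell increasing in the stickiness
`s`. Defaults mirror the study conditions: 19 subjects per group,
T = 230 at TR = 2 s, patient occupancy (0.55, 0.10, 0.07, 0.28) vs
control (0.26, 0.22, 0.16, 0.36) — pooled ≈ 40/16/11/32% — with
stickiness 0.97/0.95 giving State-1 dwells of roughly 70/25 TRs,
consistent with the published dwell times. The Markov model is
generator bookkeeping only; the analysis side never fits an HMM.

**State covariances.** Unit-diagonal block correlation matrices built
from within-network and between-network coupling levels on the
1+5+5+2+2+2+4 partition (AN, DMN, ECN, LN, SMN, SN, VN). The four
archetypes: State 1 weak-global (0.1 within / 0.05 between); State 2
strong-within, sensory-dominant and globally integrated; State 3
strong-within, association-dominant and segregated (negative between);
State 4 positively coupled DMN+VN block over a weak background. The
heterogeneous within-levels are deliberate: uniform two-level block
matrices are all perfectly collinear as edge vectors, which would make
correlation-based centroid-truth matching ill-posed. Non-PSD drafts
(strongly negative between-couplings) are repaired by eigenvalue
clipping and re-normalisation; the repaired matrix is the stored truth.

**Separation settings.** `separation="default"` uses the levels above
(hi 0.7 / mid 0.4 / between ±0.2). `separation="high"` is the
verification fixture for clustering recovery: hi 0.85 / mid 0.5 /
between ±0.45, State 1 raised to 0.25/0.08, and stickiness 0.985/0.98
so that runs are long relative to the 22-TR window. Two facts motivate
the stronger State 1 and dwells: (i) at the default 0.1/0.05 amplitude
the State-1 pattern spread (~0.02 in z) is comparable to the centroid
noise floor (~0.025) fixed by T, the window length and occupancy, so no
estimator can recover it to 0.9 correlation; (ii) assigning windows to
the *true* centroids yields the same ARI as k-means, i.e. recovery is
limited by windows straddling transitions, not by the clustering.

**Clinical covariates.** Group-specific normal marginals matching the
published demographic table (FEV1 46.1±20.6 vs 97.1±16.6 % predicted,
etc.; CRP and pH, unreported there, use plausible clinical values).
FEV1 and FEV1/FVC (negatively) and CRP (positively) are linear in the
subject's true State-1 occupancy plus Gaussian noise, scaled so the
cohort-level R² equals `coupling_r2` (default 0.25, matching the
r ≈ ±0.5 of the published correlation table); other couplings are
configurable. Sex is a matched 14M/5F split in both groups.

**What the simulator does not emulate** — hemodynamics, physiological
noise spectra, head motion, scanner drift, spatial structure (except in
the small blob phantoms used for the ICA path). Passing recovery tests
therefore demonstrates the correctness of the estimators under the
stated generative model, not robustness to real-data artefacts.
Temporal smoothing (`hrf_smoothing`) is available but off by default
because it mixes adjacent states and weakens instantaneous-covariance
fidelity.

## Numerical choices and degenerate inputs

- Fisher clamp 1e−6 before atanh; z-scale diagonals set to 0.
- Zero-variance components raise a named error in static FNC; a
  zero-weighted-variance *window* zeroes the affected edges with a
  warning (one dead window should not abort a subject).
- Confound regression always includes an intercept and reports the
  offending columns on rank deficiency.
- k-means ties and empty clusters: farthest-point reseeding;
  deterministic given the seed. All randomness in the package flows
  from explicit seeds fanned out through `numpy.random.SeedSequence`.
- Sequences of single-timepoint state runs trigger an
  unsupported-resolution warning (windows cannot resolve them).
- Monte-Carlo test claims use ±2 MC-standard-deviation envelopes with
  fixed seed ensembles.

## Problem sizes

Desk-scale fixtures keep the suite fast while preserving the study
geometry where it matters: the full 38-subject, 21-component, 230-TR
cohort is used for state recovery (7942 pooled windows); the ICA
phantom uses a 12×12×6 grid, 5 components, 150 timepoints, 4 subjects
at SNR 5; seed ensembles use 100 cohorts for power claims, 300 for
null calibration, and 500 for FDR control.
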