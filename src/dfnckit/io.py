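"""On-disk formats: cohort trees, clinical tables, state-model archives.

Everything round-trips through plain text: per-subject timecourses and
all result tables as tab-separated values, manifests and archives as
YAML. Phantom volumes go through NIfTI (nibabel) at float32 precision.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import MarkovModel, SimulatedCohort, StateCovarianceSet
from .dynamics import StateModel
from .sfnc import ComponentTimecourses

ARCHIVE_VERSION = 1


def load_masked_volume(path: str | Path, mask: np.ndarray) -> np.ndarray:
    """Load a 4-D NIfTI as a voxels-by-timepoints matrix under a mask."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got {data.ndim}-D")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"{path}: mask shape {mask.shape} != volume grid {data.shape[:3]}"
        )
    return data[mask, :]


def save_maps_nifti(
    maps: np.ndarray, mask: np.ndarray, path: str | Path
) -> None:
    """Write component maps (components x masked voxels) as a 4-D NIfTI."""
    import nibabel as nib

    mask = np.asarray(mask, dtype=bool)
    vol = np.zeros((*mask.shape, maps.shape[0]), dtype=np.float32)
    for c in range(maps.shape[0]):
        frame = np.zeros(mask.shape, dtype=np.float32)
        frame[mask] = maps[c]
        vol[..., c] = frame
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


class CorruptArchiveError(RuntimeError):
    """An archive is incomplete, truncated, or from another version."""


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# timecourses
# ---------------------------------------------------------------------------

def write_timecourses(tc: ComponentTimecourses, path: str | Path) -> None:
    """Rows = components, columns = timepoints (header of indices)."""
    df = pd.DataFrame(tc.data, columns=np.arange(tc.n_timepoints))
    df.index.name = "component"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_timecourses(
    path: str | Path, subject_id: str | None = None, tr: float = 2.0,
    labels: tuple[str, ...] | None = None,
) -> ComponentTimecourses:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ComponentTimecourses(
        subject_id=subject_id or Path(path).stem,
        data=df.to_numpy(dtype=float), tr=tr, labels=labels,
    )


# ---------------------------------------------------------------------------
# cohort tree
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> Path:
    """Write a cohort: subject files, manifest, clinical table, truth.

    Layout: ``timecourses/<subject>.tsv``, ``manifest.yaml``,
    ``clinical.tsv``, ``truth/`` (state covariances, Markov models,
    per-subject true state sequences).
    """
    out = Path(out_dir)
    (out / "timecourses").mkdir(parents=True, exist_ok=True)
    truth = out / "truth"
    truth.mkdir(exist_ok=True)

    for tc in cohort.subjects:
        write_timecourses(tc, out / "timecourses" / f"{tc.subject_id}.tsv")
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t",
                           float_format="%.10g")

    manifest = {
        "version": ARCHIVE_VERSION,
        "seed": int(cohort.seed),
        "tr": float(cohort.config.tr),
        "n_timepoints": int(cohort.config.n_timepoints),
        "component_labels": list(
            cohort.config.partition.component_labels()),
        "subjects": {
            tc.subject_id: str(cohort.groups[tc.subject_id])
            for tc in cohort.subjects
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    covs = cohort.state_covariances
    truth_meta = {
        "version": ARCHIVE_VERSION,
        "state_labels": list(covs.labels),
        "archetypes": list(covs.archetypes),
        "markov": {
            g: {
                "transition": m.transition.tolist(),
                "initial": m.initial.tolist(),
            }
            for g, m in cohort.markov_models.items()
        },
    }
    with open(truth / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth_meta, fh, sort_keys=True)
    for i, lab in enumerate(covs.labels):
        np.savetxt(truth / f"cov_{lab}.tsv", covs.matrices[i],
                   delimiter="\t", fmt="%.10g")
    for sid, seq in cohort.true_sequences.items():
        np.savetxt(truth / f"sequence_{sid}.txt", seq, fmt="%d")
    return out


def read_cohort_timecourses(
    cohort_dir: str | Path,
) -> tuple[list[ComponentTimecourses], pd.Series, pd.DataFrame, dict]:
    """Read back (subjects, groups, clinical table, manifest)."""
    root = Path(cohort_dir)
    mf = root / "manifest.yaml"
    if not mf.exists():
        raise CorruptArchiveError(f"no manifest.yaml under {root}")
    with open(mf) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "subjects" not in manifest:
        raise CorruptArchiveError("manifest.yaml is malformed")
    if manifest.get("version") != ARCHIVE_VERSION:
        raise CorruptArchiveError(
            f"archive version {manifest.get('version')} != {ARCHIVE_VERSION}"
        )
    labels = tuple(manifest.get("component_labels") or ()) or None
    tr = float(manifest["tr"])
    subjects, group_map = [], {}
    for sid, grp in manifest["subjects"].items():
        path = root / "timecourses" / f"{sid}.tsv"
        if not path.exists():
            raise CorruptArchiveError(f"missing timecourse file for {sid}")
        try:
            subjects.append(read_timecourses(path, subject_id=sid, tr=tr,
                                             labels=labels))
        except ValueError as exc:
            raise CorruptArchiveError(f"{sid}: {exc}") from exc
        group_map[sid] = grp
    n_comp = {tc.n_components for tc in subjects}
    if len(n_comp) > 1:
        raise CorruptArchiveError(
            f"component counts differ across subjects: {sorted(n_comp)}"
        )
    clinical = pd.read_csv(root / "clinical.tsv", sep="\t",
                           index_col="subject")
    return subjects, pd.Series(group_map, name="group"), clinical, manifest


def read_truth(cohort_dir: str | Path) -> dict:
    """Read the truth archive: sequences, covariances, Markov models."""
    truth = Path(cohort_dir) / "truth"
    meta_path = truth / "truth.yaml"
    if not meta_path.exists():
        raise CorruptArchiveError(f"no truth archive under {truth}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "state_labels" not in meta:
        raise CorruptArchiveError("truth.yaml is malformed")
    mats = []
    for lab in meta["state_labels"]:
        p = truth / f"cov_{lab}.tsv"
        if not p.exists():
            raise CorruptArchiveError(f"missing covariance file for {lab}")
        mats.append(np.loadtxt(p, delimiter="\t"))
    covset = StateCovarianceSet(
        labels=tuple(meta["state_labels"]),
        matrices=np.stack(mats),
        archetypes=tuple(meta["archetypes"]),
    )
    models = {
        g: MarkovModel(np.asarray(d["transition"]), np.asarray(d["initial"]))
        for g, d in meta["markov"].items()
    }
    sequences = {
        p.stem.removeprefix("sequence_"): np.loadtxt(p, dtype=np.int64)
        for p in sorted(truth.glob("sequence_*.txt"))
    }
    return {"state_covariances": covset, "markov_models": models,
            "sequences": sequences}


# ---------------------------------------------------------------------------
# state-model archive
# ---------------------------------------------------------------------------

def write_state_model(model: StateModel, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": ARCHIVE_VERSION,
        "k": int(model.k),
        "metric": model.metric,
        "seed": int(model.seed),
        "inertia": float(model.inertia),
        "occurrence": [float(v) for v in model.occurrence],
        "subjects": list(model.assignments),
    }
    with open(out / "state_model.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    np.savetxt(out / "centroids.tsv", model.centroids, delimiter="\t",
               fmt="%.10g")
    for sid, a in model.assignments.items():
        np.savetxt(out / f"assignments_{sid}.txt", a, fmt="%d")
    if model.diagnostics is not None:
        model.diagnostics.to_csv(out / "k_diagnostics.tsv", sep="\t",
                                 index=False)
    return out


def read_state_model(out_dir: str | Path) -> StateModel:
    out = Path(out_dir)
    meta_path = out / "state_model.yaml"
    if not meta_path.exists():
        raise CorruptArchiveError(f"no state_model.yaml under {out}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "k" not in meta:
        raise CorruptArchiveError("state_model.yaml is malformed")
    if meta.get("version") != ARCHIVE_VERSION:
        raise CorruptArchiveError(
            f"archive version {meta.get('version')} != {ARCHIVE_VERSION}"
        )
    centroids = np.atleast_2d(np.loadtxt(out / "centroids.tsv",
                                         delimiter="\t"))
    if centroids.shape[0] != meta["k"]:
        raise CorruptArchiveError(
            f"centroid rows ({centroids.shape[0]}) != k ({meta['k']})"
        )
    assignments = {}
    for sid in meta["subjects"]:
        p = out / f"assignments_{sid}.txt"
        if not p.exists():
            raise CorruptArchiveError(f"missing assignments for {sid}")
        assignments[sid] = np.atleast_1d(np.loadtxt(p, dtype=np.int64))
    diag_path = out / "k_diagnostics.tsv"
    diagnostics = (pd.read_csv(diag_path, sep="\t")
                   if diag_path.exists() else None)
    return StateModel(
        k=int(meta["k"]), centroids=centroids, assignments=assignments,
        occurrence=np.asarray(meta["occurrence"], dtype=float),
        metric=meta["metric"], seed=int(meta["seed"]),
        inertia=float(meta["inertia"]), diagnostics=diagnostics,
    )
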