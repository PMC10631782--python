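"""NIfTI / TSV / YAML input-output.

Runs are stored as 4D NIfTI-1 images with a 3D brain mask; masked voxels
are (un)raveled in scan order with x fastest (Fortran order), recorded in
the description header field. Synthetic cohorts pack their voxels into the
smallest cube holding ``n_voxels``. Tabular outputs are TSV with a header
row and ``NA`` for missing values.
"""

from __future__ import annotations

import math
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import BoldRun, StateSequence, SyntheticCohort, ValidationError

__all__ = [
    "read_bold",
    "write_bold",
    "write_mask",
    "read_mask",
    "voxel_grid",
    "write_cohort",
    "read_cohort_dir",
    "write_tsv",
    "read_tsv",
]

NA = "NA"


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.10g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA])


def voxel_grid(n_voxels: int) -> tuple[int, int, int]:
    """Smallest cube grid holding n_voxels."""
    side = math.ceil(n_voxels ** (1.0 / 3.0))
    while side**3 < n_voxels:  # guard against fp roundoff
        side += 1
    return (side, side, side)


def _flat_mask(mask3d: np.ndarray) -> np.ndarray:
    """Boolean mask flattened in x-fastest (Fortran) scan order."""
    return np.asarray(mask3d, dtype=bool).ravel(order="F")


def read_mask(path: str | Path) -> tuple[np.ndarray, nib.Nifti1Image]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"mask {path} must be 3-D, got {data.ndim}-D")
    return data > 0, img


def write_mask(mask3d: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(
        np.asarray(mask3d, dtype=np.uint8), affine if affine is not None else np.eye(4)
    )
    img.header["descrip"] = b"capdyn mask; voxel order x-fastest"
    nib.save(img, str(path))


def read_bold(
    path: str | Path,
    mask_path: str | Path,
    *,
    tr_override: float | None = None,
    subject_id: str | None = None,
    band_tag: str = "unfiltered",
) -> BoldRun:
    """Load a 4D NIfTI run and extract the masked voxel x time matrix.

    TR is taken from the header (pixdim[4]); a nonpositive header TR
    without ``tr_override`` is an error. Non-finite values inside the mask
    are rejected with their count.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise ValidationError(f"{path} must be 4-D (x, y, z, t), got {data.ndim}-D")
    mask, mimg = read_mask(mask_path)
    if mask.shape != data.shape[:3]:
        raise ValidationError(
            f"grid mismatch: bold {data.shape[:3]} vs mask {mask.shape}"
        )
    n_frames = data.shape[3]
    flat = data.reshape((-1, n_frames), order="F")
    series = flat[_flat_mask(mask)]
    n_bad = int((~np.isfinite(series)).sum())
    if n_bad:
        raise ValidationError(
            f"{path}: {n_bad} non-finite values inside the mask"
        )
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_override is not None:
        tr = float(tr_override)
    if tr <= 0:
        raise ValidationError(
            f"{path}: header TR is {tr}; supply a TR override"
        )
    sid = subject_id if subject_id is not None else Path(path).name.split(".")[0]
    return BoldRun(data=series, tr=tr, subject_id=sid, band_tag=band_tag)


def write_bold(run: BoldRun, mask3d: np.ndarray, path: str | Path) -> None:
    """Write a masked run back onto its 3D grid as 4D NIfTI-1.

    Voxels outside the mask are zero. The header stores TR in pixdim[4].
    """
    mask3d = np.asarray(mask3d, dtype=bool)
    flat_mask = _flat_mask(mask3d)
    if int(flat_mask.sum()) != run.n_voxels:
        raise ValidationError(
            f"mask has {int(flat_mask.sum())} voxels, run has {run.n_voxels}"
        )
    vol = np.zeros((flat_mask.size, run.n_frames))
    vol[flat_mask] = run.data
    arr = vol.reshape(mask3d.shape + (run.n_frames,), order="F")
    img = nib.Nifti1Image(arr.astype(np.float32), np.eye(4))
    zooms = list(img.header.get_zooms())
    zooms[3] = run.tr
    img.header.set_zooms(zooms)
    img.header["descrip"] = f"capdyn {run.band_tag}; x-fastest".encode()
    nib.save(img, str(path))


def write_maps_nifti(
    maps: np.ndarray, mask3d: np.ndarray, path: str | Path
) -> None:
    """Write k spatial maps (k, n_voxels) as a 4D NIfTI (one volume per CAP)."""
    mask3d = np.asarray(mask3d, dtype=bool)
    flat_mask = _flat_mask(mask3d)
    k = maps.shape[0]
    vol = np.zeros((flat_mask.size, k))
    vol[flat_mask] = maps.T
    arr = vol.reshape(mask3d.shape + (k,), order="F")
    img = nib.Nifti1Image(arr.astype(np.float32), np.eye(4))
    img.header["descrip"] = b"capdyn CAP maps; volume = CAP number"
    nib.save(img, str(path))


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort to disk (NIfTI runs + mask, TSV tables, YAML).

    Layout: ``mask.nii``, ``<subject>_bold.nii`` per subject,
    ``phenotypes.tsv``, ``ground_truth_sequences.tsv`` (long format),
    ``cohort_config.yaml`` (scalar ground truth; templates and transition
    matrices as nested lists).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    grid = voxel_grid(cfg.n_voxels)
    mask = np.zeros(grid, dtype=bool)
    mask_flat = np.zeros(int(np.prod(grid)), dtype=bool)
    mask_flat[: cfg.n_voxels] = True
    mask = mask_flat.reshape(grid, order="F")
    paths: dict[str, Path] = {}
    write_mask(mask, outdir / "mask.nii")
    paths["mask"] = outdir / "mask.nii"
    for run in cohort.runs:
        p = outdir / f"{run.subject_id}_bold.nii"
        write_bold(run, mask, p)
        paths[run.subject_id] = p
    write_tsv(cohort.phenotypes, outdir / "phenotypes.tsv")
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    seq_rows = []
    for seq in cohort.ground_truth_sequences:
        for t, lab in enumerate(seq.labels, start=1):
            seq_rows.append({"subject_id": seq.subject_id, "frame": t, "state": int(lab)})
    write_tsv(pd.DataFrame(seq_rows), outdir / "ground_truth_sequences.tsv")
    paths["sequences"] = outdir / "ground_truth_sequences.tsv"
    meta = {
        "n_subjects_per_group": dict(cfg.n_subjects_per_group),
        "k_true": int(cfg.k_true),
        "n_voxels": int(cfg.n_voxels),
        "n_frames": int(cfg.n_frames),
        "tr": float(cfg.tr),
        "noise_sd": float(cfg.noise_sd),
        "seed": int(cfg.seed),
        "score_model": {
            "intercept": float(cfg.score_model.intercept),
            "coefficients": [float(c) for c in cfg.score_model.coefficients],
            "residual_sd": float(cfg.score_model.residual_sd),
        },
        "transition_by_group": {
            g: [[float(x) for x in row] for row in p]
            for g, p in cfg.transition_by_group.items()
        },
    }
    with open(outdir / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    paths["config"] = outdir / "cohort_config.yaml"
    return paths


def read_cohort_dir(
    indir: str | Path, *, tr_override: float | None = None
) -> tuple[list[BoldRun], pd.DataFrame, np.ndarray]:
    """Read a cohort directory (as written by :func:`write_cohort`).

    Returns (runs in phenotype order, phenotype table, 3D mask array).
    """
    indir = Path(indir)
    phen = read_tsv(indir / "phenotypes.tsv")
    if phen["subject_id"].duplicated().any():
        raise ValidationError("duplicate subject ids in phenotypes.tsv")
    mask, _ = read_mask(indir / "mask.nii")
    runs = []
    for sid in phen["subject_id"]:
        p = indir / f"{sid}_bold.nii"
        if not p.exists():
            raise ValidationError(f"missing BOLD file for subject {sid}: {p}")
        runs.append(
            read_bold(p, indir / "mask.nii", tr_override=tr_override, subject_id=str(sid))
        )
    return runs, phen, mask


def read_sequences_tsv(path: str | Path, tr: float = 3.0) -> list[StateSequence]:
    """Read long-format (subject_id, frame, state) sequences."""
    df = read_tsv(path)
    seqs = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("frame")
        seqs.append(StateSequence(subject_id=str(sid), labels=grp["state"].to_numpy(), tr=tr))
    return seqs
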