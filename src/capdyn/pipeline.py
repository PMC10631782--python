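"""End-to-end orchestration: filter -> cluster -> dynamics -> statistics.

``run_pipeline`` consumes a cohort directory (4D NIfTI runs + mask +
phenotype TSV), processes each frequency band independently — temporal
filtering, frame-matrix construction, exemplar selection, optional
silhouette scan over k, two-stage CAP clustering, control-ordered CAP
numbering, dynamic metrics, group tests and MMSE correlations — then
correlates CAP maps across every band pair. All outputs are TSV/NIfTI in
the output directory, the run is deterministic given the seed, and a JSON
log records the seed, configuration hash and package versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cap import (
    CapClustering,
    assignments_to_sequences,
    build_frame_matrix,
    fit_cap_model,
    order_caps,
    select_exemplars,
    select_k,
)
from .dynamics import compute_state_metrics, metrics_table, transitions_table
from .filtering import preprocess_run
from .io import (
    read_cohort_dir,
    read_tsv,
    write_maps_nifti,
    write_tsv,
)
from .stats import (
    METRIC_COLUMNS,
    anova_from_summary,
    chi_square_2x2,
    compare_groups,
    correlate_with_score,
    cross_band_correlation,
)
from .types import FrequencyBand, ValidationError

logger = logging.getLogger("capdyn")

__all__ = ["PipelineConfig", "run_pipeline", "demographics_table"]


@dataclass
class PipelineConfig:
    """Full pipeline configuration with the canonical defaults.

    ``k`` fixes the number of CAPs; if ``k`` is None the silhouette scan
    over ``k_range`` picks it. When both are set the fixed ``k`` wins and
    a warning is logged.
    """

    input_dir: str = "."
    output_dir: str = "capdyn_out"
    bands: list[tuple[str, float, float]] = field(
        default_factory=lambda: [
            ("LFO", 0.01, 0.1),
            ("slow5", 0.01, 0.027),
            ("slow4", 0.027, 0.073),
        ]
    )
    tr: float | None = None  # None: trust the NIfTI headers
    k: int | None = 7
    k_range: list[int] | None = None
    n_restarts: int = 500
    seed: int = 0
    exemplar_min: int = 10
    exemplar_max: int = 15
    z_threshold: float = 1.5
    frame_norm: str = "zscore"
    nuisance_path: str | None = None
    nuisance_stage: str = "after_filter"
    filter_method: str = "butterworth"
    include_self_transitions: bool = True
    welch: bool = False
    chi_square_correction: bool = False
    fdr: bool = False
    group_labels: tuple[str, str] = ("AD", "NC")
    control_group: str = "NC"
    skip_filtering: bool = False

    def __post_init__(self) -> None:
        if self.k is None and not self.k_range:
            raise ValidationError("either k or k_range must be set")
        if self.frame_norm not in ("zscore", "none"):
            raise ValidationError(f"bad frame_norm {self.frame_norm!r}")
        for name, low, high in self.bands:
            FrequencyBand(name, low, high)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "bands" in raw:
            raw["bands"] = [tuple(b) for b in raw["bands"]]
        if "group_labels" in raw:
            raw["group_labels"] = tuple(raw["group_labels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        d["group_labels"] = list(self.group_labels)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def demographics_table(
    phenotypes: pd.DataFrame,
    groups: tuple[str, str] = ("AD", "NC"),
    *,
    chi_square_correction: bool = False,
) -> pd.DataFrame:
    """Table-1-style demographics: sex chi-square, age ANOVA, score means."""
    ga, gb = groups
    a = phenotypes[phenotypes["group"] == ga]
    b = phenotypes[phenotypes["group"] == gb]
    rows = []
    sex_table = np.array(
        [
            [(a["sex"] == "F").sum(), (a["sex"] == "M").sum()],
            [(b["sex"] == "F").sum(), (b["sex"] == "M").sum()],
        ]
    )
    try:
        chi2, p_sex = chi_square_2x2(sex_table, correction=chi_square_correction)
    except ValidationError:  # zero margin in a tiny cohort: untestable
        chi2, p_sex = np.nan, np.nan
    rows.append(
        {
            "variable": "sex_F/M",
            ga: f"{sex_table[0, 0]}/{sex_table[0, 1]}",
            gb: f"{sex_table[1, 0]}/{sex_table[1, 1]}",
            "statistic": chi2,
            "p": p_sex,
        }
    )
    for col in ("age", "MMSE", "CDR"):
        if col not in phenotypes.columns:
            continue
        means = [a[col].mean(), b[col].mean()]
        ses = [
            a[col].std(ddof=1) / np.sqrt(len(a)),
            b[col].std(ddof=1) / np.sqrt(len(b)),
        ]
        if min(ses) > 0:
            f, p = anova_from_summary(means, ses, [len(a), len(b)])
        else:
            f, p = np.nan, np.nan
        rows.append(
            {
                "variable": col,
                ga: f"{means[0]:.2f} +/- {ses[0]:.2f}",
                gb: f"{means[1]:.2f} +/- {ses[1]:.2f}",
                "statistic": f,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _fit_band(
    runs,
    band: FrequencyBand | None,
    config: PipelineConfig,
    mask3d,
    outdir: Path,
    nc_ids,
    regressors,
):
    """Process one band end to end; returns (model, metrics list)."""
    tag = band.name if band is not None else "unfiltered"
    if band is not None:
        runs = [
            preprocess_run(
                r,
                band,
                regressors,
                nuisance_stage=config.nuisance_stage,
                method=config.filter_method,
            )
            for r in runs
        ]
    fm = build_frame_matrix(runs, frame_norm=config.frame_norm)
    exemplars = [
        select_exemplars(r, config.exemplar_min, config.exemplar_max) for r in runs
    ]
    k = config.k
    sil: dict[int, float] = {}
    if config.k is not None and config.k_range:
        logger.warning("both k and k_range set; fixed k=%d wins", config.k)
    if config.k is None:
        k, sil = select_k(
            fm, exemplars, config.k_range, n_restarts=min(config.n_restarts, 100),
            seed=config.seed,
        )
        logger.info("band %s: silhouette selected k=%d", tag, k)
    model = fit_cap_model(
        fm, exemplars, k, n_restarts=config.n_restarts, seed=config.seed,
        z_threshold=config.z_threshold,
    )
    model.silhouette_by_k_ = sil
    order_caps(model, nc_ids)
    tr = runs[0].tr
    seqs = assignments_to_sequences(model, tr=tr)
    metrics = [compute_state_metrics(s, k) for s in seqs]

    write_maps_nifti(model.centroids_, mask3d, outdir / f"caps_centroid_{tag}.nii")
    write_maps_nifti(model.zmaps_, mask3d, outdir / f"caps_zmap_{tag}.nii")
    write_maps_nifti(
        model.thresholded_maps_, mask3d, outdir / f"caps_thresholded_{tag}.nii"
    )
    write_tsv(model.assignments_, outdir / f"assignments_{tag}.tsv")
    if sil:
        write_tsv(
            pd.DataFrame(
                {"k": list(sil), "mean_silhouette": [sil[kk] for kk in sil]}
            ),
            outdir / f"silhouette_{tag}.tsv",
        )
    mt = metrics_table(metrics)
    write_tsv(mt, outdir / f"metrics_{tag}.tsv")
    write_tsv(transitions_table(metrics), outdir / f"transitions_{tag}.tsv")
    return model, mt


def _score_correlations(
    mt: pd.DataFrame, phenotypes: pd.DataFrame, tag: str
) -> pd.DataFrame:
    """Pearson correlation of each (cap, metric) with the MMSE score."""
    merged = mt.merge(phenotypes[["subject_id", "MMSE"]], on="subject_id")
    rows = []
    for (cap, metric), grp in (
        merged.melt(
            id_vars=["subject_id", "cap", "MMSE"],
            value_vars=[m for m in METRIC_COLUMNS if m in merged.columns],
            var_name="metric",
        )
        .groupby(["cap", "metric"], sort=True)
    ):
        x = grp["value"].to_numpy(float)
        y = grp["MMSE"].to_numpy(float)
        keep = np.isfinite(x) & np.isfinite(y)
        if keep.sum() < 3 or x[keep].std() == 0 or y[keep].std() == 0:
            r, p = np.nan, np.nan
        else:
            r, p = correlate_with_score(x[keep], y[keep])
        rows.append(
            {"band": tag, "cap": cap, "metric": metric, "r": r, "p": p,
             "significant": bool(p < 0.05) if np.isfinite(p) else False}
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full multiband analysis; returns a summary dict.

    Any stage failure aborts with a stage-named error; outputs written up
    to that point are retained alongside a ``FAILED_<stage>`` marker file.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    hash_file = outdir / "config_hash.txt"
    chash = config.hash()
    if hash_file.exists():
        old = hash_file.read_text().strip()
        if old != chash:
            raise ValidationError(
                f"output dir {outdir} holds results for config {old}; "
                f"refusing to overwrite with config {chash}"
            )
    hash_file.write_text(chash + "\n")

    stage = "load"
    try:
        runs, phenotypes, mask3d = read_cohort_dir(
            config.input_dir, tr_override=config.tr
        )
        regressors = None
        if config.nuisance_path:
            regressors = read_tsv(config.nuisance_path).to_numpy(float)
        nc_ids = phenotypes.loc[
            phenotypes["group"] == config.control_group, "subject_id"
        ].tolist()
        if not nc_ids:
            raise ValidationError(
                f"no subjects in control group {config.control_group!r}"
            )

        stage = "demographics"
        demo = demographics_table(
            phenotypes, config.group_labels,
            chi_square_correction=config.chi_square_correction,
        )
        write_tsv(demo, outdir / "demographics.tsv")

        bands: list[FrequencyBand | None]
        if config.skip_filtering:
            bands = [None]
        else:
            bands = [FrequencyBand(*b) for b in config.bands]
        models: dict[str, CapClustering] = {}
        summary: dict = {"config_hash": chash, "bands": {}}
        for band in bands:
            tag = band.name if band is not None else "unfiltered"
            stage = f"band:{tag}"
            model, mt = _fit_band(
                runs, band, config, mask3d, outdir, nc_ids, regressors
            )
            models[tag] = model
            stage = f"stats:{tag}"
            gt = compare_groups(
                mt, phenotypes, groups=config.group_labels,
                welch=config.welch, fdr=config.fdr,
            )
            write_tsv(gt, outdir / f"stats_{tag}.tsv")
            sc = _score_correlations(mt, phenotypes, tag)
            write_tsv(sc, outdir / f"mmse_correlations_{tag}.tsv")
            summary["bands"][tag] = {
                "k": model.k,
                "inertia": model.inertia_,
                "n_significant_group_tests": int(gt["significant"].sum()),
                "n_significant_mmse_correlations": int(sc["significant"].sum()),
            }

        stage = "crossband"
        for ta, tb in combinations(models, 2):
            cb = cross_band_correlation(models[ta], models[tb])
            rows = [
                {"cap_a": i + 1, "cap_b": j + 1, "r": cb.r[i, j],
                 "matched": int(cb.matching[i] == j) if i < cb.matching.size else 0}
                for i in range(cb.r.shape[0])
                for j in range(cb.r.shape[1])
            ]
            write_tsv(pd.DataFrame(rows), outdir / f"crossband_{ta}_{tb}.tsv")
            summary.setdefault("crossband", {})[f"{ta}_{tb}"] = {
                "mean_matched_r": float(np.mean(cb.matched_r)),
            }

        stage = "log"
        summary["seed"] = config.seed
        summary["runtime_s"] = round(time.time() - t0, 2)
        summary["versions"] = {"capdyn": __version__, "numpy": np.__version__}
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        (outdir / f"FAILED_{stage.replace(':', '_')}").write_text(str(exc) + "\n")
        if isinstance(exc, ValidationError):
            raise ValidationError(f"[stage {stage}] {exc}") from exc
        raise RuntimeError(f"[stage {stage}] {exc}") from exc
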