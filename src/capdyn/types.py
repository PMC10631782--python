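"""Core containers for CAP analysis.

Conventions used throughout the package:

* A BOLD run is stored voxel-major: ``data`` has shape ``(n_voxels,
  n_frames)``; a single frame is a column.
* Frame matrices (clustering input) are frame-major: shape
  ``(n_frames_total, n_voxels)``; a single frame is a row.
* Frame numbers and CAP/state labels are 1-based in every public
  container, matching the CAP-1..CAP-7 convention of the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


BAND_TAGS = ("unfiltered", "LFO", "slow4", "slow5")


@dataclass
class BoldRun:
    """One subject's masked voxel x time matrix.

    Parameters
    ----------
    data : ndarray, shape (n_voxels, n_frames)
        Masked BOLD time series, one row per voxel.
    tr : float
        Repetition time in seconds (sampling interval between frames).
    subject_id : str
        Stable identifier; propagated into every downstream table.
    band_tag : str
        One of ``unfiltered``, ``LFO``, ``slow4``, ``slow5``.
    """

    data: np.ndarray
    tr: float
    subject_id: str
    band_tag: str = "unfiltered"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("BoldRun.data must be 2-D (voxels x time)")
        n, t = self.data.shape
        if n < 1 or t < 2:
            raise ValidationError(
                f"BoldRun needs >= 1 voxel and >= 2 frames, got {n} x {t}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("BoldRun.data contains non-finite values")
        if not (self.tr > 0):
            raise ValidationError(f"TR must be positive, got {self.tr}")
        if self.band_tag not in BAND_TAGS:
            raise ValidationError(
                f"band_tag must be one of {BAND_TAGS}, got {self.band_tag!r}"
            )

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, band_tag: str | None = None) -> "BoldRun":
        """Return a copy carrying new data (and optionally a new band tag)."""
        return BoldRun(
            data=data,
            tr=self.tr,
            subject_id=self.subject_id,
            band_tag=self.band_tag if band_tag is None else band_tag,
        )


@dataclass
class FrequencyBand:
    """A BOLD analysis band with inclusive edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValidationError(
                f"band requires 0 < low < high, got ({self.low_hz}, {self.high_hz})"
            )

    def validate_for_tr(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if self.high_hz > nyquist + 1e-12:
            raise ValidationError(
                f"band {self.name} high edge {self.high_hz} Hz exceeds "
                f"Nyquist {nyquist:.4f} Hz at TR={tr}s"
            )


#: The three canonical analysis bands. Slow-5 and slow-4 partition the
#: classical low-frequency-oscillation (LFO) range of the BOLD signal.
CANONICAL_BANDS: dict[str, FrequencyBand] = {
    "LFO": FrequencyBand("LFO", 0.01, 0.1),
    "slow5": FrequencyBand("slow5", 0.01, 0.027),
    "slow4": FrequencyBand("slow4", 0.027, 0.073),
}


@dataclass
class StateSequence:
    """Per-frame CAP/state labels (1-based) for one subject in one band."""

    subject_id: str
    labels: np.ndarray
    tr: float = 3.0
    band_tag: str = "unfiltered"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValidationError("labels must be a non-empty 1-D vector")
        if np.any(self.labels < 1):
            raise ValidationError("state labels are 1-based; found label < 1")

    @property
    def n_frames(self) -> int:
        return self.labels.size


@dataclass
class FrameMatrix:
    """All subjects' frames stacked row-wise for clustering.

    ``frame_index`` has one row per frame with columns ``subject_id`` and
    ``frame`` (1-based within-subject frame number).
    """

    frames: np.ndarray
    frame_index: pd.DataFrame
    band_tag: str = "unfiltered"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValidationError("frames must be 2-D (frames x voxels)")
        if len(self.frame_index) != self.frames.shape[0]:
            raise ValidationError("frame_index length must match frame count")
        required = {"subject_id", "frame"}
        if not required.issubset(self.frame_index.columns):
            raise ValidationError(f"frame_index must have columns {required}")

    @property
    def n_voxels(self) -> int:
        return self.frames.shape[1]

    def rows_for(self, subject_id: str, frame_numbers: np.ndarray) -> np.ndarray:
        """Global row indices of the given 1-based frames of one subject."""
        mask = self.frame_index["subject_id"].to_numpy() == subject_id
        rows = np.flatnonzero(mask)
        frames = self.frame_index["frame"].to_numpy()[rows]
        lookup = {f: r for f, r in zip(frames, rows)}
        try:
            return np.array([lookup[f] for f in np.asarray(frame_numbers)])
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(
                f"frame {exc.args[0]} of subject {subject_id} not in matrix"
            ) from None


@dataclass
class ExemplarSet:
    """High-variance frames of one run used to seed clustering.

    ``frame_numbers`` are sorted 1-based indices; ``is_padding`` flags
    frames added (in variance order) only to reach the minimum count, as
    opposed to genuine interior variance local maxima.
    """

    subject_id: str
    frame_numbers: np.ndarray
    is_padding: np.ndarray
    variance_series: np.ndarray

    def __post_init__(self) -> None:
        self.frame_numbers = np.asarray(self.frame_numbers, dtype=int)
        self.is_padding = np.asarray(self.is_padding, dtype=bool)
        if self.frame_numbers.size != self.is_padding.size:
            raise ValidationError("frame_numbers / is_padding length mismatch")
        if np.any(np.diff(self.frame_numbers) <= 0):
            raise ValidationError("exemplar frame numbers must be sorted unique")

    @property
    def count(self) -> int:
        return self.frame_numbers.size


@dataclass
class CapMetrics:
    """Dynamic characteristics of one subject's state sequence in one band.

    For each state ``s`` (1..K): ``occurrence[s-1]`` is the fraction of
    frames in ``s`` (fractional occupancy); ``entry_count[s-1]`` the number
    of maximal consecutive runs of ``s``; ``mean_duration_frames[s-1]`` the
    mean run length (NaN when the state is never visited). The conservation
    law occurrence*T == entry_count*mean_duration holds exactly for visited
    states.
    """

    subject_id: str
    band_tag: str
    occurrence: np.ndarray
    entry_count: np.ndarray
    mean_duration_frames: np.ndarray
    transition_matrix: np.ndarray
    n_frames: int
    tr: float

    @property
    def n_states(self) -> int:
        return self.occurrence.size

    @property
    def mean_duration_seconds(self) -> np.ndarray:
        return self.mean_duration_frames * self.tr

    @property
    def entry_rate_per_min(self) -> np.ndarray:
        """Entries per minute of scan: count * 60 / (T * TR)."""
        return self.entry_count * 60.0 / (self.n_frames * self.tr)


@dataclass
class ScoreModel:
    """Linear clinical-score model: score = intercept + coef . occupancy + e."""

    intercept: float
    coefficients: np.ndarray
    residual_sd: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be nonnegative")


def check_row_stochastic(p: np.ndarray, *, tol: float = 1e-12) -> np.ndarray:
    """Validate and return a square row-stochastic matrix."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValidationError("transition matrix must be square")
    if np.any(p < -tol) or np.any(p > 1 + tol):
        raise ValidationError("transition probabilities must lie in [0, 1]")
    rowsums = p.sum(axis=1)
    bad = np.flatnonzero(np.abs(rowsums - 1.0) > max(tol, 1e-12))
    if bad.size:
        raise ValidationError(
            f"rows {bad.tolist()} of transition matrix do not sum to 1 "
            f"(sums {rowsums[bad]})"
        )
    return p


@dataclass
class SyntheticCohortConfig:
    """Ground truth for a simulated two-group cohort.

    ``n_subjects_per_group`` maps group label -> count; ``templates`` is a
    (K, n_voxels) array of spatial patterns; ``transition_by_group`` maps
    group label -> row-stochastic (K, K) matrix driving that group's hidden
    state dynamics.
    """

    n_subjects_per_group: dict[str, int]
    templates: np.ndarray
    transition_by_group: dict[str, np.ndarray]
    noise_sd: float
    score_model: ScoreModel
    seed: int
    tr: float = 3.0
    n_frames: int = 130
    initial_dist: np.ndarray | None = None
    groups: tuple[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        if self.templates.ndim != 2:
            raise ValidationError("templates must be (K, n_voxels)")
        k, n_vox = self.templates.shape
        if k < 2:
            raise ValidationError("need at least 2 latent states")
        if n_vox < k:
            raise ValidationError("n_voxels must be >= number of states")
        if self.n_frames < 2:
            raise ValidationError("n_frames must be >= 2")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if not (self.tr > 0):
            raise ValidationError("TR must be positive")
        var = self.templates.var(axis=1)
        if np.any(var == 0):
            raise ValidationError("every template needs nonzero spatial variance")
        for i in range(k):
            for j in range(i + 1, k):
                if np.array_equal(self.templates[i], self.templates[j]):
                    raise ValidationError(f"templates {i} and {j} are identical")
        self.groups = tuple(self.n_subjects_per_group)  # type: ignore[assignment]
        if len(self.groups) != 2:
            raise ValidationError("exactly two groups are required")
        for g, n in self.n_subjects_per_group.items():
            if n < 1:
                raise ValidationError(f"group {g} needs >= 1 subject")
        for g in self.groups:
            if g not in self.transition_by_group:
                raise ValidationError(f"missing transition matrix for group {g}")
            p = check_row_stochastic(self.transition_by_group[g])
            if p.shape[0] != k:
                raise ValidationError(
                    f"transition matrix for {g} must be {k} x {k}"
                )
            self.transition_by_group[g] = p
        if self.score_model.coefficients.size != k:
            raise ValidationError("score_model needs one coefficient per state")
        if self.initial_dist is not None:
            d = np.asarray(self.initial_dist, dtype=float)
            if d.size != k or np.any(d < 0) or abs(d.sum() - 1) > 1e-9:
                raise ValidationError("initial_dist must be a length-K distribution")
            self.initial_dist = d

    @property
    def k_true(self) -> int:
        return self.templates.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.templates.shape[1]


@dataclass
class SyntheticCohort:
    """Generated runs plus the hidden truth that produced them."""

    runs: list[BoldRun]
    ground_truth_sequences: list[StateSequence]
    phenotypes: pd.DataFrame
    config: SyntheticCohortConfig

    def __post_init__(self) -> None:
        if not (
            len(self.runs)
            == len(self.ground_truth_sequences)
            == len(self.phenotypes)
        ):
            raise ValidationError("runs / sequences / phenotypes length mismatch")
        for run, seq in zip(self.runs, self.ground_truth_sequences):
            if run.subject_id != seq.subject_id:
                raise ValidationError("run/sequence subject order mismatch")
            if run.n_frames != seq.n_frames:
                raise ValidationError(
                    f"subject {run.subject_id}: run has {run.n_frames} frames "
                    f"but sequence has {seq.n_frames}"
                )
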