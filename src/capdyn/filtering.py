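"""Temporal preprocessing of BOLD runs: detrend, nuisance regression,
bandpass into the LFO / slow-4 / slow-5 analysis bands.

The default bandpass is a zero-phase forward-backward Butterworth of order
2 per pass (effective order 4), the de facto resting-state fMRI choice; an
FFT "ideal boxcar" filter with the sharp band edges of the slow-band
literature is selectable via ``method="fft"``. Band edges are the exact
canonical values: LFO 0.01-0.1 Hz, slow-5 0.01-0.027 Hz, slow-4
0.027-0.073 Hz. At TR = 3 s the Nyquist frequency is ~0.167 Hz, so all
three bands are valid.

No frames are discarded for filter edge effects; runs are assumed to have
had their dummy volumes removed upstream.
"""

from __future__ import annotations

import numpy as np
import scipy.signal
from sklearn.base import BaseEstimator, TransformerMixin

from .types import BoldRun, FrequencyBand, ValidationError

__all__ = [
    "detrend",
    "regress_nuisance",
    "bandpass",
    "BandpassFilter",
    "preprocess_run",
]


def detrend(run: BoldRun) -> BoldRun:
    """Remove the least-squares line (intercept + slope * t) per voxel.

    The output has zero mean in every voxel; a pure linear series maps to
    zeros.
    """
    if run.n_frames < 3:
        raise ValidationError("detrend needs at least 3 frames")
    out = scipy.signal.detrend(run.data, axis=1, type="linear")
    return run.with_data(out)


def regress_nuisance(run: BoldRun, regressors: np.ndarray) -> BoldRun:
    """Project out nuisance time series (e.g. white-matter and CSF means).

    Per voxel, returns the OLS residual after regressing on an intercept
    plus the given ``(T, R)`` regressor matrix. A rank-deficient design is
    rejected with the offending columns named.
    """
    x = np.atleast_2d(np.asarray(regressors, dtype=float))
    if x.shape[0] != run.n_frames:
        if x.shape[1] == run.n_frames:
            x = x.T
        else:
            raise ValidationError(
                f"regressors must have T={run.n_frames} rows, got shape {x.shape}"
            )
    design = np.column_stack([np.ones(run.n_frames), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValidationError(
            f"nuisance design is rank-deficient; collinear columns "
            f"(0=intercept): {bad}"
        )
    # residual-maker applied to all voxels at once: data (N, T), design (T, R+1)
    beta, *_ = np.linalg.lstsq(design, run.data.T, rcond=None)
    resid = run.data.T - design @ beta
    return run.with_data(resid.T)


def _collinear_columns(design: np.ndarray) -> list[int]:
    """Columns lying in the span of the preceding ones."""
    bad = []
    for j in range(1, design.shape[1]):
        prev = design[:, :j]
        col = design[:, j]
        fit, *_ = np.linalg.lstsq(prev, col, rcond=None)
        if np.linalg.norm(col - prev @ fit) < 1e-10 * max(1.0, np.linalg.norm(col)):
            bad.append(j)
    return bad


def bandpass(
    run: BoldRun,
    band: FrequencyBand,
    *,
    method: str = "butterworth",
    order: int = 2,
) -> BoldRun:
    """Zero-phase bandpass of every voxel's series into ``band``.

    Parameters
    ----------
    method : {"butterworth", "fft"}
        ``butterworth`` applies an order-``order`` Butterworth forward and
        backward (``sosfiltfilt``), doubling the effective order and
        cancelling phase. ``fft`` zeroes all DFT bins outside
        [low_hz, high_hz] (ideal boxcar).
    """
    band.validate_for_tr(run.tr)
    if run.n_frames < 16:
        raise ValidationError("bandpass needs at least 16 frames")
    fs = 1.0 / run.tr
    # remove per-voxel mean first so filter transients do not ring on DC
    data = run.data - run.data.mean(axis=1, keepdims=True)
    if method == "butterworth":
        sos = scipy.signal.butter(
            order, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
        )
        out = scipy.signal.sosfiltfilt(sos, data, axis=1)
    elif method == "fft":
        freqs = np.fft.rfftfreq(run.n_frames, d=run.tr)
        keep = (freqs >= band.low_hz) & (freqs <= band.high_hz)
        spec = np.fft.rfft(data, axis=1)
        spec[:, ~keep] = 0.0
        out = np.fft.irfft(spec, n=run.n_frames, axis=1)
    else:
        raise ValidationError(f"unknown bandpass method {method!r}")
    tag = band.name if band.name in ("LFO", "slow4", "slow5") else run.band_tag
    return run.with_data(out, band_tag=tag)


def preprocess_run(
    run: BoldRun,
    band: FrequencyBand,
    regressors: np.ndarray | None = None,
    *,
    nuisance_stage: str = "after_filter",
    method: str = "butterworth",
) -> BoldRun:
    """detrend -> bandpass -> (optional) nuisance regression.

    ``nuisance_stage`` selects whether nuisance regression runs before or
    after the bandpass (default after, matching the conventional listed
    order of rs-fMRI preprocessing streams that regress WM/CSF last).
    """
    if nuisance_stage not in ("before_filter", "after_filter"):
        raise ValidationError(f"bad nuisance_stage {nuisance_stage!r}")
    out = detrend(run)
    if regressors is not None and nuisance_stage == "before_filter":
        out = regress_nuisance(out, regressors)
    out = bandpass(out, band, method=method)
    if regressors is not None and nuisance_stage == "after_filter":
        out = regress_nuisance(out, regressors)
    return out


class BandpassFilter(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`bandpass`.

    Operates on arrays of shape ``(n_frames, n_voxels)`` (time along rows,
    the sklearn sample axis). Stateless: ``fit`` only validates.

    Parameters
    ----------
    low_hz, high_hz : float
        Band edges in Hz.
    tr : float
        Sampling interval in seconds.
    method : {"butterworth", "fft"}
    order : int
        Butterworth order per pass.
    """

    def __init__(
        self,
        low_hz: float = 0.01,
        high_hz: float = 0.1,
        tr: float = 3.0,
        method: str = "butterworth",
        order: int = 2,
    ) -> None:
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.tr = tr
        self.method = method
        self.order = order

    def _band(self) -> FrequencyBand:
        name = next(
            (
                b.name
                for b in (
                    FrequencyBand("LFO", 0.01, 0.1),
                    FrequencyBand("slow5", 0.01, 0.027),
                    FrequencyBand("slow4", 0.027, 0.073),
                )
                if (b.low_hz, b.high_hz) == (self.low_hz, self.high_hz)
            ),
            "custom",
        )
        return FrequencyBand(name, self.low_hz, self.high_hz)

    def fit(self, X, y=None):
        band = self._band()
        band.validate_for_tr(self.tr)
        self.band_ = band
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "band_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        run = BoldRun(data=X.T, tr=self.tr, subject_id="_transform")
        return bandpass(run, self.band_, method=self.method, order=self.order).data.T
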