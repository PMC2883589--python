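"""BOLD preprocessing: frame removal, temporal filtering, smoothing,
nuisance regression, and grid downsampling, in that order.

The temporal filter is a least-squares detrend (constant + linear term)
followed by an ideal Fourier-domain low-pass: every DFT bin strictly above
the high-cut frequency is zeroed, the DC bin is zeroed (the mean is already
removed), and a bin falling exactly on the high-cut is retained. Nuisance
regressors are passed through the same low-pass before the regression so
residuals cannot regain out-of-band variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_volumes import (
    BrainMask,
    DataError,
    ParameterError,
    VolumeSeries,
    downsample,
)

logger = logging.getLogger("neighborgraph")

#: FWHM → Gaussian sigma conversion factor, 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class PreprocessConfig:
    """Pipeline parameters; defaults follow standard fcMRI practice."""

    drop_frames: int = 4
    highcut_hz: float = 0.08
    fwhm_mm: float = 4.0
    working_mm: float = 4.0
    smoothing_enabled: bool = True

    def validate(self, tr: float) -> None:
        if self.drop_frames < 0:
            raise ParameterError("drop_frames must be >= 0")
        nyquist = 1.0 / (2.0 * tr)
        if not 0 < self.highcut_hz < nyquist:
            raise ParameterError(
                f"highcut {self.highcut_hz} Hz outside (0, Nyquist={nyquist:.4f})"
            )
        if self.fwhm_mm < 0:
            raise ParameterError("fwhm_mm must be >= 0")


@dataclass
class NuisanceSet:
    """Confound regressors: one column per confound time course.

    A constant column is always implicitly included by the regression; it is
    not stored here.
    """

    regressors: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, float))
        if not np.all(np.isfinite(self.regressors)):
            raise DataError("nuisance regressors must be finite")
        if not self.names:
            self.names = [f"reg{i}" for i in range(self.regressors.shape[1])]


def drop_initial_frames(vol: VolumeSeries, n: int) -> VolumeSeries:
    """Remove the first ``n`` frames (T1-equilibration period)."""
    if n < 0:
        raise ParameterError("n must be >= 0")
    if n >= vol.n_frames:
        raise ParameterError(f"cannot drop {n} of {vol.n_frames} frames")
    out = VolumeSeries(vol.data[..., n:].copy(), vol.affine.copy(), vol.tr,
                       provenance=list(vol.provenance))
    out.log_stage("drop_initial_frames", n=n)
    return out


def _detrend_design(n: int) -> np.ndarray:
    t = np.arange(n, dtype=np.float64)
    return np.column_stack([np.ones(n), t - t.mean()])


def _lowpass_matrix_apply(ts: np.ndarray, tr: float, highcut_hz: float) -> np.ndarray:
    """Ideal low-pass along the last axis; removes DC, keeps f <= highcut."""
    n = ts.shape[-1]
    spec = np.fft.rfft(ts, axis=-1)
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = freqs <= highcut_hz + 1e-12
    keep[0] = False  # mean handled by detrending
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def temporal_filter_timeseries(
    ts: np.ndarray, tr: float, highcut_hz: float
) -> np.ndarray:
    """Detrend (constant + linear) then ideal low-pass, along the last axis."""
    n = ts.shape[-1]
    if n < 4:
        raise DataError("temporal filtering needs at least 4 frames")
    X = _detrend_design(n)
    flat = ts.reshape(-1, n)
    beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    detrended = flat - (X @ beta).T
    return _lowpass_matrix_apply(detrended, tr, highcut_hz).reshape(ts.shape)


def temporal_filter(vol: VolumeSeries, highcut_hz: float = 0.08) -> VolumeSeries:
    """Remove offsets/trends and frequencies above ``highcut_hz`` per voxel."""
    nyquist = 1.0 / (2.0 * vol.tr)
    if not 0 < highcut_hz < nyquist:
        raise ParameterError(f"highcut {highcut_hz} Hz outside (0, {nyquist:.4f})")
    data = temporal_filter_timeseries(vol.data, vol.tr, highcut_hz)
    out = VolumeSeries(data, vol.affine.copy(), vol.tr,
                       provenance=list(vol.provenance))
    out.log_stage("temporal_filter", highcut_hz=highcut_hz)
    return out


def spatial_smooth(vol: VolumeSeries, fwhm_mm: float = 4.0) -> VolumeSeries:
    """Per-frame 3D Gaussian smoothing with the given FWHM in mm.

    Sigma is converted to voxel units per axis from the affine scales, so
    anisotropic grids smooth isotropically in mm. ``fwhm_mm = 0`` is the
    identity (the no-smoothing control variant).
    """
    if fwhm_mm < 0:
        raise ParameterError("fwhm_mm must be >= 0")
    if not np.all(np.isfinite(vol.data)):
        raise DataError("cannot smooth non-finite values")
    if fwhm_mm == 0:
        out = VolumeSeries(vol.data.copy(), vol.affine.copy(), vol.tr,
                           provenance=list(vol.provenance))
        out.log_stage("spatial_smooth", fwhm_mm=0.0)
        return out
    sigma_mm = fwhm_mm / FWHM_TO_SIGMA
    sigma_vox = sigma_mm / vol.voxel_sizes_mm
    data = np.empty_like(vol.data)
    for t in range(vol.n_frames):
        data[..., t] = ndimage.gaussian_filter(
            vol.data[..., t], sigma=sigma_vox, mode="constant", cval=0.0
        )
    out = VolumeSeries(data, vol.affine.copy(), vol.tr,
                       provenance=list(vol.provenance))
    out.log_stage("spatial_smooth", fwhm_mm=fwhm_mm)
    return out


def roi_mean_timecourse(vol: VolumeSeries, mask: BrainMask) -> np.ndarray:
    """Mean time course over an ROI mask."""
    mask.check_compatible(vol)
    voxels = vol.data[mask.data]
    if voxels.size == 0:
        raise DataError(f"ROI '{mask.label}' is empty")
    return voxels.mean(axis=0)


def backward_difference(col: np.ndarray) -> np.ndarray:
    """First temporal derivative by backward differences; leading element 0."""
    out = np.empty_like(col, dtype=np.float64)
    out[0] = 0.0
    out[1:] = np.diff(col)
    return out


def build_nuisance(
    vol: VolumeSeries,
    masks: list[BrainMask],
    motion: np.ndarray | None = None,
    include_derivatives: bool = True,
) -> NuisanceSet:
    """Assemble confound regressors: per-ROI means, motion, derivatives.

    ``masks`` typically holds whole-brain, ventricle and white-matter masks.
    Motion is an n_frames x 6 table (already trimmed of dropped frames) and
    is optional — synthetic data have none; absence is logged, not an error.
    """
    cols, names = [], []
    for m in masks:
        cols.append(roi_mean_timecourse(vol, m))
        names.append(f"roi_mean:{m.label}")
    if motion is not None:
        motion = np.asarray(motion, float)
        if motion.shape[0] != vol.n_frames:
            raise DataError(
                f"motion table has {motion.shape[0]} rows for "
                f"{vol.n_frames} frames"
            )
        for i in range(motion.shape[1]):
            cols.append(motion[:, i])
            names.append(f"motion:{i}")
    else:
        logger.info("no motion parameters provided; proceeding without")
    if include_derivatives:
        for col, name in zip(list(cols), list(names)):
            cols.append(backward_difference(col))
            names.append(f"deriv:{name}")
    if not cols:
        raise DataError("no nuisance regressors to build")
    return NuisanceSet(np.column_stack(cols), names=names)


def filter_nuisance(nuis: NuisanceSet, tr: float, highcut_hz: float) -> NuisanceSet:
    """Band-limit every regressor with the same detrend + low-pass as the data."""
    filtered = temporal_filter_timeseries(nuis.regressors.T, tr, highcut_hz).T
    return NuisanceSet(filtered, names=list(nuis.names))


def _dedupe_columns(X: np.ndarray, names: list) -> tuple[np.ndarray, list]:
    """Drop exactly duplicated columns, keeping the first occurrence."""
    keep, seen = [], []
    for i in range(X.shape[1]):
        if any(np.array_equal(X[:, i], X[:, j]) for j in seen):
            logger.info("dropping duplicate nuisance column %s", names[i])
            continue
        keep.append(i)
        seen.append(i)
    return X[:, keep], [names[i] for i in keep]


def regress_nuisance(vol: VolumeSeries, nuis: NuisanceSet) -> VolumeSeries:
    """Per-voxel OLS residuals against [constant | regressors]."""
    n = vol.n_frames
    X, names = _dedupe_columns(nuis.regressors, nuis.names)
    if X.shape[0] != n:
        raise DataError(f"regressors have {X.shape[0]} rows for {n} frames")
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise DataError(
            "nuisance design rank-deficient after deduplication; columns: "
            + ", ".join(["const"] + names)
        )
    flat = vol.data.reshape(-1, n).T  # frames x voxels
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    out = VolumeSeries(resid.T.reshape(vol.data.shape), vol.affine.copy(),
                       vol.tr, provenance=list(vol.provenance))
    out.log_stage("regress_nuisance", n_regressors=X.shape[1], names=names)
    return out


def preprocess_run(
    vol: VolumeSeries,
    cfg: PreprocessConfig,
    nuisance_masks: list[BrainMask] | None = None,
    motion: np.ndarray | None = None,
) -> VolumeSeries:
    """Full preprocessing pipeline in fixed order.

    Stages: frame drop → temporal filter → spatial smooth → nuisance
    regression (regressors extracted from the smoothed+filtered data, then
    band-limited) → block-mean downsample to the working grid. Every stage
    appends to the provenance log.
    """
    cfg.validate(vol.tr)
    out = drop_initial_frames(vol, cfg.drop_frames) if cfg.drop_frames else vol
    if motion is not None:
        motion = np.asarray(motion, float)[cfg.drop_frames:]
    out = temporal_filter(out, cfg.highcut_hz)
    if cfg.smoothing_enabled and cfg.fwhm_mm > 0:
        out = spatial_smooth(out, cfg.fwhm_mm)
    if nuisance_masks or motion is not None:
        nuis = build_nuisance(out, nuisance_masks or [], motion=motion,
                              include_derivatives=True)
        nuis = filter_nuisance(nuis, out.tr, cfg.highcut_hz)
        out = regress_nuisance(out, nuis)
    out = downsample(out, cfg.working_mm)
    return out
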