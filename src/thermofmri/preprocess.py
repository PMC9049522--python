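"""Temporal and spatial preprocessing of BOLD series.

Stimulus-driven runs follow the fixed order
``pairwise_average -> discard_initial -> slice_time_correct ->
rigid_motion_correct -> gaussian_smooth -> temporal_highpass``;
resting-state runs use
``discard_initial -> slice_time_correct -> rigid_motion_correct ->
temporal_lowpass``.

All operations are linear (up to the motion-correction resampling), preserve
the voxel grid except for the stated time-axis changes, and keep the timing
metadata (`tr`, `t0`) consistent so downstream design matrices and
event-related windows line up with the acquisition clock.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.interpolate import CubicSpline

from .core import BoldSeries, ConfigError, InputError

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class PreprocessConfig:
    """Preprocessing parameters for one run class."""

    n_discard_volumes: int = 2
    pairwise_average: bool = True
    slice_order: str = "none"  # "ascending_interleaved" or "none"
    smoothing_fwhm: float = 2.0  # pixels, in-plane
    highpass_fwhm: float = 12.0  # s, metadata only (see temporal_highpass)
    highpass_cycles: int = 9
    lowpass_hz: float | None = None
    motion_correction: str = "none"  # "none" or "rigid"

    def __post_init__(self) -> None:
        if self.n_discard_volumes < 0:
            raise ConfigError("n_discard_volumes must be >= 0")
        if self.smoothing_fwhm < 0:
            raise ConfigError("smoothing_fwhm must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PreprocessConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def pairwise_average(series: BoldSeries) -> BoldSeries:
    """Average consecutive volume pairs, halving t and doubling TR.

    An odd trailing volume is dropped with a warning. The first-volume time
    moves to the pair midpoint (t0 + TR/2).
    """
    n = series.n_volumes
    if n < 2:
        raise InputError("pairwise averaging needs at least 2 volumes")
    if n % 2:
        warnings.warn("odd number of volumes: dropping the trailing volume", stacklevel=2)
        n -= 1
    data = 0.5 * (series.data[..., 0:n:2] + series.data[..., 1:n:2])
    return series.copy_with(data=data, tr=2.0 * series.tr, t0=series.t0 + 0.5 * series.tr)


def discard_initial(series: BoldSeries, n: int) -> BoldSeries:
    """Drop the first ``n`` volumes (MR saturation), shifting t0 by n*TR."""
    if n < 0:
        raise InputError("n must be >= 0")
    if n >= series.n_volumes:
        raise InputError(f"cannot discard {n} of {series.n_volumes} volumes")
    if n == 0:
        return series.copy_with()
    return series.copy_with(data=series.data[..., n:], t0=series.t0 + n * series.tr)


def _slice_acquisition_order(n_slices: int) -> np.ndarray:
    """Ascending interleaved: even-index slices first, then odd-index."""
    return np.concatenate([np.arange(0, n_slices, 2), np.arange(1, n_slices, 2)])


def slice_time_correct(series: BoldSeries, slice_order: str = "ascending_interleaved") -> BoldSeries:
    """Resample each slice's time course to the first slice's acquisition times.

    Uses cubic-spline interpolation; evaluation times are clamped to the
    acquired range (endpoint volumes are held rather than extrapolated).
    """
    if slice_order == "none" or series.shape[2] == 1:
        return series.copy_with()
    if slice_order != "ascending_interleaved":
        raise ConfigError(f"unknown slice order: {slice_order}")
    nz = series.shape[2]
    order = _slice_acquisition_order(nz)
    offset = np.empty(nz)
    offset[order] = np.arange(nz) / nz * series.tr
    ref_offset = offset[0]
    vol_times = series.tr * np.arange(series.n_volumes)
    out = np.empty_like(series.data)
    for z in range(nz):
        acq = vol_times + offset[z]
        y = series.data[:, :, z, :].reshape(-1, series.n_volumes).T
        cs = CubicSpline(acq, y, axis=0)
        eval_t = np.clip(vol_times + ref_offset, acq[0], acq[-1])
        out[:, :, z, :] = cs(eval_t).T.reshape(series.shape[0], series.shape[1], series.n_volumes)
    return series.copy_with(data=out)


# --------------------------------------------------------------------------
# Rigid-body motion correction (simplified: MSE metric, trilinear resampling)
# --------------------------------------------------------------------------
def _rigid_matrix(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tx, ty, tz, rx, ry, rz = params
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx, np.array([tx, ty, tz])


def _apply_rigid(volume: np.ndarray, params: np.ndarray) -> np.ndarray:
    rot, trans = _rigid_matrix(params)
    center = (np.array(volume.shape) - 1) / 2.0
    offset = center - rot @ center + trans
    return ndimage.affine_transform(volume, rot, offset=offset, order=1, mode="constant", cval=0.0)


def rigid_motion_correct(series: BoldSeries, reference_index: int = 0) -> tuple[BoldSeries, pd.DataFrame]:
    """Align every volume rigidly (3 translations + 3 rotations) to the reference.

    Similarity metric: negative mean squared difference, optimized with
    Powell's method from the identity; volumes whose optimization fails are
    flagged and passed through untransformed. Translations are estimated in
    voxel units.
    """
    if series.n_volumes < 2:
        raise InputError("motion correction needs at least 2 volumes")
    ref = np.asarray(series.data[..., reference_index], dtype=float)
    out = np.empty_like(series.data)
    rows = []
    for i in range(series.n_volumes):
        vol = np.asarray(series.data[..., i], dtype=float)
        if i == reference_index:
            params, flagged = np.zeros(6), False
        else:

            def cost(p):
                return float(np.mean((_apply_rigid(vol, p) - ref) ** 2))

            res = optimize.minimize(
                cost,
                np.zeros(6),
                method="Powell",
                options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 2000},
            )
            flagged = not res.success
            params = np.zeros(6) if flagged else res.x
        out[..., i] = _apply_rigid(vol, params) if np.any(params) else vol
        rows.append(
            {
                "volume": i,
                "tx": params[0],
                "ty": params[1],
                "tz": params[2],
                "rx": params[3],
                "ry": params[4],
                "rz": params[5],
                "flagged": flagged,
            }
        )
    return series.copy_with(data=out), pd.DataFrame(rows)


def gaussian_smooth(series: BoldSeries, fwhm_pixels: float) -> BoldSeries:
    """In-plane (x, y) Gaussian smoothing per volume; zero-padded boundaries.

    Smoothing is 2D only: slice thickness (1 mm) is much larger than the
    in-plane voxel size and the kernel width is stated in pixels.
    """
    if fwhm_pixels < 0:
        raise ConfigError("fwhm must be >= 0")
    if fwhm_pixels == 0:
        return series.copy_with()
    sigma = fwhm_pixels * FWHM_TO_SIGMA
    src = series.data if np.issubdtype(series.data.dtype, np.floating) else np.asarray(series.data, dtype=float)
    data = ndimage.gaussian_filter(src, sigma=(sigma, sigma, 0.0, 0.0), mode="constant", cval=0.0)
    return series.copy_with(data=data)


def _highpass_basis(n: int, cycles: int, dtype) -> np.ndarray:
    """Orthonormal low-frequency basis: linear trend plus Fourier pairs at
    1 .. cycles-1 cycles per run (all components strictly below the cutoff)."""
    t = np.arange(n, dtype=dtype)
    cols = [t - t.mean()]
    for k in range(1, int(cycles)):
        cols.append(np.cos(2 * np.pi * k * t / n))
        cols.append(np.sin(2 * np.pi * k * t / n))
    B = np.column_stack(cols)
    B -= B.mean(axis=0)
    Q, _ = np.linalg.qr(B)
    return Q.astype(dtype)


def _highpass_1d(y: np.ndarray, cycles: int, restore_mean: bool) -> np.ndarray:
    """High-pass along the last axis of a 2D array (series, t): joint
    projection out of the linear trend and all Fourier components below
    cycles/(run duration)."""
    n = y.shape[-1]
    dtype = y.dtype if np.issubdtype(y.dtype, np.floating) else np.float64
    Q = _highpass_basis(n, cycles, dtype)
    mean = y.mean(axis=-1, keepdims=True)
    centered = y - mean
    out = centered - (centered @ Q) @ Q.T
    if restore_mean:
        out = out + mean
    return out


def temporal_highpass(series: BoldSeries, fwhm_s: float = 12.0, cycles: int = 9) -> BoldSeries:
    """Per-voxel linear detrend plus FFT high-pass at ``cycles``/run-duration.

    Fourier components at frequencies strictly below cycles/(n*TR) are
    zeroed; the voxel mean (DC) is restored afterwards. ``fwhm_s`` is carried
    for provenance only -- the cycles cutoff is the operative parameter.
    """
    if cycles < 1:
        raise ConfigError("cycles must be >= 1")
    src = series.data if np.issubdtype(series.data.dtype, np.floating) else np.asarray(series.data, dtype=float)
    flat = src.reshape(-1, series.n_volumes)
    out = _highpass_1d(flat, cycles, restore_mean=True)
    prov = dict(series.provenance)
    prov.setdefault("preprocess", []).append(
        {"op": "temporal_highpass", "fwhm_s": fwhm_s, "cycles": cycles}
    )
    return series.copy_with(data=out.reshape(series.shape), provenance=prov)


def highpass_design(matrix: np.ndarray, cycles: int) -> np.ndarray:
    """Apply the same detrend + FFT high-pass operator to design-matrix columns.

    Constant columns are passed through unchanged. Filtering the regressors
    with the operator applied to the data keeps the GLM unbiased.
    """
    out = np.array(matrix, dtype=float)
    for j in range(out.shape[1]):
        col = out[:, j]
        if np.ptp(col) == 0:
            continue
        out[:, j] = _highpass_1d(col[None, :], cycles, restore_mean=False)[0]
    return out


def temporal_lowpass(series: BoldSeries, cutoff_hz: float) -> BoldSeries:
    """Zero all Fourier components above ``cutoff_hz`` per voxel."""
    nyquist = 1.0 / (2.0 * series.tr)
    if cutoff_hz >= nyquist:
        raise ConfigError(f"cutoff {cutoff_hz} Hz is not below Nyquist {nyquist} Hz")
    n = series.n_volumes
    freqs = np.fft.rfftfreq(n, d=series.tr)
    flat = np.asarray(series.data, dtype=float).reshape(-1, n)
    spec = np.fft.rfft(flat, axis=-1)
    spec[:, freqs > cutoff_hz] = 0.0
    out = np.fft.irfft(spec, n=n, axis=-1)
    return series.copy_with(data=out.reshape(series.shape))


# --------------------------------------------------------------------------
# Run-class pipelines
# --------------------------------------------------------------------------
def preprocess_stimulus_run(series: BoldSeries, config: PreprocessConfig) -> BoldSeries:
    """Fixed stimulus-run chain: average pairs, discard, slice-time, motion,
    smooth, high-pass."""
    out = series
    if config.pairwise_average:
        out = pairwise_average(out)
    if config.n_discard_volumes:
        out = discard_initial(out, config.n_discard_volumes)
    out = slice_time_correct(out, config.slice_order)
    if config.motion_correction == "rigid":
        out, _ = rigid_motion_correct(out)
    out = gaussian_smooth(out, config.smoothing_fwhm)
    out = temporal_highpass(out, config.highpass_fwhm, config.highpass_cycles)
    return out


def preprocess_resting_run(series: BoldSeries, config: PreprocessConfig) -> BoldSeries:
    """Fixed resting-state chain: discard, slice-time, motion, low-pass."""
    out = series
    if config.n_discard_volumes:
        out = discard_initial(out, config.n_discard_volumes)
    out = slice_time_correct(out, config.slice_order)
    if config.motion_correction == "rigid":
        out, _ = rigid_motion_correct(out)
    if config.lowpass_hz is not None:
        out = temporal_lowpass(out, config.lowpass_hz)
    return out
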