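"""Post-alignment preprocessing of BOLD time series.

Implements the stages applied after rigid-body realignment and spatial
normalization (which are upstream concerns): discarding initial volumes,
head-motion quality control, Gaussian spatial smoothing, linear detrending
and ideal band-pass filtering. The default stage order is

    discard -> motion QC gate -> smooth -> detrend -> bandpass

Smoothing before the concordance computation inflates local synchrony, so
``smooth_stage`` can defer it until after the ReHo map is formed, or switch
it off; the default applies it to the time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import BrainMask, MotionTrace, Volume4D, affine_has_shear, voxel_sizes

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: tolerance on passband edges so bin inclusion is deterministic across platforms
EDGE_EPS_HZ = 1e-9


@dataclass
class PreprocConfig:
    n_discard: int = 10
    max_translation: float = 1.0  # mm
    max_rotation: float = 1.0  # degrees
    fwhm: tuple[float, float, float] = (8.0, 8.0, 8.0)  # mm
    passband: tuple[float, float] = (0.01, 0.08)  # Hz
    smooth_stage: str = "before_reho"  # before_reho | after_reho | off
    renormalize_in_mask: bool = False

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.max_translation <= 0 or self.max_rotation <= 0:
            raise ValueError("motion thresholds must be positive")
        low, high = self.passband
        if not (0 <= low < high):
            raise ValueError(f"invalid passband {self.passband}")
        if self.smooth_stage not in ("before_reho", "after_reho", "off"):
            raise ValueError(f"unknown smooth_stage {self.smooth_stage!r}")


@dataclass
class MotionQCResult:
    passed: bool
    worst_translation: float  # mm, relative to first retained volume
    worst_rotation: float  # degrees


def motion_qc(trace: MotionTrace, config: PreprocConfig) -> MotionQCResult:
    """Apply the head-motion exclusion rule.

    Displacement is measured per axis relative to the first retained volume
    (cumulative-from-reference, the DPARSF convention, not frame-to-frame).
    A subject fails only if the worst excursion exceeds the threshold
    strictly ("more than 1 mm / 1 degree"): exactly 1.0 passes.
    """
    if trace.n_volumes < 2:
        raise ValueError("motion trace must cover at least 2 volumes")
    t_disp = np.abs(trace.translations - trace.translations[0])
    r_disp = np.abs(trace.rotations - trace.rotations[0])
    worst_t = float(t_disp.max())
    worst_r = float(r_disp.max())
    passed = (worst_t <= config.max_translation) and (worst_r <= config.max_rotation)
    return MotionQCResult(passed=passed, worst_translation=worst_t, worst_rotation=worst_r)


def discard_initial(vol: Volume4D, n_discard: int) -> Volume4D:
    """Drop the first ``n_discard`` volumes (signal-equilibration frames)."""
    if n_discard == 0:
        return vol
    if vol.n_volumes <= n_discard + 1:
        raise ValueError(
            f"cannot discard {n_discard} of {vol.n_volumes} volumes"
        )
    return Volume4D(data=vol.data[..., n_discard:], affine=vol.affine, tr=vol.tr)


def smooth_gaussian(
    vol_or_frame: Volume4D | np.ndarray,
    fwhm: tuple[float, float, float],
    mask: BrainMask | None = None,
    affine: np.ndarray | None = None,
    renormalize_in_mask: bool = False,
):
    """Convolve each frame with a separable Gaussian of the given FWHM (mm).

    Sigma per axis is ``fwhm * 1/(2*sqrt(2*ln 2))`` in mm, converted to voxel
    units through the affine scales. Convolution is zero-padded, so total
    in-frame intensity is conserved away from boundaries; the optional
    in-mask renormalization divides by the smoothed mask to undo attenuation
    at mask edges (off by default).

    Accepts either a :class:`Volume4D` (smoothing every frame) or a bare 3D
    array plus ``affine``.
    """
    fwhm = np.asarray(fwhm, dtype=float)
    if np.any(fwhm < 0):
        raise ValueError("fwhm components must be >= 0")

    if isinstance(vol_or_frame, Volume4D):
        aff = vol_or_frame.affine
        data = vol_or_frame.data
        is_vol = True
    else:
        if affine is None:
            raise ValueError("affine required when smoothing a bare array")
        aff = affine
        data = np.asarray(vol_or_frame)
        is_vol = False

    if affine_has_shear(aff):
        raise ValueError("sheared affines are unsupported for separable smoothing")

    if np.all(fwhm == 0):
        return vol_or_frame

    sigma_vox = fwhm * FWHM_TO_SIGMA / voxel_sizes(aff)

    def _smooth3d(frame: np.ndarray) -> np.ndarray:
        out = ndimage.gaussian_filter(frame.astype(float), sigma=sigma_vox, mode="constant")
        if renormalize_in_mask and mask is not None:
            weight = ndimage.gaussian_filter(
                mask.data.astype(float), sigma=sigma_vox, mode="constant"
            )
            inside = mask.data & (weight > 1e-12)
            out = np.where(inside, out / np.where(inside, weight, 1.0), out)
        return out

    if is_vol:
        out = np.empty_like(data, dtype=float)
        for t in range(data.shape[3]):
            out[..., t] = _smooth3d(data[..., t])
        return Volume4D(data=out, affine=aff, tr=vol_or_frame.tr)
    return _smooth3d(data)


def detrend_linear(vol: Volume4D, mask: BrainMask | None = None) -> Volume4D:
    """Remove each voxel's least-squares line (intercept + slope) over time.

    Output series have zero mean and zero linear trend; idempotent.
    """
    n = vol.n_volumes
    if n < 3:
        raise ValueError("need at least 3 time points to detrend")
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t])
    # hat matrix applied along the time axis for every voxel at once
    pinv = np.linalg.pinv(X)  # (2, n)
    flat = vol.data.reshape(-1, n).astype(float)
    if mask is not None:
        mask.check_matches(vol)
        sel = mask.data.reshape(-1)
        beta = pinv @ flat[sel].T
        flat = flat.copy()
        flat[sel] = flat[sel] - (X @ beta).T
    else:
        beta = pinv @ flat.T
        flat = flat - (X @ beta).T
    return Volume4D(data=flat.reshape(vol.data.shape), affine=vol.affine, tr=vol.tr)


def bandpass(
    vol: Volume4D,
    passband: tuple[float, float] = (0.01, 0.08),
    tr: float | None = None,
    mask: BrainMask | None = None,
) -> Volume4D:
    """Ideal rectangular frequency-domain filter per voxel.

    Discrete-Fourier bins with frequency inside ``[low, high]`` (inclusive,
    with a 1e-9 Hz guard on the edges) are retained, all others — including
    DC whenever ``low > 0`` — are zeroed. Idempotent by construction.
    """
    tr = float(tr if tr is not None else vol.tr)
    low, high = passband
    nyquist = 1.0 / (2.0 * tr)
    if not (0 <= low < high):
        raise ValueError(f"invalid passband {passband}")
    if high >= nyquist:
        raise ValueError(f"passband high {high} Hz >= Nyquist {nyquist:.4f} Hz")
    n = vol.n_volumes
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low - EDGE_EPS_HZ) & (freqs <= high + EDGE_EPS_HZ)
    flat = vol.data.reshape(-1, n).astype(float)
    if mask is not None:
        mask.check_matches(vol)
        sel = mask.data.reshape(-1)
        spec = np.fft.rfft(flat[sel], axis=1)
        spec[:, ~keep] = 0
        flat = flat.copy()
        flat[sel] = np.fft.irfft(spec, n=n, axis=1)
    else:
        spec = np.fft.rfft(flat, axis=1)
        spec[:, ~keep] = 0
        flat = np.fft.irfft(spec, n=n, axis=1)
    return Volume4D(data=flat.reshape(vol.data.shape), affine=vol.affine, tr=vol.tr)


def preprocess_volume(
    vol: Volume4D, mask: BrainMask, config: PreprocConfig
) -> Volume4D:
    """Run discard -> (smooth) -> detrend -> bandpass in the default order.

    Motion QC is a gate applied by the caller before this function; the
    smoothing stage is skipped here unless ``smooth_stage == 'before_reho'``.
    """
    mask.check_matches(vol)
    out = discard_initial(vol, config.n_discard)
    if config.smooth_stage == "before_reho":
        out = smooth_gaussian(
            out, config.fwhm, mask=mask, renormalize_in_mask=config.renormalize_in_mask
        )
    out = detrend_linear(out, mask=mask)
    out = bandpass(out, config.passband, mask=mask)
    return out
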