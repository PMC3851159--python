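"""Synthetic resting-state BOLD cohorts with controllable regional synchrony.

Each subject's in-mask voxel series is a convex mixture of a shared,
band-limited regional signal and voxel-private noise, plus a linear scanner
drift:

    y_v(t) = w * s_r(t) + (1 - w) * eps_v(t) + d(t)

where ``s_r`` is one signal per region (white noise filtered to the
passband in the frequency domain, then standardized to zero mean and unit
variance), ``w`` is the region's synchrony weight for the subject's group
(0 outside all regions), ``eps_v`` is i.i.d. Gaussian noise per voxel with
SD ``noise_sd``, and ``d`` is a linear ramp spanning ``drift_amplitude``
over the scan. Raising ``w`` raises the neighborhood concordance of the
region monotonically, which is the ground truth the downstream group
comparison has to recover. Out-of-mask voxels carry pure noise.

Cohorts come with synthetic rigid-body motion traces (small-amplitude
Gaussian random walks; amplitude overridable per subject so QC pass and
fail cases can both be produced), and a design table with covariates drawn
independently of group (an optional per-group anxiety-score shift lets
tests exercise the covariate-adjustment path under confounding).

Everything is reproducible from ``(spec.seed, subject index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BrainMask,
    DesignTable,
    MotionTrace,
    Volume4D,
    write_design,
    write_mask,
    write_motion,
    write_volume4d,
)

#: covariate sampling ranges (uniform), matching a middle-aged clinical cohort
AGE_RANGE = (20.0, 53.0)
EDUCATION_RANGE = (9.0, 17.0)
HAMA_RANGE = (2.0, 20.0)


@dataclass
class RegionSpec:
    """A set of in-mask voxels sharing one synchronous signal."""

    label: str
    voxels: np.ndarray  # (n, 3) int voxel indices
    sync_weight_per_group: dict[str, float]

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if self.voxels.shape[1] != 3:
            raise ValueError("region voxels must be (n, 3) index triples")
        for g, w in self.sync_weight_per_group.items():
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"sync weight for group {g!r} must lie in [0, 1]")

    def weight(self, group: str) -> float:
        return self.sync_weight_per_group.get(group, 0.0)


def block_region(
    label: str,
    corner: tuple[int, int, int],
    size: tuple[int, int, int],
    sync_weight_per_group: dict[str, float],
) -> RegionSpec:
    """Convenience: a rectangular block of voxels."""
    grids = np.meshgrid(
        *[np.arange(c, c + s) for c, s in zip(corner, size)], indexing="ij"
    )
    voxels = np.stack([g.reshape(-1) for g in grids], axis=1)
    return RegionSpec(label=label, voxels=voxels, sync_weight_per_group=sync_weight_per_group)


@dataclass
class CohortSpec:
    """Study conditions for one simulated cohort.

    Defaults mirror a 6 min 24 s EPI acquisition: 128 volumes at TR = 3 s,
    spontaneous fluctuations in the 0.01-0.08 Hz band, unit-variance voxel
    noise and a half-unit linear drift over the scan.
    """

    groups: dict[str, int]
    mask: BrainMask
    regions: list[RegionSpec] = field(default_factory=list)
    n_volumes: int = 128
    tr: float = 3.0
    drift_amplitude: float = 0.5
    noise_sd: float = 1.0
    passband: tuple[float, float] = (0.01, 0.08)
    motion_translation_sd: float = 0.02  # mm per random-walk step
    motion_rotation_sd: float = 0.02  # degrees per step
    hama_group_shift: dict[str, float] = field(default_factory=dict)  # confound knob
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.groups.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 subjects")
        if self.n_volumes < 32:
            raise ValueError("n_volumes must be >= 32")
        low, high = self.passband
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0 <= low < high < nyquist):
            raise ValueError(f"passband {self.passband} outside (0, Nyquist={nyquist:.4f})")
        shape = self.mask.data.shape
        for region in self.regions:
            if np.any(region.voxels < 0) or np.any(region.voxels >= np.array(shape)):
                raise ValueError(f"region {region.label!r} has voxels outside the grid")
            if not self.mask.data[tuple(region.voxels.T)].all():
                raise ValueError(f"region {region.label!r} has voxels outside the mask")


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    volume: Volume4D
    motion: MotionTrace
    covariates: dict[str, float]


def band_limited_signal(
    n: int, tr: float, passband: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """White noise filtered to the passband, standardized to mean 0 / SD 1."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=tr)
    low, high = passband
    keep = (freqs >= low - 1e-9) & (freqs <= high + 1e-9)
    if not keep.any():
        raise ValueError(f"passband {passband} contains no DFT bin at n={n}, tr={tr}")
    spec[~keep] = 0
    sig = np.fft.irfft(spec, n=n)
    sd = sig.std(ddof=0)
    if sd <= 0:  # pragma: no cover - keep.any() guarantees power
        raise ValueError("degenerate band-limited signal")
    return (sig - sig.mean()) / sd


def generate_subject(spec: CohortSpec, group: str, subject_seed: int) -> Volume4D:
    """One subject's 4D volume, reproducible from (spec.seed, subject_seed)."""
    if group not in spec.groups:
        raise KeyError(f"unknown group {group!r}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, int(subject_seed)]))
    shape = spec.mask.data.shape
    T = spec.n_volumes

    # fixed draw order: region signals first (spec order), then the noise field
    signals = [band_limited_signal(T, spec.tr, spec.passband, rng) for _ in spec.regions]
    data = rng.standard_normal((*shape, T)) * spec.noise_sd

    drift = spec.drift_amplitude * np.linspace(0.0, 1.0, T)
    in_mask = spec.mask.data
    for region, sig in zip(spec.regions, signals):
        w = region.weight(group)
        if w == 0:
            continue
        idx = tuple(region.voxels.T)
        data[idx] = w * sig + (1.0 - w) * data[idx]
    data[in_mask] += drift
    return Volume4D(data=data, affine=spec.mask.affine, tr=spec.tr)


def generate_motion(
    n_volumes: int,
    rng: np.random.Generator,
    translation_sd: float,
    rotation_sd: float,
) -> MotionTrace:
    """Small-amplitude Gaussian random-walk motion starting at zero."""
    t_steps = rng.normal(0.0, translation_sd, size=(n_volumes, 3))
    r_steps = rng.normal(0.0, rotation_sd, size=(n_volumes, 3))
    t_steps[0] = 0.0
    r_steps[0] = 0.0
    return MotionTrace(
        translations=np.cumsum(t_steps, axis=0), rotations=np.cumsum(r_steps, axis=0)
    )


def generate_cohort(
    spec: CohortSpec,
    motion_sd_overrides: dict[str, tuple[float, float]] | None = None,
) -> tuple[list[SyntheticSubject], DesignTable]:
    """Full cohort: volumes, motion traces and the design table.

    ``motion_sd_overrides`` maps subject id (``sub-<group><k>``) to
    per-step (translation mm, rotation degree) SDs, so individual subjects
    can be pushed over the motion-QC limit.
    """
    motion_sd_overrides = motion_sd_overrides or {}
    subjects: list[SyntheticSubject] = []
    rows = []
    index = 0
    for group in spec.groups:  # insertion order: deterministic
        for k in range(spec.groups[group]):
            sid = f"sub-{group}{k + 1:02d}"
            vol = generate_subject(spec, group, index)
            aux_rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, int(index), 1])
            )
            t_sd, r_sd = motion_sd_overrides.get(
                sid, (spec.motion_translation_sd, spec.motion_rotation_sd)
            )
            motion = generate_motion(spec.n_volumes, aux_rng, t_sd, r_sd)
            cov = {
                "age": round(float(aux_rng.uniform(*AGE_RANGE)), 1),
                "gender": int(aux_rng.integers(0, 2)),
                "education": round(float(aux_rng.uniform(*EDUCATION_RANGE)), 1),
                "hama": round(
                    float(
                        aux_rng.uniform(*HAMA_RANGE)
                        + spec.hama_group_shift.get(group, 0.0)
                    ),
                    1,
                ),
            }
            subjects.append(
                SyntheticSubject(
                    subject_id=sid, group=group, volume=vol, motion=motion, covariates=cov
                )
            )
            rows.append({"id": sid, "group": group, **cov})
            index += 1
    design = DesignTable(table=pd.DataFrame(rows))
    return subjects, design


def write_cohort(
    subjects: list[SyntheticSubject],
    design: DesignTable,
    mask: BrainMask,
    out_dir: str | Path,
) -> Path:
    """Write a cohort in the pipeline's on-disk input layout.

    ``<dir>/sub-XXX_bold.nii.gz``, ``<dir>/rp_sub-XXX.txt`` (rotations in
    radians, the rp dialect), ``<dir>/mask.nii.gz``, ``<dir>/design.csv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        write_volume4d(s.volume, out / f"{s.subject_id}_bold.nii.gz")
        write_motion(s.motion, out / f"rp_{s.subject_id}.txt")
    write_mask(mask, out / "mask.nii.gz")
    write_design(design, out / "design.csv")
    return out
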