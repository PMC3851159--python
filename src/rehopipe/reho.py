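"""Regional homogeneity: Kendall's coefficient of concordance over cubic
voxel neighborhoods.

For a neighborhood of K time series of length n, each series is ranked
independently over time (midranks on ties) and the concordance is

    W = 12 * sum_i (R_i - Rbar)^2 / (K^2 * (n^3 - n))

where R_i is the sum of ranks at time point i across the K series and Rbar
their mean. W ranges from 0 (no agreement) to 1 (all series ranking the
time points identically). The optional tie correction subtracts
K * sum(t^3 - t) over tie groups from the denominator; it is off by default
because the classical formula used throughout the ReHo literature carries no
tie term, and band-passed BOLD series are effectively tie-free.

A voxel's ReHo is W over the series of the voxel plus its neighbors in a
3x3x3 cube: K = 27 (full cube, the standard choice), 19 (faces + edges) or
7 (faces only). Boundary voxels whose in-mask neighborhood is smaller than
``min_neighbors`` emit 0 and are excluded from the whole-brain statistics
used for map standardization, which avoids biasing the normalizing mean
with partial-cube values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io import BrainMask, Volume4D

_OFFSETS_27 = [np.array(o) for o in itertools.product((-1, 0, 1), repeat=3)]


def neighborhood_offsets(k: int) -> list[np.ndarray]:
    """Voxel offsets of the cubic neighborhood for K in {7, 19, 27}."""
    if k == 27:
        return list(_OFFSETS_27)
    if k == 19:
        return [o for o in _OFFSETS_27 if np.abs(o).sum() <= 2]
    if k == 7:
        return [o for o in _OFFSETS_27 if np.abs(o).sum() <= 1]
    raise ValueError(f"K must be one of 7, 19, 27; got {k}")


@dataclass
class ReHoParams:
    K: int = 27
    tie_correction: bool = False
    min_neighbors: int | None = None  # None -> require the full K-voxel cube

    def __post_init__(self) -> None:
        if self.K not in (7, 19, 27):
            raise ValueError(f"K must be one of 7, 19, 27; got {self.K}")
        if self.min_neighbors is None:
            self.min_neighbors = self.K
        if not (1 <= self.min_neighbors <= self.K):
            raise ValueError("min_neighbors must lie in [1, K]")


@dataclass
class ReHoMap:
    """3D concordance map, raw (values in [0, 1]) or standardized."""

    data: np.ndarray
    affine: np.ndarray
    standardization: str  # raw | divided_by_mean | zscore
    params: ReHoParams
    valid: np.ndarray = field(repr=False)  # voxels carrying a real W value
    n_partial: int = 0  # in-mask voxels skipped for incomplete neighborhoods


def kendalls_w(series_set: np.ndarray, tie_correction: bool = False) -> float:
    """Kendall's W of K time series of length n.

    Degenerate inputs (all series constant, or a tie-corrected denominator
    that vanishes) are defined as W = 0.
    """
    series = np.asarray(series_set, dtype=float)
    if series.ndim != 2:
        raise ValueError("series_set must be a (K, n) array")
    K, n = series.shape
    if K < 2:
        raise ValueError("need at least 2 series")
    if n < 3:
        raise ValueError("need at least 3 time points")
    ranks = rankdata(series, axis=1)
    R = ranks.sum(axis=0)
    S = float(((R - R.mean()) ** 2).sum())
    denom = K * K * (n**3 - n)
    if tie_correction:
        denom -= K * _tie_term(ranks)
    if denom <= 0:
        return 0.0
    return min(12.0 * S / denom, 1.0)


def _tie_term(ranks: np.ndarray) -> float:
    """sum over series and tie groups of (t^3 - t), t the tie-group size."""
    total = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        total += float((counts.astype(float) ** 3 - counts).sum())
    return total


def compute_reho_map(
    vol: Volume4D, mask: BrainMask, params: ReHoParams | None = None
) -> ReHoMap:
    """Voxel-wise Kendall's W over cubic neighborhoods, vectorized.

    Every voxel's series is ranked once; neighborhood rank sums are then
    accumulated by shifting the rank volume through the K cube offsets, so
    the result matches a per-voxel loop over :func:`kendalls_w` exactly.
    Voxels whose in-mask neighborhood has fewer than ``min_neighbors``
    members emit 0 and are flagged invalid.
    """
    params = params or ReHoParams()
    mask.check_matches(vol)
    n = vol.n_volumes
    if n < 3:
        raise ValueError("need at least 3 time points")
    shape = mask.data.shape
    m = mask.data

    flat = vol.data.reshape(-1, n).astype(float)
    ranks = np.zeros_like(flat)
    sel = m.reshape(-1)
    ranks[sel] = rankdata(flat[sel], axis=1)
    ranks = ranks.reshape(*shape, n)

    if params.tie_correction:
        tie_flat = np.zeros(flat.shape[0])
        idx = np.flatnonzero(sel)
        r_in = ranks.reshape(-1, n)[idx]
        sorted_r = np.sort(r_in, axis=1)
        # tie-group sizes via run lengths of equal sorted ranks
        for j, row in enumerate(sorted_r):
            _, counts = np.unique(row, return_counts=True)
            tie_flat[idx[j]] = float((counts.astype(float) ** 3 - counts).sum())
        tie_vol = tie_flat.reshape(shape)
    else:
        tie_vol = None

    rank_sum = np.zeros((*shape, n))
    count = np.zeros(shape)
    tie_sum = np.zeros(shape) if tie_vol is not None else None
    masked_ranks = ranks * m[..., None]
    for off in neighborhood_offsets(params.K):
        shifted_r = _shift(masked_ranks, off)
        shifted_m = _shift(m.astype(float), off)
        rank_sum += shifted_r
        count += shifted_m
        if tie_sum is not None:
            tie_sum += _shift(tie_vol * m, off)

    S = ((rank_sum - rank_sum.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    denom = count**2 * (n**3 - n)
    if tie_sum is not None:
        denom -= count * tie_sum
    valid = m & (count >= params.min_neighbors) & (denom > 0)
    W = np.zeros(shape)
    W[valid] = np.minimum(12.0 * S[valid] / denom[valid], 1.0)
    n_partial = int((m & ~valid).sum())
    return ReHoMap(
        data=W,
        affine=mask.affine,
        standardization="raw",
        params=params,
        valid=valid,
        n_partial=n_partial,
    )


def _shift(arr: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Shift the first three axes by ``offset``, zero-filling the border."""
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    for ax, d in enumerate(offset):
        if d > 0:
            src[ax], dst[ax] = slice(0, arr.shape[ax] - d), slice(d, None)
        elif d < 0:
            src[ax], dst[ax] = slice(-d, None), slice(0, arr.shape[ax] + d)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def standardize_map(
    reho: ReHoMap, mask: BrainMask, mode: str = "divided_by_mean"
) -> ReHoMap:
    """Standardize a raw concordance map across the brain.

    ``divided_by_mean`` divides every voxel by the whole-brain mean W
    (subject-level normalization; in-mask mean becomes exactly 1);
    ``zscore`` subtracts the whole-brain mean and divides by the SD
    (in-mask mean 0, SD 1). Statistics are taken over voxels with complete
    neighborhoods only; flagged partial voxels remain 0.
    """
    if reho.standardization != "raw":
        raise ValueError("can only standardize a raw map")
    if mode not in ("divided_by_mean", "zscore"):
        raise ValueError(f"unknown standardization mode {mode!r}")
    sel = reho.valid & mask.data
    if not sel.any():
        raise ValueError("no valid in-mask voxels to standardize over")
    vals = reho.data[sel]
    out = np.zeros_like(reho.data)
    if mode == "divided_by_mean":
        mu = vals.mean()
        if mu <= 0:
            raise ValueError("in-mask mean concordance is not positive")
        out[sel] = reho.data[sel] / mu
    else:
        mu, sd = vals.mean(), vals.std(ddof=0)
        if sd <= 0:
            raise ValueError("constant map cannot be z-scored")
        out[sel] = (reho.data[sel] - mu) / sd
    return ReHoMap(
        data=out,
        affine=reho.affine,
        standardization=mode,
        params=reho.params,
        valid=reho.valid,
        n_partial=reho.n_partial,
    )
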