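"""Voxel-wise two-sample inference on standardized ReHo maps, plus the
summary-statistic reconstructions used for demographic tables.

Group contrasts use the pooled (equal-variance) two-sample t statistic, the
SPM-family convention. Nuisance covariates (age, gender coded 0/1, years of
education, anxiety score) can be handled two ways:

``residualize``
    Fit the covariate model (with intercept) across all subjects at each
    voxel, t-test the residuals between groups with df = n1 + n2 - 2. This
    mirrors "regress out nuisance covariates, then compare".
``ancova``
    Test the group coefficient in a joint linear model containing the group
    indicator and the covariates; df = n1 + n2 - 2 - (number of covariates).

The two coincide when the covariates are exactly orthogonal to the group
indicator. Voxels with zero pooled variance yield t = 0 and are counted in
``StatMap.n_degenerate`` rather than propagating NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import BrainMask

COVARIATE_NAMES = ["age", "gender", "education", "hama"]


@dataclass
class GroupDesign:
    """Maps and covariates entering one two-sample contrast.

    ``maps`` is an ordered mapping subject id -> standardized 3D map;
    ``membership`` maps subject id -> group label; ``contrast`` orders the
    two labels (positive t = first-listed group higher). ``covariates`` is
    a DataFrame indexed by subject id with numeric columns; required unless
    ``adjustment_mode == 'none'``.
    """

    maps: dict[str, np.ndarray]
    membership: dict[str, str]
    contrast: tuple[str, str]
    covariates: pd.DataFrame | None = None
    adjustment_mode: str = "residualize"  # none | residualize | ancova
    covariate_names: list[str] = field(default_factory=lambda: list(COVARIATE_NAMES))

    def __post_init__(self) -> None:
        if self.adjustment_mode not in ("none", "residualize", "ancova"):
            raise ValueError(f"unknown adjustment_mode {self.adjustment_mode!r}")
        g1, g2 = self.contrast
        ids1 = [s for s, g in self.membership.items() if g == g1 and s in self.maps]
        ids2 = [s for s, g in self.membership.items() if g == g2 and s in self.maps]
        if len(ids1) < 2 or len(ids2) < 2:
            raise ValueError(
                f"each group needs >= 2 subjects with maps "
                f"({g1}: {len(ids1)}, {g2}: {len(ids2)})"
            )
        self._ids1, self._ids2 = ids1, ids2
        if self.adjustment_mode != "none":
            if self.covariates is None:
                raise ValueError("covariates required for adjusted modes")
            missing = [
                s for s in ids1 + ids2
                if s not in self.covariates.index
                or self.covariates.loc[s, self.covariate_names].isna().any()
            ]
            if missing:
                raise ValueError(f"incomplete covariates for subjects: {missing}")

    @property
    def group_ids(self) -> tuple[list[str], list[str]]:
        return self._ids1, self._ids2


@dataclass
class StatMap:
    t: np.ndarray
    affine: np.ndarray
    df: int
    contrast: tuple[str, str]
    n_degenerate: int = 0


@dataclass
class SummaryGroup:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Pooled-variance two-sample t per column; returns (t, df, n_degenerate)."""
    n1, n2 = a.shape[0], b.shape[0]
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(axis=0, ddof=1) + (n2 - 1) * b.var(axis=0, ddof=1)) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = a.mean(axis=0) - b.mean(axis=0)
    degenerate = se <= 0
    t = np.zeros_like(diff)
    ok = ~degenerate
    t[ok] = diff[ok] / se[ok]
    return t, df, int(degenerate.sum())


def voxelwise_ttest(design: GroupDesign, mask: BrainMask) -> StatMap:
    """Per-voxel pooled two-sample t over in-mask voxels, covariate-adjusted
    according to ``design.adjustment_mode``."""
    ids1, ids2 = design.group_ids
    all_ids = ids1 + ids2
    sel = mask.data.reshape(-1)
    Y = np.stack([design.maps[s].reshape(-1)[sel] for s in all_ids])  # (n, V)
    n1, n2 = len(ids1), len(ids2)
    n = n1 + n2

    mode = design.adjustment_mode
    if mode == "none":
        t, df, ndeg = _pooled_t(Y[:n1], Y[n1:])
    elif mode == "residualize":
        C = design.covariates.loc[all_ids, design.covariate_names].to_numpy(float)
        X = np.column_stack([np.ones(n), C])
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        R = Y - X @ beta
        t, df, ndeg = _pooled_t(R[:n1], R[n1:])
    else:  # ancova: group coefficient in the joint model
        C = design.covariates.loc[all_ids, design.covariate_names].to_numpy(float)
        g = np.concatenate([np.ones(n1), np.zeros(n2)])
        X = np.column_stack([np.ones(n), g, C])
        p = X.shape[1]
        df = n - p
        if df < 1:
            raise ValueError("not enough subjects for the ancova model")
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ Y
        resid = Y - X @ beta
        sigma2 = (resid**2).sum(axis=0) / df
        var_g = sigma2 * XtX_inv[1, 1]
        degenerate = var_g <= 0
        t = np.zeros(Y.shape[1])
        ok = ~degenerate
        t[ok] = beta[1, ok] / np.sqrt(var_g[ok])
        ndeg = int(degenerate.sum())

    tmap = np.zeros(mask.data.shape).reshape(-1)
    tmap[sel] = t
    return StatMap(
        t=tmap.reshape(mask.data.shape),
        affine=mask.affine,
        df=df,
        contrast=design.contrast,
        n_degenerate=ndeg,
    )


def critical_t(alpha: float, df: int) -> float:
    """Two-tailed critical value: c with P(|T_df| > c) = alpha."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def anova_from_summary(
    groups: list[SummaryGroup],
) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed exactly from per-group (mean, sd, n).

    SSB = sum n_j (xbar_j - xbar)^2, SSW = sum (n_j - 1) s_j^2.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    N = ns.sum()
    grand = (ns * means).sum() / N
    ssb = (ns * (means - grand) ** 2).sum()
    ssw = ((ns - 1) * sds**2).sum()
    df_b = len(groups) - 1
    df_w = int(N) - len(groups)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), df_b, df_w, p


def ttest_from_summary(a: SummaryGroup, b: SummaryGroup) -> tuple[float, int, float]:
    """Pooled two-sample t from per-group summaries."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    if se <= 0:
        return (0.0, df, 1.0) if a.mean == b.mean else (np.inf, df, 0.0)
    t = (a.mean - b.mean) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), df, p


def chisq_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("table must be a 2-way array of nonnegative counts")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("degenerate margins")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
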