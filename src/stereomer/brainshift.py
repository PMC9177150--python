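"""Imaging-vs-electrophysiology agreement statistics.

Along each trajectory two depth signals are compared: the arctan-transformed
NRMS (electrophysiological activity) and the arctan-transformed *proximity*
to the atlas nucleus (negated distance, so agreement produces a positive
correlation peak).  Their normalized cross-correlation over depth lags gives
a per-trajectory maximum correlation and the lag at which it occurs — the
electrophysiology-based brain-shift estimate.

Group analyses: split trajectories into low/high-lag groups (high = lag more
than one SD above the mean within the best-correlating half), compare the
imaging-based shift between groups with a rank test, correlate lag against
the imaging estimate in the high-lag group, and compare NRMS between the
trajectories closest to and farthest from the nucleus per 0.1 mm depth bin
with Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InsufficientOverlapError
from .models import DEPTH_GRID_MM, DepthProfile, ShiftEstimate

__all__ = [
    "atan_transform",
    "xcorr_max_lag",
    "split_lag_groups",
    "compare_shift_groups",
    "correlate_lag_with_imaging",
    "depth_band_comparison",
    "bh_fdr",
]


def atan_transform(profile: DepthProfile) -> DepthProfile:
    """Elementwise inverse tangent; compresses heavy tails toward ±π/2.

    Missing (NaN) values stay missing.
    """
    return DepthProfile(profile.dtt_mm.copy(), np.arctan(profile.values))


def _grid_offset(a_top: float, b_top: float) -> int:
    k = (a_top - b_top) / DEPTH_GRID_MM
    ki = int(round(k))
    if abs(k - ki) > 1e-6:
        raise ValueError("profiles are not on the same 0.1 mm depth lattice")
    return ki


def xcorr_max_lag(ephys: DepthProfile, anatomy: DepthProfile,
                  max_lag_mm: float = 5.0, min_overlap: int = 20,
                  trajectory_id: str = "") -> ShiftEstimate:
    """Maximum normalized cross-correlation and its depth lag.

    Both profiles must sit on the same 0.1 mm lattice (their extents may
    differ).  At each candidate lag λ the correlation is computed between
    ``ephys(dtt)`` and ``anatomy(dtt − λ)`` over their overlapping non-missing
    bins after z-scoring on the overlap; a positive lag therefore means the
    physiological pattern sits *above* (dorsal to) the imaging-defined one.
    Ties are broken toward the smaller absolute lag.

    Raises :class:`InsufficientOverlapError` when any evaluated lag has
    fewer than ``min_overlap`` overlapping bins.
    """
    e, a = ephys.values, anatomy.values
    base = _grid_offset(anatomy.dtt_mm[0], ephys.dtt_mm[0])
    n_lags = int(round(max_lag_mm / DEPTH_GRID_MM))
    best_r, best_lag = -np.inf, 0.0
    # evaluate in order of increasing |lag| so ties resolve toward zero
    for k in sorted(range(-n_lags, n_lags + 1), key=lambda k: (abs(k), -k)):
        i = np.arange(len(e))
        j = base + i + k  # anatomy index aligned with ephys bin i at lag 0.1k
        ok = (j >= 0) & (j < len(a))
        i, j = i[ok], j[ok]
        valid = np.isfinite(e[i]) & np.isfinite(a[j])
        if valid.sum() < min_overlap:
            raise InsufficientOverlapError(
                f"only {int(valid.sum())} overlapping bins at lag {0.1 * k:+.1f} mm "
                f"(need {min_overlap})")
        x, y = e[i[valid]], a[j[valid]]
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > best_r + 1e-12:
            best_r, best_lag = r, DEPTH_GRID_MM * k
    if not np.isfinite(best_r):
        raise InsufficientOverlapError("no lag produced a defined correlation")
    return ShiftEstimate(trajectory_id, min(max(best_r, -1.0), 1.0), round(best_lag, 6))


@dataclass
class LagGroups:
    """Low/high-lag trajectory groups from the best-correlating half."""

    low: list[ShiftEstimate]
    high: list[ShiftEstimate]
    degenerate: bool = False  # zero lag spread; groups empty


def split_lag_groups(estimates: list[ShiftEstimate], sd_k: float = 1.0) -> LagGroups:
    """Top half by correlation, then split by lag mean + 1 SD.

    The trajectories are sorted by maximum cross-correlation and the better
    half retained (those near the nucleus with clear activity).  Within it,
    the high-lag group holds lags above mean + ``sd_k``·SD; the low-lag
    group is the equally sized set with the smallest lags.
    """
    if len(estimates) < 4:
        raise ValueError("at least 4 trajectories required")
    top = sorted(estimates, key=lambda s: s.max_xcorr, reverse=True)[:len(estimates) // 2]
    lags = np.array([s.lag_mm for s in top])
    sd = lags.std(ddof=1)
    if sd == 0:
        return LagGroups([], [], degenerate=True)
    cut = lags.mean() + sd_k * sd
    high = [s for s in top if s.lag_mm > cut]
    low = sorted(top, key=lambda s: s.lag_mm)[:len(high)]
    return LagGroups(low, high)


def compare_shift_groups(low_shift_mm: np.ndarray, high_shift_mm: np.ndarray,
                         method: str = "ranksum") -> tuple[float, float]:
    """Rank-based comparison of imaging-based shift between lag groups.

    ``ranksum`` (default) is the unpaired Mann-Whitney/Wilcoxon rank-sum
    test, appropriate for two independent groups; ``signed-rank`` pairs the
    groups by lag order and applies Wilcoxon's signed-rank test.  Returns
    ``(statistic, p)``; all-tied data yields p = 1 with a warning.
    """
    x = np.asarray(low_shift_mm, float)
    y = np.asarray(high_shift_mm, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(np.concatenate([x, y]) == np.concatenate([x, y])[0]):
        warnings.warn("all values tied; p = 1", stacklevel=2)
        return 0.0, 1.0
    if method == "ranksum":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    elif method == "signed-rank":
        if len(x) != len(y):
            raise ValueError("signed-rank requires equal group sizes")
        res = stats.wilcoxon(np.sort(x), np.sort(y), alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def correlate_lag_with_imaging(estimates: list[ShiftEstimate],
                               method: str = "pearson") -> tuple[float, float]:
    """Correlation between electrophysiology lag and imaging shift (R, p)."""
    lag = np.array([s.lag_mm for s in estimates])
    img = np.array([s.imaging_shift_mm for s in estimates])
    if len(lag) < 3:
        raise ValueError("at least 3 trajectories required")
    if lag.std() == 0 or img.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(lag, img)
    elif method == "spearman":
        r, p = stats.spearmanr(lag, img)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def bh_fdr(pvals: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg rejection mask at FDR level q."""
    pvals = np.asarray(pvals, float)
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


@dataclass
class DepthBandResult:
    """Per-bin statistics of the closest-vs-farthest trajectory comparison."""

    bins: pd.DataFrame  # dtt_mm, p, significant, n_top, n_bottom
    band_mm: tuple[float, float] | None  # (upper, lower) dtt of the significant band
    median_entry_exit_mm: tuple[float, float] | None = None
    skipped_bins: int = 0


def depth_band_comparison(profiles: list[DepthProfile],
                          stn_distance_mm: np.ndarray,
                          entry_exit_mm: list[tuple[float, float] | None] | None = None,
                          frac: float = 0.2, q: float = 0.01,
                          min_per_group: int = 5) -> DepthBandResult:
    """Compare NRMS of nucleus-near vs nucleus-far trajectories per depth bin.

    Trajectories are sorted by their distance to the nucleus; the closest
    ``frac`` (top 20%) are compared against the farthest ``frac`` (bottom
    20%) at every 0.1 mm normalized-depth bin holding at least
    ``min_per_group`` values per group, using the two-sided rank-sum test.
    Benjamini-Hochberg correction across bins at FDR ``q`` yields the
    significant band.  Also reports the median imaging-defined entry/exit of
    the near group when boundaries are supplied.
    """
    n = len(profiles)
    if n < 10:
        raise ValueError("at least 10 trajectories required")
    dist = np.asarray(stn_distance_mm, float)
    if len(dist) != n:
        raise ValueError("one distance per profile required")
    k = max(1, int(round(frac * n)))
    order = np.argsort(dist, kind="stable")
    top_idx, bottom_idx = order[:k], order[-k:]

    tops = [profiles[i].dtt_mm[0] for i in range(n)]
    bots = [profiles[i].dtt_mm[-1] for i in range(n)]
    hi = max(tops)
    lo = min(bots)
    m = int(round((hi - lo) / DEPTH_GRID_MM)) + 1
    grid = hi - DEPTH_GRID_MM * np.arange(m)

    def gather(indices):
        mat = np.full((len(indices), m), np.nan)
        for row, i in enumerate(indices):
            shift = _grid_offset(hi, profiles[i].dtt_mm[0])
            mat[row, shift:shift + len(profiles[i].values)] = profiles[i].values
        return mat

    top_mat, bot_mat = gather(top_idx), gather(bottom_idx)
    recs = []
    skipped = 0
    for j in range(m):
        a = top_mat[:, j][np.isfinite(top_mat[:, j])]
        b = bot_mat[:, j][np.isfinite(bot_mat[:, j])]
        if len(a) < min_per_group or len(b) < min_per_group:
            skipped += 1
            continue
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        recs.append({"dtt_mm": grid[j], "p": p, "n_top": len(a), "n_bottom": len(b)})
    bins = pd.DataFrame(recs)
    if len(bins):
        bins["significant"] = bh_fdr(bins["p"].to_numpy(), q)
    else:
        bins["significant"] = pd.Series(dtype=bool)
    band = None
    if len(bins) and bins["significant"].any():
        sig_d = bins.loc[bins["significant"], "dtt_mm"]
        band = (float(sig_d.max()), float(sig_d.min()))
    med_ee = None
    if entry_exit_mm is not None:
        pairs = [entry_exit_mm[i] for i in top_idx if entry_exit_mm[i] is not None]
        if pairs:
            med_ee = (float(np.median([p[0] for p in pairs])),
                      float(np.median([p[1] for p in pairs])))
    return DepthBandResult(bins, band, med_ee, skipped)
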