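"""BOLD functional coupling of tumour habitats with the global signal.

The global signal (GS) is the frame-wise mean BOLD over healthy grey
matter, excluding the tumour (and, for the contralateral analysis, the
mirrored tumour region as well). Coupling of a region with the GS is the
slope of a linear regression between the two series; by default both
series are standardized to unit variance so the slope is symmetric in the
two series and equals their Pearson correlation. Slopes whose FDR-adjusted
p exceeds 0.05 are set to 0 (no evidence of coupling), with the raw value
retained. Habitats are compared with a Friedman test followed by pairwise
Wilcoxon signed-rank tests under FDR correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .cognition import bh_fdr
from .grids import MaskVolume, VolumeGrid, check_same_grid

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingEstimate",
    "CouplingComparisonReport",
    "global_signal",
    "band_filter",
    "scrub_frames",
    "coupling_beta",
    "per_voxel_beta",
    "zero_nonsignificant",
    "compare_coupling",
]

MIN_FRAMES = 50


def global_signal(
    bold: VolumeGrid,
    gm: MaskVolume,
    tumour: MaskVolume,
    also_exclude: MaskVolume | None = None,
) -> np.ndarray:
    """Frame-wise mean BOLD over gm minus tumour (minus also_exclude)."""
    check_same_grid(bold, gm, tumour)
    healthy = gm.data & ~tumour.data
    if also_exclude is not None:
        check_same_grid(bold, also_exclude)
        healthy &= ~also_exclude.data
    if not healthy.any():
        raise ValueError("no healthy grey-matter voxels left for the global signal")
    if bold.data.ndim != 4:
        raise ValueError("BOLD series must be 4-D")
    return bold.data[healthy].mean(axis=0)


def band_filter(
    ts: np.ndarray, tr: float, low: float = 0.03, high: float = 0.12,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Forward-backward filtering doubles the effective order and cancels the
    phase shift, so in-band oscillations keep their timing while energy an
    octave outside the band is attenuated by tens of dB.
    """
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[-1]
    if n < 64:
        raise ValueError(f"series too short to filter ({n} frames)")
    nyquist = 0.5 / tr
    if low >= nyquist:
        raise ValueError(f"band ({low}-{high} Hz) infeasible at TR={tr}s")
    high = min(high, 0.99 * nyquist)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr,
                        output="sos")
    # mirror the series before filtering: the forward-backward pass then
    # settles before reaching the retained segment, taming edge transients
    ext = np.concatenate([ts[..., ::-1], ts, ts[..., ::-1]], axis=-1)
    return signal.sosfiltfilt(sos, ext, axis=-1)[..., n:2 * n]


def scrub_frames(fd: np.ndarray, threshold: float = 0.5) -> tuple[np.ndarray, bool]:
    """Indices of frames with framewise displacement <= threshold (mm).

    Returns (retained_indices, flagged); flagged is True when more than
    half the frames were motion-corrupted.
    """
    fd = np.asarray(fd, dtype=float)
    retained = np.flatnonzero(fd <= threshold)
    flagged = len(retained) < 0.5 * len(fd)
    if flagged:
        logger.warning("scrubbing dropped %d/%d frames: subject flagged",
                       len(fd) - len(retained), len(fd))
    return retained, flagged


@dataclass
class CouplingEstimate:
    """Regression slope of a region's BOLD signal against the GS."""

    region: str
    beta: float
    p: float
    raw_beta: float = field(default=np.nan)
    p_fdr: float = np.nan
    zeroed: bool = False

    def __post_init__(self) -> None:
        if np.isnan(self.raw_beta):
            self.raw_beta = self.beta


def _autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    full = np.correlate(x, x, mode="full")[len(x) - 1:]
    return full[: max_lag + 1] / full[0]


def effective_n(x: np.ndarray, y: np.ndarray) -> float:
    """Bartlett effective sample size for the correlation of two series.

    Band-limited BOLD series are strongly autocorrelated, which inflates
    the nominal degrees of freedom of the slope t-test; the classical
    correction divides n by 1 + 2 * sum_k rho_x(k) * rho_y(k).
    """
    n = len(x)
    max_lag = n // 4
    rx = _autocorr(x, max_lag)
    ry = _autocorr(y, max_lag)
    denom = 1.0 + 2.0 * float((rx[1:] * ry[1:]).sum())
    denom = max(denom, 1.0)
    return float(np.clip(n / denom, 5.0, n))


def coupling_beta(
    region_ts: np.ndarray,
    gs_ts: np.ndarray,
    region: str = "",
    standardized: bool = True,
    dof_correction: str = "bartlett",
) -> CouplingEstimate:
    """Slope (with t-test p) of the region series regressed on the GS.

    In the default standardized mode both series are scaled to unit
    variance first, so beta equals the Pearson correlation and is
    comparable across regions of different signal amplitude. The slope
    p-value uses Bartlett's effective sample size by default, which keeps
    the test calibrated on autocorrelated (band-limited) series; pass
    ``dof_correction="naive"`` for the iid t-test.
    """
    region_ts = np.asarray(region_ts, float)
    gs_ts = np.asarray(gs_ts, float)
    if region_ts.shape != gs_ts.shape or region_ts.ndim != 1:
        raise ValueError("series must be 1-D and equally long")
    if len(gs_ts) < MIN_FRAMES:
        raise ValueError(f"need >= {MIN_FRAMES} retained frames")
    if np.std(gs_ts) == 0 or np.std(region_ts) == 0:
        raise ValueError("zero-variance series")
    if standardized:
        region_ts = (region_ts - region_ts.mean()) / region_ts.std()
        gs_ts = (gs_ts - gs_ts.mean()) / gs_ts.std()
    res = stats.linregress(gs_ts, region_ts)
    r = float(np.clip(res.rvalue, -1.0, 1.0))
    if dof_correction == "bartlett":
        n_eff = effective_n(region_ts, gs_ts)
    else:
        n_eff = float(len(gs_ts))
    df = max(n_eff - 2.0, 1.0)
    if 1.0 - r * r < 1e-15:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CouplingEstimate(region=region, beta=float(res.slope), p=p)


def per_voxel_beta(
    bold: VolumeGrid,
    tumour: MaskVolume,
    gs_ts: np.ndarray,
    retained: np.ndarray | None = None,
    standardized: bool = True,
) -> VolumeGrid:
    """Map of coupling slopes for every tumour voxel (0 outside the mask)."""
    check_same_grid(bold, tumour)
    sig = bold.data[tumour.data]            # (n_vox, frames)
    gs = np.asarray(gs_ts, float)
    if retained is not None:
        sig = sig[:, retained]
        gs = gs[retained]
    if standardized:
        sd = sig.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        sig = (sig - sig.mean(axis=1, keepdims=True)) / sd
        gs = (gs - gs.mean()) / gs.std()
    betas = sig @ gs / (gs @ gs)
    out = np.zeros(tumour.shape, dtype=float)
    out[tumour.data] = betas
    return VolumeGrid(data=out, affine=tumour.affine)


def zero_nonsignificant(
    estimates: list[CouplingEstimate], alpha: float = 0.05
) -> list[CouplingEstimate]:
    """BH-FDR across one family of estimates; zero slopes with p_fdr > alpha.

    The raw slope is retained in ``raw_beta`` so zeroing is reversible.
    """
    if not estimates:
        return estimates
    adj = bh_fdr([e.p for e in estimates])
    for e, p in zip(estimates, adj):
        e.p_fdr = float(p)
        e.raw_beta = e.beta if not e.zeroed else e.raw_beta
        if p > alpha:
            e.beta = 0.0
            e.zeroed = True
        else:
            e.beta = e.raw_beta
            e.zeroed = False
    n_zero = sum(e.zeroed for e in estimates)
    logger.info("zeroed %d/%d non-significant couplings", n_zero, len(estimates))
    return estimates


@dataclass
class CouplingComparisonReport:
    """Friedman comparison of coupling across habitats plus Wilcoxon post-hocs."""

    chi2: float
    df: int
    p: float
    posthoc: pd.DataFrame    # columns: a, b, z, p, p_fdr


def compare_coupling(beta_table: pd.DataFrame) -> CouplingComparisonReport:
    """Compare slopes across conditions (columns) within subjects (rows).

    Requires complete rows; incomplete subjects are named in the error so
    the caller can decide to drop them explicitly.
    """
    bad = beta_table.index[beta_table.isna().any(axis=1)].tolist()
    if bad:
        raise ValueError(f"incomplete coupling rows for subjects: {bad}")
    cols = list(beta_table.columns)
    if len(cols) < 3:
        raise ValueError("Friedman test needs >= 3 conditions")
    arrays = [beta_table[c].to_numpy() for c in cols]
    if all(np.allclose(a, arrays[0]) for a in arrays[1:]):
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.friedmanchisquare(*arrays)
    rows = []
    for a, b in itertools.combinations(cols, 2):
        diff = beta_table[a].to_numpy() - beta_table[b].to_numpy()
        if np.allclose(diff, 0):
            z, pw = 0.0, 1.0
        else:
            res = stats.wilcoxon(diff, method="approx")
            pw = float(res.pvalue)
            z = float(np.sign(np.median(diff)) * abs(stats.norm.isf(pw / 2)))
        rows.append({"a": a, "b": b, "z": z, "p": pw})
    posthoc = pd.DataFrame(rows)
    posthoc["p_fdr"] = bh_fdr(posthoc["p"].to_numpy())
    return CouplingComparisonReport(
        chi2=float(chi2), df=len(cols) - 1, p=float(p), posthoc=posthoc
    )
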