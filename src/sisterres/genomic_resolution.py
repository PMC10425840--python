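"""Genomic resolution score from sister-phased Hi-C contacts.

The cis/trans sister contact ratio — average same-chromatid contact
probability divided by average inter-sister contact probability at the
same genomic distance — is high at short range (sisters are locally
resolved) and decays towards 1 at long range (cis and trans contacts
equally likely, sisters intermixed).  The genomic resolution score of a
sample is the first genomic distance, scanning from short to long, at
which the smoothed ratio curve comes down to a threshold of 1.25
(slightly above noise): the genomic range over which sister chromatids
are resolved.

The pipeline: equal-total downsampling across samples (so curves are
comparable at matched depth), log-binned cis and trans contact-frequency
(scaling) curves, their ratio, cubic-spline interpolation of the ratio
against log distance, Savitzky-Golay smoothing, and threshold
first-crossing with linear interpolation between grid points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

logger = logging.getLogger("sisterres.resolution")

__all__ = [
    "ScalingCurve", "RatioCurve", "ResolutionScore",
    "default_bin_edges", "downsample_equal", "scaling_curve", "ratio_curve",
    "genomic_resolution", "resolution_report",
]

DEFAULT_THRESHOLD = 1.25
MIN_SEPARATION = 1_000          # bp; shorter contacts are ignored throughout
BIN_FACTOR = 2.0 ** (1.0 / 3.0)  # three log-spaced bins per octave


@dataclass
class ScalingCurve:
    """Per-distance-bin average contact probability, split by phase.

    Counts are normalized by the bin span in bp and by the total number
    of qualifying contacts (cis + trans together, so the cis/trans ratio
    of a bin equals its count ratio).
    """

    bin_edges: np.ndarray
    cis_prob: np.ndarray
    trans_prob: np.ndarray
    n_cis: np.ndarray
    n_trans: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])


@dataclass
class RatioCurve:
    """Cis/trans ratio at the geometric bin centers; invalid bins masked."""

    distances: np.ndarray
    ratio: np.ndarray
    valid: np.ndarray


@dataclass
class ResolutionScore:
    threshold: float
    resolution_bp: float | None
    status: str                 # resolved | never_above_threshold | never_crossed
    sample: str = ""


def default_bin_edges(max_dist: float, first_edge: float = MIN_SEPARATION,
                      factor: float = BIN_FACTOR) -> np.ndarray:
    """Log-spaced bin edges from 1 kb to just past the longest distance."""
    n = int(np.ceil(np.log(max_dist / first_edge) / np.log(factor))) + 1
    return first_edge * factor ** np.arange(n + 1)


def _qualifying(table: pd.DataFrame, min_sep: int) -> pd.Series:
    return (table["pos2"] - table["pos1"]) > min_sep


def downsample_equal(tables: list[pd.DataFrame], min_sep: int = MIN_SEPARATION,
                     seed: int = 0) -> list[pd.DataFrame]:
    """Subsample each table so qualifying totals match the smallest sample.

    Qualifying contacts (cis + trans at distance > ``min_sep``) are
    subsampled without replacement to the minimum total across tables;
    sub-threshold contacts are dropped (the scaling curves exclude them
    anyway).  Deterministic given the seed.
    """
    totals = []
    for i, t in enumerate(tables):
        n = int(_qualifying(t, min_sep).sum())
        if n == 0:
            raise ValueError(f"table {i} has no contacts beyond {min_sep} bp")
        totals.append(n)
    target = min(totals)
    rng = np.random.default_rng(seed)
    out = []
    for t, n in zip(tables, totals):
        qual = t[_qualifying(t, min_sep)]
        if n == target:
            out.append(qual.reset_index(drop=True))
        else:
            idx = rng.choice(n, size=target, replace=False)
            out.append(qual.iloc[np.sort(idx)].reset_index(drop=True))
    logger.info("downsampled %d tables to %d qualifying contacts each",
                len(tables), target)
    return out


def scaling_curve(table: pd.DataFrame,
                  bin_edges: np.ndarray | None = None) -> ScalingCurve:
    """Binned average contact probability per phase.

    Contacts below the first edge are excluded; each bin's count is
    divided by its span in bp and by the total qualifying contact count.
    """
    if len(table) == 0:
        raise ValueError("empty contact table")
    dist = (table["pos2"] - table["pos1"]).to_numpy()
    if bin_edges is None:
        bin_edges = default_bin_edges(max(dist.max(), MIN_SEPARATION * 2))
    bin_edges = np.asarray(bin_edges, dtype=np.float64)
    keep = dist >= bin_edges[0]
    dist = dist[keep]
    phase = table["phase"].to_numpy()[keep]
    if dist.size == 0:
        raise ValueError("no contacts at or beyond the first bin edge")
    n_cis, _ = np.histogram(dist[phase == "cis"], bins=bin_edges)
    n_trans, _ = np.histogram(dist[phase == "trans"], bins=bin_edges)
    spans = np.diff(bin_edges)
    total = dist.size
    return ScalingCurve(bin_edges=bin_edges,
                        cis_prob=n_cis / (spans * total),
                        trans_prob=n_trans / (spans * total),
                        n_cis=n_cis, n_trans=n_trans)


def ratio_curve(scaling: ScalingCurve) -> RatioCurve:
    """Elementwise cis/trans probability ratio on bins where both are > 0."""
    valid = (scaling.cis_prob > 0) & (scaling.trans_prob > 0)
    ratio = np.full(valid.shape, np.nan)
    ratio[valid] = scaling.cis_prob[valid] / scaling.trans_prob[valid]
    return RatioCurve(distances=scaling.bin_centers, ratio=ratio, valid=valid)


def genomic_resolution(ratio: RatioCurve, threshold: float = DEFAULT_THRESHOLD,
                       savgol_window: int = 5, savgol_order: int = 2,
                       grid_points: int = 500) -> ResolutionScore:
    """First genomic distance at which the smoothed ratio reaches the threshold.

    The valid bins are interpolated with a cubic spline of ratio against
    log10(distance) on a dense grid, smoothed with a Savitzky-Golay
    filter, and scanned short → long for the first grid point at or
    below the threshold; the crossing is linearly interpolated between
    grid points.  A curve already at/below threshold at its short end
    reports ``never_above_threshold`` with resolution 0; one that never
    descends to the threshold reports ``never_crossed``.
    """
    if threshold <= 1.0:
        raise ValueError("threshold must exceed 1")
    x = np.log10(ratio.distances[ratio.valid])
    y = ratio.ratio[ratio.valid]
    if x.size < 5:
        raise ValueError(f"need >= 5 valid bins, got {x.size}")
    spline = CubicSpline(x, y)
    grid = np.linspace(x[0], x[-1], grid_points)
    smooth = savgol_filter(spline(grid), window_length=savgol_window,
                           polyorder=savgol_order)
    below = smooth <= threshold
    if below[0]:
        return ResolutionScore(threshold=threshold, resolution_bp=0.0,
                               status="never_above_threshold")
    if not below.any():
        return ResolutionScore(threshold=threshold, resolution_bp=None,
                               status="never_crossed")
    i = int(np.argmax(below))
    x0, x1 = grid[i - 1], grid[i]
    y0, y1 = smooth[i - 1], smooth[i]
    xc = x0 + (threshold - y0) * (x1 - x0) / (y1 - y0)
    return ResolutionScore(threshold=threshold, resolution_bp=float(10 ** xc),
                           status="resolved")


def resolution_report(tables: dict[str, pd.DataFrame],
                      threshold: float = DEFAULT_THRESHOLD,
                      min_sep: int = MIN_SEPARATION,
                      downsample: bool = True, seed: int = 0,
                      bin_edges: np.ndarray | None = None,
                      savgol_window: int = 5, savgol_order: int = 2,
                      ) -> tuple[list[ResolutionScore], pd.DataFrame]:
    """Per-sample resolution scores plus the underlying curves.

    With more than one table the samples are first downsampled to equal
    qualifying totals.  Returns the scores and a long-format curve table
    (sample, distance_bp, cis_prob, trans_prob, ratio).
    """
    names = list(tables)
    tbls = [tables[n] for n in names]
    if downsample and len(tbls) > 1:
        tbls = downsample_equal(tbls, min_sep=min_sep, seed=seed)
    scores, curves = [], []
    for name, t in zip(names, tbls):
        sc = scaling_curve(t, bin_edges)
        rc = ratio_curve(sc)
        score = genomic_resolution(rc, threshold=threshold,
                                   savgol_window=savgol_window,
                                   savgol_order=savgol_order)
        score.sample = name
        scores.append(score)
        curves.append(pd.DataFrame({
            "sample": name, "distance_bp": sc.bin_centers,
            "cis_prob": sc.cis_prob, "trans_prob": sc.trans_prob,
            "ratio": rc.ratio}))
    return scores, pd.concat(curves, ignore_index=True)
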