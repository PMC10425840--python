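"""Cross-axis line-profile analysis of sister DNA around SMC protein axes.

Lines are drawn perpendicularly across a chromosome's SMC (cohesin or
condensin) axis, always from the labelled chromatid towards the
unlabelled one, and sampled in three channels: the SMC axis protein, the
single-sister nucleotide label, and the general DNA stain.  Because only
one sister carries the label, the unlabelled sister's profile is
recovered by subtracting the normalized label signal from the normalized
DNA signal wherever the label exceeds the DNA, then renormalizing.
Polynomial fits smooth each channel; peak counts classify the profile
(single axis expects one SMC peak, split axes expect two; both expect
exactly one label peak and one DNA-minus-label peak); accepted profiles
yield the sister DNA peak-to-peak distance and the signed radial
displacement of the labelled sister relative to the nearest axis
(positive = outward, towards the labelled side the line starts from).
Per-cell percentage summaries aggregate manually measured axis-segment
and fragment lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .io_formats import ProfileRecord

__all__ = [
    "NormalizedProfile", "PeakSet", "PeakParams", "ProfileMeasurement",
    "AxisSegmentMeasurement", "FragmentMeasurement",
    "minmax_normalize", "dna_minus_label", "fit_and_find_peaks",
    "classify_profile", "peak_to_peak", "radial_displacement",
    "measure_profile", "align_profiles", "percent_split_axes",
    "percent_labelled_fragments",
]


class ProfileRejected(ValueError):
    """Raised when a profile cannot be normalized or fitted."""


@dataclass
class NormalizedProfile:
    """A profile with each channel min/max-scaled to [0, 1].

    Carries the derived ``dna_minus_label`` channel once computed.
    """

    cell_id: str
    line_id: str
    positions: np.ndarray
    channels: dict[str, np.ndarray]


@dataclass
class PeakSet:
    """Fitted-curve peaks per channel: positions (µm) and heights in [0, 1]."""

    positions: dict[str, np.ndarray]
    heights: dict[str, np.ndarray]

    def count(self, channel: str) -> int:
        return len(self.positions.get(channel, ()))


@dataclass
class PeakParams:
    """Polynomial-fit and peak-detection settings.

    The fit degree is capped at one third of the sample count so short
    profiles are not interpolated through their noise; prominence and
    height thresholds act on the [0, 1] fitted curve.
    """

    fit_degree: int = 10
    degree_cap_divisor: int = 3
    prominence: float = 0.1
    height: float = 0.2
    grid_oversample: int = 10


@dataclass
class ProfileMeasurement:
    line_id: str
    cell_id: str
    mode: str                               # single | split
    accepted: bool
    reason: str = ""
    dna_peak_distance: float | None = None  # µm
    radial_displacement: float | None = None  # µm, signed; + = outward
    peaks: PeakSet | None = field(default=None, repr=False)
    tie_broken: bool = False


@dataclass
class AxisSegmentMeasurement:
    """Measured lengths (µm) of one traced axis line."""

    cell_id: str
    total_axis_length: float
    split_length: float
    single_length: float


@dataclass
class FragmentMeasurement:
    """Lengths (µm) of 0/1/2-sister-labelled fragments within one line."""

    cell_id: str
    lengths: dict[int, float]   # class (0, 1 or 2) -> length


# ---------------------------------------------------------------------------
# Normalization and subtraction
# ---------------------------------------------------------------------------

def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise ProfileRejected("constant channel cannot be min/max normalized")
    return (v - lo) / (hi - lo)


def minmax_normalize(profile: ProfileRecord) -> NormalizedProfile:
    """Min/max-scale every channel to [0, 1], removing raw-intensity scale."""
    channels = {role: _minmax(vals) for role, vals in profile.intensities.items()}
    return NormalizedProfile(cell_id=profile.cell_id, line_id=profile.line_id,
                             positions=profile.positions.copy(), channels=channels)


def dna_minus_label(norm: NormalizedProfile) -> np.ndarray:
    """Recover the unlabelled-sister DNA profile.

    Where the normalized label exceeds the normalized DNA, the label is
    subtracted from the DNA; elsewhere the DNA value is kept.  The result
    is min/max-normalized again and stored as the ``dna_minus_label``
    channel.
    """
    dna = norm.channels["dna"]
    lab = norm.channels["label"]
    out = np.where(lab > dna, dna - lab, dna)
    out = _minmax(out)
    norm.channels["dna_minus_label"] = out
    return out


# ---------------------------------------------------------------------------
# Fitting, peaks, classification
# ---------------------------------------------------------------------------

def fit_and_find_peaks(norm: NormalizedProfile, channel: str,
                       params: PeakParams | None = None) -> PeakSet:
    """Fit a least-squares polynomial to one channel and find its peaks.

    The fitted curve is evaluated on a grid ``grid_oversample`` times
    denser than the native sampling; local maxima passing the prominence
    and height thresholds are returned sorted by position, with heights
    clipped into [0, 1].
    """
    params = params or PeakParams()
    x = norm.positions
    y = norm.channels[channel]
    deg = min(params.fit_degree, max(x.size // params.degree_cap_divisor, 1))
    if x.size < deg + 2:
        raise ProfileRejected(f"{x.size} samples too few for degree-{deg} fit")
    # fit on a centred/scaled abscissa for conditioning
    with np.errstate(all="ignore"):
        series = np.polynomial.Polynomial.fit(x, y, deg)
    coef = series.convert().coef
    if not np.all(np.isfinite(coef)):
        raise ProfileRejected("ill-conditioned polynomial fit")
    grid = np.linspace(x[0], x[-1], x.size * params.grid_oversample)
    curve = series(grid)
    idx, _ = find_peaks(curve, prominence=params.prominence, height=params.height)
    order = np.argsort(grid[idx])
    return PeakSet(positions={channel: grid[idx][order]},
                   heights={channel: np.clip(curve[idx][order], 0.0, 1.0)})


def peaks_all_channels(norm: NormalizedProfile,
                       params: PeakParams | None = None) -> PeakSet:
    """Peaks for the smc, label and dna_minus_label channels of one profile."""
    if "dna_minus_label" not in norm.channels:
        dna_minus_label(norm)
    positions, heights = {}, {}
    for ch in ("smc", "label", "dna_minus_label"):
        ps = fit_and_find_peaks(norm, ch, params)
        positions[ch] = ps.positions[ch]
        heights[ch] = ps.heights[ch]
    return PeakSet(positions=positions, heights=heights)


def classify_profile(peaks: PeakSet, mode: str) -> tuple[bool, str]:
    """Accept or reject a profile from its per-channel peak counts.

    ``single`` mode (one expected axis) accepts (smc, label,
    dna_minus_label) counts of (1, 1, 1); ``split`` mode accepts
    (2, 1, 1).  Everything else is rejected with the counts in the
    reason.
    """
    if mode not in ("single", "split"):
        raise ValueError(f"unknown mode {mode!r}")
    counts = (peaks.count("smc"), peaks.count("label"),
              peaks.count("dna_minus_label"))
    want = (1, 1, 1) if mode == "single" else (2, 1, 1)
    if counts == want:
        return True, ""
    return False, (f"peak counts smc={counts[0]}, label={counts[1]}, "
                   f"dna_minus_label={counts[2]}; expected {want} for {mode}")


def peak_to_peak(peaks: PeakSet) -> float:
    """Sister DNA peak-to-peak distance |dna_minus_label peak - label peak| (µm)."""
    lab = peaks.positions["label"]
    dml = peaks.positions["dna_minus_label"]
    if len(lab) != 1 or len(dml) != 1:
        raise ValueError("peak_to_peak needs exactly one label and one "
                         "dna_minus_label peak")
    return float(abs(dml[0] - lab[0]))


def radial_displacement(peaks: PeakSet, mode: str) -> tuple[float, bool]:
    """Signed distance from the label peak to the nearest SMC axis peak (µm).

    Lines run labelled → unlabelled, so a label peak at a lower position
    than its nearest axis lies outward of the chromosome midline:
    ``d = pos(nearest smc peak) - pos(label peak)``, positive = outward.
    For split axes the nearer of the two is used; an exact tie is broken
    towards the lower-position axis and flagged.
    """
    lab = peaks.positions["label"]
    smc = peaks.positions["smc"]
    n_expected = 1 if mode == "single" else 2
    if len(lab) != 1 or len(smc) != n_expected:
        raise ValueError(f"radial_displacement needs 1 label and {n_expected} "
                         f"smc peaks for mode {mode!r}")
    dists = np.abs(smc - lab[0])
    tie = len(smc) == 2 and np.isclose(dists[0], dists[1])
    # exact ties (to float tolerance) break towards the lower-position axis
    nearest = smc[0] if tie else smc[int(np.argmin(dists))]
    return float(nearest - lab[0]), bool(tie)


def measure_profile(record: ProfileRecord, mode: str,
                    params: PeakParams | None = None) -> ProfileMeasurement:
    """Normalize, subtract, fit, classify and measure one profile.

    Rejected profiles are returned with ``accepted=False`` and the
    reason, never dropped.
    """
    try:
        norm = minmax_normalize(record)
        peaks = peaks_all_channels(norm, params)
    except ProfileRejected as exc:
        return ProfileMeasurement(line_id=record.line_id, cell_id=record.cell_id,
                                  mode=mode, accepted=False, reason=str(exc))
    ok, reason = classify_profile(peaks, mode)
    if not ok:
        return ProfileMeasurement(line_id=record.line_id, cell_id=record.cell_id,
                                  mode=mode, accepted=False, reason=reason,
                                  peaks=peaks)
    d = peak_to_peak(peaks)
    r, tie = radial_displacement(peaks, mode)
    return ProfileMeasurement(line_id=record.line_id, cell_id=record.cell_id,
                              mode=mode, accepted=True, dna_peak_distance=d,
                              radial_displacement=r, peaks=peaks, tie_broken=tie)


# ---------------------------------------------------------------------------
# Alignment and per-cell summaries
# ---------------------------------------------------------------------------

def align_profiles(profiles: Sequence[NormalizedProfile], mode: str,
                   params: PeakParams | None = None,
                   channels: Sequence[str] = ("label", "dna_minus_label"),
                   ) -> dict[str, np.ndarray]:
    """Mean channel curves re-centered on the SMC axis anchor.

    Each profile is shifted so its anchor — the single SMC peak, or the
    midpoint of the two SMC peaks for split axes — sits at position 0,
    then linearly interpolated onto a common grid whose spacing is the
    median native step.  Returns the grid, per-channel mean curves, and
    the per-position profile count ``n``.
    """
    if not profiles:
        raise ValueError("align_profiles needs at least one profile")
    anchors, shifted = [], []
    for p in profiles:
        if "dna_minus_label" in channels and "dna_minus_label" not in p.channels:
            dna_minus_label(p)
        smc = fit_and_find_peaks(p, "smc", params).positions["smc"]
        want = 1 if mode == "single" else 2
        if len(smc) != want:
            continue
        anchor = smc[0] if mode == "single" else float(np.mean(smc))
        anchors.append(anchor)
        shifted.append((p.positions - anchor, p))
    if not shifted:
        raise ValueError("no profile had the expected SMC peak count")
    steps = [np.median(np.diff(pos)) for pos, _ in shifted]
    dx = float(np.median(steps))
    lo = min(pos[0] for pos, _ in shifted)
    hi = max(pos[-1] for pos, _ in shifted)
    grid = np.arange(np.floor(lo / dx), np.ceil(hi / dx) + 1) * dx

    out: dict[str, np.ndarray] = {"position": grid}
    n_any = np.zeros(grid.size)
    sums = {ch: np.zeros(grid.size) for ch in channels}
    counts = {ch: np.zeros(grid.size) for ch in channels}
    for pos, p in shifted:
        inside = (grid >= pos[0]) & (grid <= pos[-1])
        n_any += inside
        for ch in channels:
            vals = np.interp(grid[inside], pos, p.channels[ch])
            sums[ch][inside] += vals
            counts[ch][inside] += 1
    for ch in channels:
        with np.errstate(invalid="ignore"):
            out[ch] = np.where(counts[ch] > 0, sums[ch] / counts[ch], np.nan)
    out["n"] = n_any
    return out


def percent_split_axes(measurements: Sequence[AxisSegmentMeasurement],
                       ) -> dict[str, float]:
    """Per-cell percentage of SMC axis length that is split.

    100 · split / (split + single); cells with zero measured length are
    skipped.
    """
    split: dict[str, float] = {}
    single: dict[str, float] = {}
    for m in measurements:
        split[m.cell_id] = split.get(m.cell_id, 0.0) + m.split_length
        single[m.cell_id] = single.get(m.cell_id, 0.0) + m.single_length
    out = {}
    for cell in split:
        total = split[cell] + single[cell]
        if total <= 0:
            continue
        out[cell] = 100.0 * split[cell] / total
    return out


def percent_labelled_fragments(measurements: Sequence[FragmentMeasurement],
                               ) -> dict[str, dict[int, float]]:
    """Per-cell percentage of line length in 0/1/2-sister-labelled fragments.

    Percentages per cell sum to 100; cells with zero total length are
    skipped.
    """
    totals: dict[str, dict[int, float]] = {}
    for m in measurements:
        cell = totals.setdefault(m.cell_id, {0: 0.0, 1: 0.0, 2: 0.0})
        for cls, length in m.lengths.items():
            if cls not in (0, 1, 2):
                raise ValueError(f"fragment class must be 0, 1 or 2, got {cls}")
            cell[cls] += length
    out = {}
    for cell, lens in totals.items():
        total = sum(lens.values())
        if total <= 0:
            continue
        out[cell] = {cls: 100.0 * v / total for cls, v in lens.items()}
    return out
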