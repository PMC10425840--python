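"""Synthetic 3D sister-chromatid image phantoms with known ground truth.

A phantom emulates a replicated mitotic chromosome imaged in three
fluorescence channels:

* ``dna``   — a general DNA stain seeing both sister chromatids,
* ``label`` — a nucleotide-analogue label carried by one sister (after one
  labelled S phase plus one unlabelled cycle) or, as a control, by both,
* ``smc``   — an SMC-protein (cohesin/condensin) axis: a thin ridge either
  at the chromosome midline (unresolved, "single" axis) or at both sister
  centerlines ("split" axes).

Each chromatid is a tube with Gaussian cross-section following a smooth
centerline; the two sisters run parallel at a controlled center-to-center
distance.  Rendering deposits the centerlines onto the voxel grid,
convolves with the tube cross-section and then with an anisotropic
Gaussian point-spread function, and finally applies Poisson shot noise
plus additive Gaussian read noise.  Everything downstream of a seed is
deterministic, and the generator returns the exact geometry used, so the
image pipelines can be validated against known separations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter, map_coordinates

from .io_formats import GeometryError, ImageStack, ProfileRecord

__all__ = [
    "PhantomSpec", "GroundTruth", "generate_phantom", "generate_population",
    "sample_ground_truth_profiles", "default_centerline",
]

# PSF sigmas (nm) approximating processed super-resolution confocal data.
DEFAULT_PSF_SIGMA = (250.0, 90.0, 90.0)  # (z, y, x)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic sister-chromatid stack.

    All lengths are nanometres.  ``separation_d`` is the center-to-center
    sister distance; ``tube_sigma`` the Gaussian cross-section of each
    chromatid; ``axis_sigma`` the (thinner) SMC-axis ridge.  ``background``
    is relative to the tube peak and scales with each channel's amplitude,
    so noiseless channels of identical geometry stay exactly proportional.
    """

    shape: tuple[int, int, int] = (13, 72, 72)          # (z, y, x) voxels
    voxel_size: tuple[float, float, float] = (150.0, 50.0, 50.0)
    centerline: np.ndarray | None = None                 # (n, 3) nm, (z, y, x)
    separation_d: float = 600.0
    tube_sigma: float = 200.0
    axis_sigma: float = 80.0
    label_mode: str = "one_sister"                       # one_sister | two_sister
    axis_mode: str = "single"                            # single | split
    label_quench: float = 0.5                            # dna-stain dimming on labelled sisters
    amplitude: dict[str, float] = field(
        default_factory=lambda: {"dna": 1000.0, "label": 800.0, "smc": 600.0})
    background: float = 0.1
    psf_sigma: tuple[float, float, float] = DEFAULT_PSF_SIGMA
    poisson: bool = True
    gaussian_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation_d < 0:
            raise ValueError("separation_d must be >= 0")
        if self.tube_sigma <= 0:
            raise ValueError("tube_sigma must be > 0")
        if self.label_mode not in ("one_sister", "two_sister"):
            raise ValueError(f"unknown label_mode {self.label_mode!r}")
        if self.axis_mode not in ("single", "split"):
            raise ValueError(f"unknown axis_mode {self.axis_mode!r}")
        if not 0.0 <= self.label_quench < 1.0:
            raise ValueError("label_quench must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Exact geometry of a generated phantom, in nm grid coordinates."""

    true_separation_d: float
    sister1_centerline: np.ndarray   # (n, 3) nm, labelled sister
    sister2_centerline: np.ndarray
    axis_centerlines: list[np.ndarray]
    label_assignment: int = 1        # which sister carries the label
    midline: np.ndarray | None = None


def default_centerline(shape: Sequence[int],
                       voxel_size: Sequence[float],
                       length_frac: float = 0.16,
                       bow: float = 0.05) -> np.ndarray:
    """Control points for a gently bowed path along x through the volume center."""
    nz, ny, nx = shape
    ez, ey, ex = nz * voxel_size[0], ny * voxel_size[1], nx * voxel_size[2]
    half = length_frac * ex
    xs = np.linspace(-half, half, 7)
    ys = bow * ey * np.cos(np.pi * xs / (2 * half))
    pts = np.column_stack([np.zeros_like(xs), ys, xs])
    center = np.array([ez / 2, ey / 2, ex / 2])
    return pts + center


def _spline_path(control: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Densely sample a cubic-spline path; return points and unit tangents."""
    control = np.asarray(control, dtype=np.float64)
    seg = np.linalg.norm(np.diff(control, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    spl = CubicSpline(t, control, axis=0)
    n = max(int(np.ceil(t[-1] / step)) + 1, 8)
    ts = np.linspace(0.0, t[-1], n)
    pts = spl(ts)
    tang = spl(ts, 1)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return pts, tang


def _in_plane_normal(tangents: np.ndarray) -> np.ndarray:
    """Unit normal perpendicular to the tangent within the xy plane."""
    n = np.zeros_like(tangents)
    n[:, 1] = -tangents[:, 2]
    n[:, 2] = tangents[:, 1]
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def _deposit(points: np.ndarray, weights: np.ndarray,
             shape: tuple[int, int, int],
             voxel_size: Sequence[float]) -> np.ndarray:
    """Trilinearly splat weighted path points onto the voxel grid."""
    vol = np.zeros(shape, dtype=np.float64)
    coords = points / np.asarray(voxel_size)[None, :] - 0.5  # voxel centers
    lo = np.floor(coords).astype(int)
    frac = coords - lo
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                idx = lo + np.array([dz, dy, dx])
                w = (weights
                     * np.where(dz, frac[:, 0], 1 - frac[:, 0])
                     * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                     * np.where(dx, frac[:, 2], 1 - frac[:, 2]))
                ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
                np.add.at(vol, (idx[ok, 0], idx[ok, 1], idx[ok, 2]), w[ok])
    return vol


def _render_tube(points: np.ndarray, sigma_nm: float,
                 shape: tuple[int, int, int],
                 voxel_size: Sequence[float]) -> np.ndarray:
    # weight each sample by its local arclength so DNA mass per unit tube
    # length is constant, also for paths offset from a curved midline
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    weights = np.empty(points.shape[0])
    weights[0] = seg[0]
    weights[-1] = seg[-1]
    weights[1:-1] = 0.5 * (seg[:-1] + seg[1:])
    vol = _deposit(points, weights, shape, voxel_size)
    sig_vox = [sigma_nm / s for s in voxel_size]
    return gaussian_filter(vol, sigma=sig_vox, mode="constant")


def _check_fits(points: np.ndarray, margin: np.ndarray,
                extent: np.ndarray) -> None:
    lo = points.min(axis=0) - margin
    hi = points.max(axis=0) + margin
    if np.any(lo < 0) or np.any(hi > extent):
        raise GeometryError(
            f"tube (with {np.round(margin)} nm margins) exceeds volume "
            f"extent {extent}")


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one phantom stack plus its exact ground-truth geometry.

    The dna channel sums both sister tubes; the label channel holds one
    tube (``one_sister``) or both (``two_sister``); the smc channel is a
    thin ridge at the midline (``single``) or at both tube centers
    (``split``).  The PSF is applied to the noiseless expectation; noise
    (Poisson then Gaussian) is applied last and only if enabled.
    """
    shape = tuple(spec.shape)
    vs = np.asarray(spec.voxel_size, dtype=np.float64)
    extent = np.array(shape) * vs
    control = (np.asarray(spec.centerline, dtype=np.float64)
               if spec.centerline is not None
               else default_centerline(shape, vs))
    step = min(vs[1], vs[2]) / 2.0
    mid_pts, tang = _spline_path(control, step)
    normal = _in_plane_normal(tang)
    half = spec.separation_d / 2.0
    sister1 = mid_pts + half * normal   # labelled sister
    sister2 = mid_pts - half * normal

    # sisters are displaced within the xy plane, so the z margin carries no
    # separation term; per-axis blur = tube cross-section (+) PSF
    sigma_ax = np.sqrt(spec.tube_sigma**2 + np.asarray(spec.psf_sigma) ** 2)
    margin = 3.0 * sigma_ax + np.array([0.0, half, half])
    _check_fits(mid_pts, margin, extent)

    d1 = _render_tube(sister1, spec.tube_sigma, shape, vs)
    d2 = _render_tube(sister2, spec.tube_sigma, shape, vs)
    # the DNA stain is partially quenched on analogue-substituted DNA, so
    # labelled sisters are dimmer in the dna channel (harlequin effect);
    # with both sisters labelled the quench is a uniform gain, keeping the
    # dna and label channels exactly proportional
    q = 1.0 - spec.label_quench
    gain = {"dna": spec.amplitude["dna"], "label": spec.amplitude["label"],
            "smc": spec.amplitude["smc"]}
    if spec.label_mode == "two_sister":
        label_density = d1 + d2
        dna_density = label_density
        gain["dna"] *= q
    else:
        label_density = d1
        dna_density = q * d1 + d2
    if spec.axis_mode == "single":
        axes = [mid_pts]
        smc_density = _render_tube(mid_pts, spec.axis_sigma, shape, vs)
    else:
        axes = [sister1, sister2]
        smc_density = (_render_tube(sister1, spec.axis_sigma, shape, vs)
                       + _render_tube(sister2, spec.axis_sigma, shape, vs))

    psf_vox = [s / v for s, v in zip(spec.psf_sigma, vs)]
    peak = (d1 + d2).max()
    # blur each distinct density once and reuse, so channels sharing a
    # geometry (two_sister label = dna) stay exactly proportional
    blurred_cache: dict[int, np.ndarray] = {}

    def expectation(role: str, density: np.ndarray) -> np.ndarray:
        key = id(density)
        if key not in blurred_cache:
            blurred_cache[key] = (
                gaussian_filter(density, sigma=psf_vox, mode="constant") / peak
                + spec.background)
        return gain[role] * blurred_cache[key]

    channels = {role: expectation(role, density)
                for role, density in (("dna", dna_density),
                                      ("label", label_density),
                                      ("smc", smc_density))}

    voxels = np.stack([channels["dna"], channels["label"], channels["smc"]], axis=-1)
    rng = np.random.default_rng(spec.seed)
    if spec.poisson:
        voxels = rng.poisson(voxels).astype(np.float64)
    if spec.gaussian_sd > 0:
        voxels = np.maximum(voxels + rng.normal(0, spec.gaussian_sd, voxels.shape), 0.0)

    stack = ImageStack(voxels=voxels,
                       channel_roles={"dna": 0, "label": 1, "smc": 2},
                       voxel_size=tuple(vs))
    truth = GroundTruth(true_separation_d=spec.separation_d,
                        sister1_centerline=sister1, sister2_centerline=sister2,
                        axis_centerlines=axes, label_assignment=1,
                        midline=mid_pts)
    return stack, truth


def _rotated_centerline(base: np.ndarray, angle: float,
                        center: np.ndarray) -> np.ndarray:
    """Rotate control points about the volume center within the xy plane."""
    rel = base - center
    c, s = np.cos(angle), np.sin(angle)
    rot = rel.copy()
    rot[:, 1] = c * rel[:, 1] + s * rel[:, 2]
    rot[:, 2] = -s * rel[:, 1] + c * rel[:, 2]
    return rot + center


def generate_population(
    spec: PhantomSpec, n_cells: int, jitter: float = 0.1,
) -> list[tuple[ImageStack, GroundTruth]]:
    """Generate a seeded population of phantoms with per-cell variation.

    Each cell gets an independently rotated centerline (uniform in-plane
    angle) and multiplicative intensity jitter of relative width
    ``jitter`` on every channel amplitude, from sub-streams of the spec
    seed; ``jitter=0`` disables the intensity variation.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    shape, vs = tuple(spec.shape), np.asarray(spec.voxel_size)
    base = (np.asarray(spec.centerline, dtype=np.float64)
            if spec.centerline is not None else default_centerline(shape, vs))
    center = np.array(shape) * vs / 2.0
    master = np.random.SeedSequence(spec.seed)
    out = []
    for i, child in enumerate(master.spawn(n_cells)):
        rng = np.random.default_rng(child)
        angle = rng.uniform(0, 2 * np.pi)
        amp = {k: v * (1.0 + jitter * rng.uniform(-1, 1))
               for k, v in spec.amplitude.items()}
        cell_seed = int(rng.integers(0, 2**31 - 1))
        cell_spec = replace(spec, centerline=_rotated_centerline(base, angle, center),
                            amplitude=amp, seed=cell_seed)
        out.append(generate_phantom(cell_spec))
    return out


def sample_ground_truth_profiles(
    spec: PhantomSpec,
    ground_truth: GroundTruth,
    n_lines: int = 5,
    line_margin: float = 600.0,
    width_voxels: int = 5,
    cell_id: str = "phantom",
) -> list[ProfileRecord]:
    """Sample cross-axis line profiles from the noiseless phantom channels.

    Lines are drawn perpendicular to the local chromosome axis, oriented
    from the labelled chromatid towards the unlabelled one (position 0 at
    the labelled end), averaging over ``width_voxels`` parallel offsets
    along the axis — the same 5-pixel-wide convention used for manually
    drawn profiles.  Lines that would exit the volume are skipped.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    noiseless = replace(spec, poisson=False, gaussian_sd=0.0)
    stack, _ = generate_phantom(noiseless)
    vs = np.asarray(spec.voxel_size)
    extent = np.array(spec.shape) * vs
    mid = ground_truth.midline
    n_pts = mid.shape[0]
    # local tangent/normal of the midline, labelled sister on +normal side
    tang = np.gradient(mid, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = _in_plane_normal(tang)

    half = spec.separation_d / 2.0 + line_margin
    step = float(min(vs[1], vs[2]))             # native sampling step, nm
    n_samp = int(np.round(2 * half / step)) + 1
    s_axis = np.arange(n_samp) * step           # position along the line, nm

    idxs = np.linspace(int(0.2 * n_pts), int(0.8 * n_pts), n_lines).astype(int)
    records = []
    for k, i in enumerate(idxs):
        start = mid[i] + half * normal[i]       # labelled-chromatid end
        direction = -normal[i]
        offsets = (np.arange(width_voxels) - (width_voxels - 1) / 2) * step
        lines = []
        ok = True
        for off in offsets:
            pts = (start[None, :] + np.outer(s_axis, direction)
                   + off * tang[i][None, :])
            if np.any(pts < 0) or np.any(pts >= extent):
                ok = False
                break
            coords = (pts / vs[None, :] - 0.5).T
            sampled = {role: map_coordinates(stack.channel(role), coords,
                                             order=1, mode="nearest")
                       for role in ("dna", "label", "smc")}
            lines.append(sampled)
        if not ok:
            import logging
            logging.getLogger("sisterres.phantom").warning(
                "line %d exits the volume; skipped", k)
            continue
        intens = {role: np.mean([ln[role] for ln in lines], axis=0)
                  for role in ("dna", "label", "smc")}
        records.append(ProfileRecord(cell_id=cell_id, line_id=f"line{k}",
                                     positions=s_axis / 1000.0,  # µm
                                     intensities=intens))
    return records
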