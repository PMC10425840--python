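"""Readers and writers for every external artifact the pipelines touch.

Image stacks travel as TIFF/OME-TIFF, line profiles as CSV (one row per
sampled position, grouped by cell and line ids), and sister-phased contacts
as pairs-like tab-separated text with ``#`` header lines.  All parsing and
serialisation lives here so the analysis modules stay pure computation on
in-memory containers.

Conventions
-----------
* Voxel sizes are nanometres, ordered ``(z, y, x)``; the default z spacing
  of 150 nm matches optimal confocal sectioning for this sample type.
* Profile positions are micrometres, starting at 0 at the labelled-chromatid
  end of the drawn line.
* Contact coordinates are 0-based; genomic distance is ``pos2 - pos1``.
* Image intensities become floating point after offset subtraction and are
  clamped at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("sisterres.io")

CHANNEL_ROLES = ("dna", "label", "smc", "marker")
PHASES = ("cis", "trans")

DEFAULT_VOXEL_SIZE = (150.0, 50.0, 50.0)  # nm (z, y, x)


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


class GeometryError(ValueError):
    """Raised when requested geometry does not fit the available volume."""


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A 3D multi-channel voxel grid with channel roles and voxel sizes.

    ``voxels`` is indexed ``(z, y, x, channel)`` and holds non-negative
    intensities.  ``channel_roles`` maps a role name (``dna``, ``label``,
    ``smc``, ``marker``) to a channel index.
    """

    voxels: np.ndarray
    channel_roles: Mapping[str, int]
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 4:
            raise FormatError(f"voxels must be (z, y, x, channel), got ndim={v.ndim}")
        self.voxels = v
        n_ch = v.shape[3]
        seen: dict[int, str] = {}
        for role, idx in self.channel_roles.items():
            if role not in CHANNEL_ROLES:
                raise FormatError(f"unknown channel role {role!r}")
            if not (0 <= idx < n_ch):
                raise FormatError(
                    f"role {role!r} maps to channel {idx}, stack has {n_ch} channels"
                )
            if idx in seen:
                raise FormatError(
                    f"roles {seen[idx]!r} and {role!r} both map to channel {idx}"
                )
            seen[idx] = role
        if any(s <= 0 for s in self.voxel_size):
            raise FormatError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    def channel(self, role: str) -> np.ndarray:
        """Return the (z, y, x) volume for a named channel role."""
        if role not in self.channel_roles:
            raise FormatError(f"stack has no channel with role {role!r}")
        return self.voxels[..., self.channel_roles[role]]


def read_image_stack(
    path: str | Path,
    channel_roles: Mapping[str, int],
    voxel_size: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF z-stack into an :class:`ImageStack`.

    The stack is transposed to ``(z, y, x, channel)`` using the axis order
    recorded in the file; a bare 3D array is treated as single-channel.
    Voxel sizes come from OME metadata when present, else from
    ``voxel_size``, else from the package default.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes.upper()
    data = _to_zyxc(data, axes)
    if not np.issubdtype(data.dtype, np.number):
        raise FormatError(f"{path}: non-numeric pixel data ({data.dtype})")
    missing = [r for r in channel_roles if channel_roles[r] >= data.shape[3]]
    if missing:
        raise FormatError(
            f"{path}: channel role(s) {missing} out of range for "
            f"{data.shape[3]}-channel stack"
        )
    vs = voxel_size if voxel_size is not None else DEFAULT_VOXEL_SIZE
    return ImageStack(voxels=data.astype(np.float64), channel_roles=dict(channel_roles),
                      voxel_size=tuple(vs))


def _to_zyxc(data: np.ndarray, axes: str) -> np.ndarray:
    if data.ndim == 2:
        data, axes = data[None, ...], "Z" + (axes if len(axes) == 2 else "YX")
    if data.ndim == 3:
        if "C" in axes and "Z" not in axes:
            data = data[None, ...]
            axes = "Z" + axes
        else:
            data = data[..., None]
            axes = (axes if len(axes) == 3 else "ZYX") + "C"
    if data.ndim != 4:
        raise FormatError(f"cannot interpret {data.ndim}-dimensional TIFF")
    if len(axes) != 4 or set(axes) != set("ZYXC"):
        axes = "ZCYX" if data.shape[1] <= 8 < data.shape[3] else "ZYXC"
    order = [axes.index(a) for a in "ZYXC"]
    return np.transpose(data, order)


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with ZCYX axes and voxel-size metadata."""
    data = np.transpose(stack.voxels, (0, 3, 1, 2))  # ZCYX
    zs, ys, xs = stack.voxel_size
    tifffile.imwrite(
        Path(path),
        data.astype(np.float32),
        metadata={
            "axes": "ZCYX",
            "PhysicalSizeZ": zs / 1000.0, "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": ys / 1000.0, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": xs / 1000.0, "PhysicalSizeXUnit": "µm",
        },
    )


def subtract_offset(stack: ImageStack, offset: float) -> ImageStack:
    """Subtract a constant grey-value offset, clamping at zero.

    Image-reconstruction software can add a constant pedestal (e.g. 10,000
    grey values) to every processed pixel; this removes it before any
    quantification.  Shape, roles and voxel sizes are unchanged.
    """
    if offset < 0:
        raise ValueError(f"offset must be non-negative, got {offset}")
    voxels = np.maximum(stack.voxels.astype(np.float64) - offset, 0.0)
    return ImageStack(voxels=voxels, channel_roles=dict(stack.channel_roles),
                      voxel_size=stack.voxel_size)


# ---------------------------------------------------------------------------
# Line profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileRecord:
    """One drawn cross-axis line: sampled positions plus channel intensities.

    Positions are micrometres, strictly increasing, starting at 0 at the
    labelled-chromatid end of the line.  ``intensities`` maps channel role
    (``smc``, ``label``, ``dna``) to a vector the same length as
    ``positions``.
    """

    cell_id: str
    line_id: str
    positions: np.ndarray
    intensities: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        if pos.ndim != 1 or pos.size < 2:
            raise FormatError("profile needs at least two sampled positions")
        if not np.all(np.diff(pos) > 0):
            raise FormatError("profile positions must be strictly increasing")
        self.positions = pos
        clean = {}
        for role, vals in self.intensities.items():
            v = np.asarray(vals, dtype=np.float64)
            if v.shape != pos.shape:
                raise FormatError(
                    f"channel {role!r} has {v.size} samples, expected {pos.size}"
                )
            clean[role] = v
        self.intensities = clean

    @property
    def n_samples(self) -> int:
        return int(self.positions.size)


DEFAULT_PROFILE_COLUMNS = {
    "cell_id": "cell_id",
    "line_id": "line_id",
    "position": "distance_um",
    "smc": "smc",
    "label": "label",
    "dna": "dna",
}

MIN_PROFILE_SAMPLES = 8


def read_profiles_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    position_scale: float = 1.0,
) -> list[ProfileRecord]:
    """Read line-profile exports (one row per sampled position) from CSV.

    ``column_map`` renames the expected logical columns (``cell_id``,
    ``line_id``, ``position`` and the channel roles) to whatever headers
    the export used; ``position_scale`` converts positions to µm (e.g.
    1e-3 for nm exports).  Lines with non-monotonic positions or fewer
    than 8 samples are rejected with a logged reason, not fatal.
    """
    cols = dict(DEFAULT_PROFILE_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(Path(path))
    required = [cols["cell_id"], cols["line_id"], cols["position"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    channel_cols = {r: cols[r] for r in ("smc", "label", "dna") if cols[r] in df.columns}
    if not channel_cols:
        raise FormatError(f"{path}: no recognised channel columns")

    records: list[ProfileRecord] = []
    for (cell_id, line_id), grp in df.groupby([cols["cell_id"], cols["line_id"]],
                                              sort=False):
        pos = grp[cols["position"]].to_numpy(dtype=np.float64) * position_scale
        if pos.size < MIN_PROFILE_SAMPLES:
            logger.warning("profile %s/%s rejected: only %d samples",
                           cell_id, line_id, pos.size)
            continue
        if not np.all(np.diff(pos) > 0):
            logger.warning("profile %s/%s rejected: non-monotonic positions",
                           cell_id, line_id)
            continue
        intens = {role: grp[col].to_numpy(dtype=np.float64)
                  for role, col in channel_cols.items()}
        records.append(ProfileRecord(str(cell_id), str(line_id), pos, intens))
    logger.info("read %d profiles from %s", len(records), path)
    return records


def write_profiles_csv(records: Sequence[ProfileRecord], path: str | Path) -> None:
    """Write profiles in the long CSV layout :func:`read_profiles_csv` expects."""
    frames = []
    for rec in records:
        d = {"cell_id": rec.cell_id, "line_id": rec.line_id,
             "distance_um": rec.positions}
        d.update(rec.intensities)
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Sister-phased contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactRecord:
    """A single sister-phased intra-chromosomal contact."""

    chrom: str
    pos1: int
    pos2: int
    phase: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise FormatError(f"phase must be cis or trans, got {self.phase!r}")
        if self.pos2 < self.pos1:
            raise FormatError("pos1 must not exceed pos2")

    @property
    def distance(self) -> int:
        return self.pos2 - self.pos1


CONTACT_COLUMNS = ["chrom", "pos1", "pos2", "phase"]


def read_phased_pairs(path: str | Path) -> pd.DataFrame:
    """Read a pairs-like phased-contact table.

    Tab-separated text; lines starting with ``#`` are headers.  Columns:
    chrom, pos1, pos2, phase (``cis`` = same chromatid, ``trans`` =
    inter-sister).  Records with ``pos2 < pos1`` are swapped with a
    warning; an unknown phase token is a parse error naming the line.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, p1, p2, phase = parts[0], parts[1], parts[2], parts[3]
            if phase not in PHASES:
                raise FormatError(f"{path}:{lineno}: unknown phase token {phase!r}")
            try:
                pos1, pos2 = int(p1), int(p2)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position") from exc
            if pos2 < pos1:
                logger.warning("%s:%d: pos2 < pos1, swapping", path, lineno)
                pos1, pos2 = pos2, pos1
            rows.append((chrom, pos1, pos2, phase))
    if not rows:
        raise FormatError(f"{path}: no contact records")
    df = pd.DataFrame(rows, columns=CONTACT_COLUMNS)
    counts = df["phase"].value_counts()
    logger.info("read %d contacts from %s (cis=%d, trans=%d)", len(df), path,
                counts.get("cis", 0), counts.get("trans", 0))
    return df


def write_phased_pairs(table: pd.DataFrame, path: str | Path,
                       header_lines: Sequence[str] = ()) -> None:
    """Write a contact table as pairs-like TSV with ``#`` header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# columns: chrom\tpos1\tpos2\tphase\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", header=False, index=False,
                     columns=CONTACT_COLUMNS)


def contact_records(table: pd.DataFrame) -> list[ContactRecord]:
    """Materialise a contact DataFrame as validated records."""
    return [ContactRecord(r.chrom, int(r.pos1), int(r.pos2), r.phase)
            for r in table.itertuples(index=False)]
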