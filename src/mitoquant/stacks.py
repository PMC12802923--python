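"""3-D multi-channel image container with physical voxel spacing.

All imaging stages of the pipeline operate on :class:`ImageStack3D`: a set of
equally shaped 3-D voxel grids (one per named fluorescence channel, e.g.
``DAPI``, ``Top2``, ``Nop1``) together with the physical voxel spacing in
nanometres per axis, ordered ``(z, y, x)``.  Spinning-disk confocal stacks are
strongly anisotropic (plane spacing ~200 nm vs. ~65 nm pixels), so the spacing
travels with the data and the morphometry stages resample to an isotropic grid
before measuring anything geometric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack3D", "read_stack", "write_stack"]


@dataclass
class ImageStack3D:
    """Multi-channel 3-D fluorescence stack with per-axis physical spacing.

    Parameters
    ----------
    channels
        Mapping from channel name to a 3-D float array, axis order (z, y, x).
        All channels must share one shape.
    spacing_nm
        Physical voxel spacing in nm, ordered (z, y, x); all entries > 0.
    """

    channels: dict[str, np.ndarray]
    spacing_nm: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must carry at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        shape = next(iter(shapes))
        if len(shape) != 3:
            raise ValueError(f"channels must be 3-D (z, y, x), got shape {shape}")
        self.spacing_nm = tuple(float(s) for s in self.spacing_nm)
        if len(self.spacing_nm) != 3 or any(s <= 0 for s in self.spacing_nm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_nm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def is_isotropic(self) -> bool:
        z, y, x = self.spacing_nm
        return abs(z - y) < 1e-9 and abs(y - x) < 1e-9

    @property
    def voxel_volume_um3(self) -> float:
        z, y, x = self.spacing_nm
        return (z * y * x) * 1e-9  # nm^3 -> um^3

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in stack (have {sorted(self.channels)})"
            ) from None


def write_stack(stack: ImageStack3D, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF (one series per channel) plus a
    plain-text sidecar ``<path>.spacing.tsv`` recording channel order and
    spacing.  Integer-valued data round-trips losslessly."""
    path = Path(path)
    names = sorted(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=0)
    tifffile.imwrite(path, data.astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".spacing.tsv")
    with open(sidecar, "w") as fh:
        fh.write("# axis order z,y,x; spacing in nm\n")
        fh.write("spacing_nm\t" + "\t".join(f"{s:g}" for s in stack.spacing_nm) + "\n")
        fh.write("channels\t" + "\t".join(names) + "\n")
    return path


def read_stack(path: str | Path, spacing_nm: tuple[float, float, float] | None = None) -> ImageStack3D:
    """Read a multi-page TIFF written by :func:`write_stack`.

    The spacing sidecar is required unless ``spacing_nm`` is given explicitly;
    a missing sidecar raises with instructions to supply the spacing.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # corrupt/unreadable file: explicit contract
        raise ValueError(f"cannot parse TIFF at {path}: {exc}") from exc
    sidecar = path.with_suffix(path.suffix + ".spacing.tsv")
    names: list[str] | None = None
    if sidecar.exists():
        side_spacing = None
        for line in sidecar.read_text().splitlines():
            if line.startswith("#") or not line.strip():
                continue
            key, *vals = line.split("\t")
            if key == "spacing_nm":
                side_spacing = tuple(float(v) for v in vals)
            elif key == "channels":
                names = list(vals)
        if spacing_nm is None:
            spacing_nm = side_spacing
    if spacing_nm is None:
        raise ValueError(
            f"no spacing sidecar at {sidecar}; pass spacing_nm (or --spacing z,y,x on the CLI)"
        )
    if data.ndim == 3:
        data = data[None]
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    channels = {n: np.asarray(data[i], dtype=np.float64) for i, n in enumerate(names)}
    return ImageStack3D(channels=channels, spacing_nm=tuple(spacing_nm))
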