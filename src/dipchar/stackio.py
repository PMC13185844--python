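"""File formats: image-stack manifests, force-trace CSV, trajectory CSV.

Slice geometries, dose fields and light-sheet frames all travel as 8-bit
single-channel image stacks — one PNG (default) or TIFF per z-slice with
zero-padded numeric names, layer index 0 at the container base.  Force
traces and calibration tables are plain CSV with mandatory headers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DomainError, StackError
from .mechtest import CalibrationCurve, ForceTrace, apply_calibration

__all__ = [
    "StackManifest",
    "read_stack",
    "write_stack",
    "read_trace_csv",
    "write_trace_csv",
    "read_calibration_csv",
]

TRACE_COLUMNS_N = ("time_s", "z_m", "force_N")
TRACE_COLUMNS_COUNTS = ("time_s", "z_m", "counts")


@dataclass(frozen=True)
class StackManifest:
    """Where and how an image stack lives on disk.

    ``pattern`` is a glob with one integer group, e.g. ``layer_*.png``;
    indices must be contiguous and zero-padded, shapes and bit depth uniform.
    """

    directory: Path
    pattern: str = "layer_*.png"
    layer_height_um: float = 50.0
    pixel_pitch_um: float = 50.0
    bit_depth: int = 8

    @property
    def n_layers_expected(self) -> int | None:
        return None

    def layer_count(self, build_height_um: float) -> int:
        """Number of layers for a build height at this layer pitch."""
        k = build_height_um / self.layer_height_um
        if abs(k - round(k)) > 1e-9:
            raise DomainError(
                f"build height {build_height_um} um is not a multiple of the "
                f"layer height {self.layer_height_um} um"
            )
        return int(round(k))

    def _files(self) -> list[tuple[int, Path]]:
        rx = re.compile(
            "^" + re.escape(self.pattern).replace(r"\*", r"(\d+)") + "$"
        )
        out = []
        for p in sorted(Path(self.directory).iterdir()):
            m = rx.match(p.name)
            if m:
                out.append((int(m.group(1)), p))
        return sorted(out)


def read_stack(manifest: StackManifest, binary: bool = False) -> np.ndarray:
    """Load an image stack as a (rows, cols, K) grid, z index 0 first.

    With ``binary=True`` the 8-bit data are thresholded at > 127.  Gaps in
    the index sequence and mixed image shapes are errors.
    """
    files = manifest._files()
    if not files:
        raise StackError(f"no files matching {manifest.pattern!r} in {manifest.directory}")
    indices = [i for i, _ in files]
    expected = list(range(indices[0], indices[0] + len(indices)))
    if indices != expected:
        missing = sorted(set(expected) - set(indices))[0]
        raise StackError(f"stack index {missing} missing from sequence")
    slices = []
    for _, path in files:
        img = np.asarray(iio.imread(path))
        if img.ndim != 2:
            raise StackError(f"{path.name}: expected single-channel grayscale image")
        slices.append(img)
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise StackError(f"mixed slice shapes in stack: {sorted(shapes)}")
    grid = np.stack(slices, axis=-1)
    if binary:
        grid = (grid > 127).astype(np.uint8)
    return grid


def write_stack(grid: np.ndarray, manifest: StackManifest, width: int = 4) -> list[Path]:
    """Write a (rows, cols, K) grid as one 8-bit image per z-slice.

    Values must already lie in [0, 255] (quantize first); encoding is
    lossless, names zero-padded from index 0.
    """
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise DomainError("write_stack expects a (rows, cols, K) grid")
    if grid.min() < 0 or grid.max() > 255:
        raise DomainError("stack values must lie in [0, 255]; quantize first")
    directory = Path(manifest.directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem, suffix = manifest.pattern.split("*")
    paths = []
    for k in range(grid.shape[-1]):
        path = directory / f"{stem}{k:0{width}d}{suffix}"
        iio.imwrite(path, grid[..., k].astype(np.uint8))
        paths.append(path)
    return paths


def read_trace_csv(path, calibration: CalibrationCurve | None = None) -> ForceTrace:
    """Load a force trace CSV (``time_s,z_m,force_N`` or ``time_s,z_m,counts``).

    Raw-counts traces require a calibration curve and are converted to
    newtons before anything else touches them.
    """
    df = pd.read_csv(path)
    cols = tuple(df.columns[:3])
    if cols == TRACE_COLUMNS_N:
        return ForceTrace(
            time=df["time_s"].to_numpy(),
            z=df["z_m"].to_numpy(),
            force=df["force_N"].to_numpy(),
        )
    if cols == TRACE_COLUMNS_COUNTS:
        if calibration is None:
            raise DomainError(
                f"{path}: raw-counts trace requires a calibration curve"
            )
        raw = ForceTrace(
            time=df["time_s"].to_numpy(),
            z=df["z_m"].to_numpy(),
            force=df["counts"].to_numpy(),
        )
        return apply_calibration(raw, calibration)
    raise DomainError(
        f"{path}: expected header {TRACE_COLUMNS_N} or {TRACE_COLUMNS_COUNTS}, got {cols}"
    )


def write_trace_csv(trace: ForceTrace, path) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "z_m": trace.z, "force_N": trace.force}
    ).to_csv(path, index=False)


def read_calibration_csv(path) -> list[tuple[float, float]]:
    """Load a ``mass_g,counts`` calibration table."""
    df = pd.read_csv(path)
    if tuple(df.columns[:2]) != ("mass_g", "counts"):
        raise DomainError(f"{path}: expected header ('mass_g', 'counts')")
    return list(zip(df["mass_g"].astype(float), df["counts"].astype(float)))
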