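"""Seed-based resting-state functional connectivity.

The seed time course is the average BOLD waveform of a voxel and its 26
nearest neighbors (27 voxels), excluding CSF-containing voxels; functional
connectivity is the temporal Pearson correlation between that seed waveform
and every gray-matter voxel's series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .grid import VolumeGrid


@dataclass
class BOLDSeries:
    """4D BOLD data (x, y, z, t) on a grid, with repetition time in seconds."""

    grid: VolumeGrid
    data: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[:3] != self.grid.shape:
            raise ConfigError("BOLD data must be 4D with spatial shape matching the grid")
        if self.data.shape[3] < 10:
            raise ConfigError("BOLD series must have at least 10 time points")
        if not np.isfinite(self.data).all():
            raise ConfigError("BOLD data must be finite")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class CorrMap:
    """Per-voxel Pearson r to the seed; NaN outside the mask / where undefined."""

    grid: VolumeGrid
    values: np.ndarray
    seed_voxel: tuple[int, int, int]


def detrend(bold: BOLDSeries, order: int = 1) -> BOLDSeries:
    """Remove a per-voxel polynomial trend of the given order (0, 1 or 2).

    Stands in for the full resting-state nuisance pipeline; order >= 0 leaves
    every voxel with zero temporal mean.
    """
    if order not in (0, 1, 2):
        raise ConfigError("detrend order must be 0, 1 or 2")
    t = np.arange(bold.n_volumes, dtype=float)
    basis = np.vander(t, order + 1, increasing=True)  # (T, order+1)
    flat = bold.data.reshape(-1, bold.n_volumes)
    coef, *_ = np.linalg.lstsq(basis, flat.T, rcond=None)
    resid = flat - (basis @ coef).T
    return BOLDSeries(bold.grid, resid.reshape(bold.data.shape), bold.tr_s)


def seed_timecourse(
    bold: BOLDSeries, seed_voxel, csf_mask: np.ndarray | None = None
) -> tuple[np.ndarray, int]:
    """Mean series over the 27-voxel neighborhood of the seed, excluding CSF.

    The neighborhood is the 3x3x3 block centred on the seed intersected with
    the grid; CSF-containing voxels are dropped.  Returns the mean waveform
    and the number of contributing voxels.
    """
    seed = tuple(int(x) for x in np.asarray(seed_voxel).ravel())
    if not bold.grid.contains(np.array(seed)):
        raise ConfigError(f"seed voxel {seed} outside the grid")
    if csf_mask is not None:
        csf_mask = np.asarray(csf_mask, dtype=bool)
        if csf_mask[seed]:
            raise ConfigError(f"seed voxel {seed} lies in CSF")

    shape = bold.grid.shape
    members = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                v = (seed[0] + di, seed[1] + dj, seed[2] + dk)
                if not all(0 <= v[a] < shape[a] for a in range(3)):
                    continue
                if csf_mask is not None and csf_mask[v]:
                    continue
                members.append(v)
    if not members:
        raise ConfigError("all neighborhood voxels are CSF; no seed series")
    stack = np.stack([bold.data[v] for v in members])
    return stack.mean(axis=0), len(members)


def correlation_map(
    bold: BOLDSeries, seed_series: np.ndarray, gm_mask: np.ndarray,
    seed_voxel=(0, 0, 0),
) -> CorrMap:
    """Pearson r between the seed series and every in-mask voxel series.

    Zero-variance voxels get NaN (undefined correlation); a constant seed
    series is an error.
    """
    seed_series = np.asarray(seed_series, dtype=float)
    if seed_series.shape != (bold.n_volumes,):
        raise ConfigError("seed series length must equal the number of volumes")
    s = seed_series - seed_series.mean()
    s_norm = np.sqrt((s**2).sum())
    if s_norm == 0:
        raise ConfigError("seed series is constant; correlation undefined")

    gm = np.asarray(gm_mask, dtype=bool)
    if gm.shape != bold.grid.shape:
        raise ConfigError("gm_mask shape does not match the grid")
    series = bold.data[gm]  # (n_vox, T)
    x = series - series.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((x**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ s) / (x_norm * s_norm)
    r[x_norm == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)

    values = np.full(bold.grid.shape, np.nan)
    values[gm] = r
    return CorrMap(bold.grid, values, tuple(int(v) for v in np.asarray(seed_voxel).ravel()))
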