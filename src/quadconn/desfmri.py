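"""Block-design GLM t-maps for direct-electrical-stimulation fMRI (DES-fMRI).

Stimulation is delivered in 32 s on/off blocks (four on-blocks, TR 2 s, 5 min
acquisition); the BOLD series at every gray-matter voxel is fit by ordinary
least squares against the hemodynamically convolved boxcar, and the t-score
of the task coefficient is the connectivity measure (its absolute value when
compared against signed modalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConfigError
from .grid import VolumeGrid
from .rsfmri import BOLDSeries


def single_gamma_hrf(t: np.ndarray, peak_s: float = 5.0, shape: float = 6.0) -> np.ndarray:
    """Canonical single-gamma hemodynamic response, unit peak amplitude.

    ``h(t) ∝ t^(shape-1) exp(-t/scale)`` with ``scale = peak_s / (shape - 1)``
    so the response peaks at ``peak_s`` seconds.
    """
    t = np.asarray(t, dtype=float)
    scale = peak_s / (shape - 1.0)
    h = stats.gamma.pdf(t, a=shape, scale=scale)
    m = h.max()
    return h / m if m > 0 else h


@dataclass
class DesignMatrix:
    """GLM design: columns over volumes; the task regressor is column 0."""

    matrix: np.ndarray  # (n_volumes, n_regressors)
    names: list[str]
    tr_s: float
    boxcar: np.ndarray  # raw on/off envelope before convolution

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ConfigError("design matrix must be 2D")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ConfigError("design matrix is rank deficient")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def task(self) -> np.ndarray:
        return self.matrix[:, 0]


@dataclass
class TMap:
    """Per-voxel t-scores with degrees of freedom; NaN outside the mask.

    Voxels that fit the design with zero residual get a +/-inf sentinel.
    """

    grid: VolumeGrid
    values: np.ndarray
    df: int


def build_design(
    block_s: float = 32.0,
    tr_s: float = 2.0,
    n_blocks: int = 4,
    total_s: float = 300.0,
    hrf=None,
    drift: bool = False,
) -> DesignMatrix:
    """HRF-convolved alternating off/on boxcar design plus intercept.

    The acquisition starts with an off block; ``n_blocks`` on-blocks of
    ``block_s`` seconds alternate with off blocks, truncated to
    ``total_s / tr_s`` volumes.  ``hrf`` maps a time vector (s) to response
    amplitudes; ``None`` selects the canonical single-gamma response, and an
    identity (delta) HRF can be injected for testing.  With ``n_blocks=0``
    the design is intercept-only (no t-map can be requested from it).
    """
    n_vol = int(round(total_s / tr_s))
    vol_per_block = int(round(block_s / tr_s))
    if vol_per_block < 1 or n_vol < 1:
        raise ConfigError("block and total duration must cover at least one volume")
    if n_blocks < 0:
        raise ConfigError("n_blocks must be >= 0")
    if n_blocks > 0 and vol_per_block * 2 > n_vol:
        raise ConfigError(
            f"one off+on block pair ({2 * vol_per_block} volumes) exceeds the "
            f"acquisition ({n_vol} volumes)"
        )

    boxcar = np.zeros(n_vol)
    for b in range(n_blocks):
        on = (2 * b + 1) * vol_per_block
        boxcar[on : on + vol_per_block] = 1.0
    if n_blocks > 0 and not boxcar.any():
        raise ConfigError("no on-block fits inside the acquisition")

    if n_blocks == 0:
        cols = []
        names = []
    else:
        if hrf is None:
            t = np.arange(0, 32.0, tr_s)
            kernel = single_gamma_hrf(t)
        else:
            kernel = np.asarray(hrf(np.arange(0, 32.0, tr_s)), dtype=float)
        task = np.convolve(boxcar, kernel)[:n_vol]
        peak = np.abs(task).max()
        if peak > 0:
            task = task / peak  # unit peak so amplitudes are in signal units
        cols = [task]
        names = ["task"]
    cols.append(np.ones(n_vol))
    names.append("intercept")
    if drift:
        cols.append(np.linspace(-1, 1, n_vol))
        names.append("drift")
    return DesignMatrix(np.column_stack(cols), names, tr_s, boxcar)


def glm_tmap(bold: BOLDSeries, design: DesignMatrix, gm_mask: np.ndarray) -> TMap:
    """Voxelwise OLS fit; t = task coefficient / its standard error.

    Degrees of freedom are ``volumes - rank(design)``.  Zero-residual voxels
    are flagged with a +/-inf sentinel and a warning.
    """
    if "task" not in design.names:
        raise ConfigError("design has no task regressor; cannot form a t-map")
    X = design.matrix
    if X.shape[0] != bold.n_volumes:
        raise ConfigError("design rows must match the number of volumes")
    gm = np.asarray(gm_mask, dtype=bool)
    if gm.shape != bold.grid.shape:
        raise ConfigError("gm_mask shape does not match the grid")

    Y = bold.data[gm].T  # (T, n_vox)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    df = X.shape[0] - X.shape[1]
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    c = xtx_inv[0, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[0] / np.sqrt(sigma2 * c)
    zero_resid = rss <= 1e-12 * np.maximum((Y**2).sum(axis=0), 1e-300)
    if zero_resid.any():
        warnings.warn(
            f"{int(zero_resid.sum())} voxels fit the design exactly; "
            "t set to +/-inf sentinel",
            stacklevel=2,
        )
        t[zero_resid] = np.sign(beta[0][zero_resid]) * np.inf

    values = np.full(bold.grid.shape, np.nan)
    values[gm] = t
    return TMap(bold.grid, values, df)


def connectivity_from_tmap(tmap: TMap, mode: str = "absolute") -> np.ndarray:
    """Per-voxel connectivity values from a t-map: identity or |t|."""
    if mode == "signed":
        return tmap.values.copy()
    if mode == "absolute":
        return np.abs(tmap.values)
    raise ConfigError(f"unknown mode {mode!r}")
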