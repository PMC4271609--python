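"""Pairwise cross-modal consistency of connectivity measures.

Connectivity values from any two modalities are aligned over a common target
set (electrode contacts, or gray-matter voxels), turned into a scatter of
paired values, and summarized by the Pearson r^2 and its two-sided p-value.
All six pairs of the four modalities form the comparison matrix; sessions or
phantoms can be pooled by concatenating their pairs before one global r^2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .grid import VolumeGrid
from .phantom import ElectrodeTable


@dataclass
class TargetSet:
    """Common comparison targets: contact ids or voxel indices.

    ``excluded`` records targets dropped for lying within the exclusion
    radius of the seed.
    """

    kind: str  # "contacts" | "voxels"
    identifiers: list
    excluded: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("contacts", "voxels"):
            raise ConfigError("target kind must be 'contacts' or 'voxels'")
        if len(self.identifiers) == 0:
            raise ConfigError("target set is empty after exclusions")
        if len(set(map(tuple_or_id, self.identifiers))) != len(self.identifiers):
            raise ConfigError("target identifiers contain duplicates")


def tuple_or_id(x):
    return tuple(x) if isinstance(x, (list, np.ndarray)) else x


@dataclass
class PairedComparison:
    """Aligned value pairs for two modalities with their Pearson statistics."""

    modality_a: str
    modality_b: str
    values_a: np.ndarray
    values_b: np.ndarray
    r2: float
    p: float
    n: int
    n_dropped: int = 0


def sample_map_at_contacts(
    values: np.ndarray,
    grid: VolumeGrid,
    electrodes: ElectrodeTable,
    radius_mm: float = 0.0,
    mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Volumetric map value at each contact: mean over voxels within radius_mm.

    With radius 0 the nearest voxel is used.  Voxels outside ``mask`` (or
    non-finite map values) do not contribute; a contact with no usable voxel
    in range gets NaN.
    """
    out: dict[str, float] = {}
    shape = grid.shape
    vox_centers = None
    for c in electrodes.contacts:
        idx = grid.world_to_index(c.world_mm)
        if not bool(grid.contains(idx)):
            raise ConfigError(f"contact {c.contact_id} falls outside the grid")
        if radius_mm <= 0:
            v = values[tuple(idx)]
            ok = np.isfinite(v) and (mask is None or mask[tuple(idx)])
            out[c.contact_id] = float(v) if ok else np.nan
            continue
        if vox_centers is None:
            ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
            all_idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
            vox_centers = grid.voxel_to_world(all_idx)
        d = np.linalg.norm(vox_centers - np.asarray(c.world_mm), axis=1)
        near = d <= radius_mm
        vals = values.ravel()[near]
        ok = np.isfinite(vals)
        if mask is not None:
            ok &= mask.ravel()[near]
        out[c.contact_id] = float(vals[ok].mean()) if ok.any() else np.nan
    return out


def build_target_set(
    kind: str,
    seed_world_mm,
    exclusion_radius_mm: float = 10.0,
    grid: VolumeGrid | None = None,
    gm_mask: np.ndarray | None = None,
    electrodes: ElectrodeTable | None = None,
) -> TargetSet:
    """All candidate targets minus those within the exclusion radius of the seed.

    For ``contacts`` the candidates are the recording contacts (stim contacts
    are always excluded); for ``voxels`` they are the gray-matter voxels.
    """
    if exclusion_radius_mm < 0:
        raise ConfigError("exclusion radius must be >= 0")
    seed = np.asarray(seed_world_mm, dtype=float)
    if kind == "contacts":
        if electrodes is None:
            raise ConfigError("contacts target set needs an electrode table")
        kept, dropped = [], []
        for c in electrodes.contacts:
            if c.role == "stim":
                dropped.append(c.contact_id)
                continue
            if np.linalg.norm(np.asarray(c.world_mm) - seed) <= exclusion_radius_mm:
                dropped.append(c.contact_id)
            else:
                kept.append(c.contact_id)
        return TargetSet("contacts", kept, dropped)
    if kind == "voxels":
        if grid is None or gm_mask is None:
            raise ConfigError("voxel target set needs a grid and gm_mask")
        idx = np.column_stack(np.nonzero(gm_mask))
        world = grid.voxel_to_world(idx)
        d = np.linalg.norm(world - seed, axis=1)
        keep = d > exclusion_radius_mm
        kept = [tuple(v) for v in idx[keep]]
        dropped = [tuple(v) for v in idx[~keep]]
        return TargetSet("voxels", kept, dropped)
    raise ConfigError(f"unknown target kind {kind!r}")


def pair_values(
    vals_a: dict, vals_b: dict, targets: TargetSet,
    modality_a: str = "a", modality_b: str = "b",
) -> PairedComparison:
    """Pairwise-complete alignment of two value sets over the targets.

    Targets missing (absent or NaN) in either modality are dropped and
    counted; fewer than 3 complete pairs is an error.  Statistics are not
    filled in here (see :func:`pearson_r2`).
    """
    a, b, dropped = [], [], 0
    for t in targets.identifiers:
        key = tuple_or_id(t)
        va = vals_a.get(key, np.nan)
        vb = vals_b.get(key, np.nan)
        if np.isfinite(va) and np.isfinite(vb):
            a.append(va)
            b.append(vb)
        else:
            dropped += 1
    if len(a) < 3:
        raise ConfigError(
            f"only {len(a)} complete pairs between {modality_a} and {modality_b}; need >= 3"
        )
    return PairedComparison(
        modality_a, modality_b, np.asarray(a), np.asarray(b),
        r2=np.nan, p=np.nan, n=len(a), n_dropped=dropped,
    )


def pearson_r2(values_a, values_b) -> tuple[float, float]:
    """Pearson r^2 and two-sided p for aligned value pairs.

    r is the standard product-moment coefficient; p comes from
    ``t = r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigError("paired values must be 1D arrays of equal length")
    if a.size < 3:
        raise ConfigError("need at least 3 pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConfigError("constant column; correlation undefined")
    res = stats.pearsonr(a, b)
    return float(res.statistic**2), float(res.pvalue)


def compare(
    vals_a: dict, vals_b: dict, targets: TargetSet,
    modality_a: str = "a", modality_b: str = "b",
) -> PairedComparison:
    """Align two modality value sets and fill in r^2 and p."""
    pc = pair_values(vals_a, vals_b, targets, modality_a, modality_b)
    pc.r2, pc.p = pearson_r2(pc.values_a, pc.values_b)
    return pc


def comparison_matrix(
    modality_value_sets: dict[str, dict] | list[dict[str, dict]],
    targets: TargetSet | list[TargetSet],
    normalize: bool = False,
) -> pd.DataFrame:
    """All pairwise comparisons between the supplied modalities.

    ``modality_value_sets`` is either one mapping ``modality -> {target:
    value}`` or a list of such mappings (sessions/phantoms); sessions are
    pooled by concatenating their aligned pairs before computing one global
    r^2 per modality pair.  With ``normalize=True`` each session's aligned
    values are z-scored per modality before pooling (raw units are pooled by
    default, since sessions share the same instruments here; the flag covers
    heterogeneous-session pooling).  Returns a tidy DataFrame with one row
    per modality pair (r2, p, n, n_dropped).
    """
    if isinstance(modality_value_sets, dict):
        modality_value_sets = [modality_value_sets]
        targets = [targets]
    if len(modality_value_sets) != len(targets):
        raise ConfigError("need one target set per session")
    modalities = list(modality_value_sets[0].keys())
    if len(modalities) < 2:
        raise ConfigError("need at least 2 modalities")

    rows = []
    for ma, mb in itertools.combinations(modalities, 2):
        a_all, b_all, dropped = [], [], 0
        for sess, tset in zip(modality_value_sets, targets):
            pc = pair_values(sess[ma], sess[mb], tset, ma, mb)
            va, vb = pc.values_a, pc.values_b
            if normalize:
                va = (va - va.mean()) / (va.std() if va.std() > 0 else 1.0)
                vb = (vb - vb.mean()) / (vb.std() if vb.std() > 0 else 1.0)
            a_all.append(va)
            b_all.append(vb)
            dropped += pc.n_dropped
        a = np.concatenate(a_all)
        b = np.concatenate(b_all)
        r2, p = pearson_r2(a, b)
        rows.append({"modality_a": ma, "modality_b": mb,
                     "r2": r2, "p": p, "n": a.size, "n_dropped": dropped})
    return pd.DataFrame(rows)
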