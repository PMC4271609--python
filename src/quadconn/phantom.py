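"""Synthetic multimodal phantom: configuration, masks, electrodes, FOD rendering.

One ground-truth network (see :mod:`quadconn.network`) drives four simulated
datasets — an FOD field for tractography, resting BOLD, stimulus-locked
evoked recordings and block-design stimulation BOLD — so every downstream
connectivity measure can be validated against the same latent truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, PlacementError
from .grid import VolumeGrid
from .network import GroundTruthNetwork, Node, generate_network
from .structural import FODField, OFFSETS, neighbor_directions


@dataclass(frozen=True)
class PhantomConfig:
    """All knobs of the synthetic phantom (defaults are the study conditions).

    Noise levels: ``sigma_ccep`` is additive waveform noise in uV,
    ``sigma_bold`` is additive BOLD noise as a fraction of the unit latent
    signal, ``kappa`` is the FOD concentration (per unit edge weight;
    0 = isotropic).
    """

    shape: tuple[int, int, int] = (36, 36, 36)
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    n_nodes: int = 6
    n_edges: int = 5
    weight_range: tuple[float, float] = (0.3, 0.95)
    hub_distance: int = 6
    patch_radius: int = 1
    hub_jitter_vox: int = 3

    sigma_ccep: float = 5.0     # uV
    sigma_bold: float = 0.1     # fraction of latent signal sd
    kappa: float = 20.0         # FOD concentration per unit weight

    n_trials: int = 40
    sampling_rate_hz: float = 1000.0
    outlier_fraction: float = 0.1
    ccep_amp_uv: float = 120.0
    artifact_amp_uv: float = 800.0
    latency_ms: float = 100.0
    latency_per_edge_ms: float = 10.0
    epoch_pre_ms: float = 100.0
    epoch_post_ms: float = 400.0

    tr_s: float = 2.0
    block_s: float = 32.0
    n_blocks: int = 4
    des_total_s: float = 300.0
    des_amp: float = 1.0
    negative_fraction: float = 0.25

    rest_volumes: int = 132
    ar_rho: float = 0.5

    n_contacts: int = 12
    jitter_mm: float = 0.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_ccep, self.sigma_bold, self.kappa) < 0:
            raise ConfigError("noise levels must be >= 0")
        if self.n_trials % 2 != 0 or self.n_trials < 2:
            raise ConfigError("n_trials must be even (polarity pairs must balance)")
        if self.rest_volumes < 10:
            raise ConfigError("rest_volumes must be >= 10")
        if not 0 <= self.outlier_fraction < 1:
            raise ConfigError("outlier_fraction must be in [0, 1)")
        if self.n_contacts < 2:
            raise ConfigError("need at least 2 contacts (the stimulating pair)")

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid(self.shape, self.voxel_size_mm)

    def with_seed(self, seed: int) -> "PhantomConfig":
        return replace(self, rng_seed=int(seed))


#: low-noise variant used for consistency-recovery experiments: negligible
#: BOLD/waveform noise and strongly concentrated FODs (orientation dispersion
#: then contributes no pathway-score noise)
def low_noise(config: PhantomConfig) -> PhantomConfig:
    return replace(config, sigma_bold=0.05, sigma_ccep=0.5, kappa=40.0,
                   outlier_fraction=0.0)


@dataclass(frozen=True)
class Contact:
    contact_id: str
    world_mm: tuple[float, float, float]   # recorded (possibly jittered) position
    voxel: tuple[int, int, int]            # recorded position voxelized
    role: str                              # "stim" | "record"
    true_voxel: tuple[int, int, int]       # actual placement (signal source)


@dataclass
class ElectrodeTable:
    contacts: list[Contact]

    def __post_init__(self) -> None:
        ids = [c.contact_id for c in self.contacts]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate contact ids")
        if sum(1 for c in self.contacts if c.role == "stim") != 2:
            raise ConfigError("exactly one stim pair (two contacts) per session")

    def __getitem__(self, contact_id: str) -> Contact:
        for c in self.contacts:
            if c.contact_id == contact_id:
                return c
        raise KeyError(f"no contact {contact_id!r} in the electrode table")

    @property
    def stim_pair(self) -> tuple[Contact, Contact]:
        pair = [c for c in self.contacts if c.role == "stim"]
        return pair[0], pair[1]

    @property
    def stim_midpoint_mm(self) -> np.ndarray:
        a, b = self.stim_pair
        return (np.asarray(a.world_mm) + np.asarray(b.world_mm)) / 2.0

    def recording_contacts(self) -> list[Contact]:
        return [c for c in self.contacts if c.role == "record"]


@dataclass
class Masks:
    brain: np.ndarray
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    @property
    def tracking(self) -> np.ndarray:
        """White + gray matter: where pathways may run."""
        return self.gm | self.wm


def build_masks(network: GroundTruthNetwork, grid: VolumeGrid) -> Masks:
    """Brain sphere with bundle white matter and a small CSF pocket.

    Gray matter is the brain minus white matter and CSF; node patches are
    always gray.  The CSF pocket is placed at the first of a fixed list of
    candidate offsets that keeps 2.5 voxels clear of every patch and bundle
    (omitted, with no error, if none fits).
    """
    shape = np.asarray(grid.shape)
    center = shape / 2.0 - 0.5
    # generous radius: every node patch and bundle must stay well interior,
    # otherwise boundary renormalization of transition probabilities biases
    # pathway scores toward nodes near the mask edge
    radius = 0.47 * shape.min()
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij")
    dist = np.sqrt((ii - center[0]) ** 2 + (jj - center[1]) ** 2 + (kk - center[2]) ** 2)
    brain = dist <= radius

    patch = np.zeros(grid.shape, dtype=bool)
    for n in network.nodes:
        vox = network.patch_voxels(n.node_id, grid)
        patch[tuple(vox.T)] = True
        brain[tuple(vox.T)] = True  # patches always belong to the brain

    wm = np.zeros(grid.shape, dtype=bool)
    bundle_pts = []
    for e in network.edges:
        wm[tuple(e.bundle.T)] = True
        brain[tuple(e.bundle.T)] = True
        bundle_pts.append(e.bundle)
    wm &= ~patch
    occupied = np.column_stack(np.nonzero(patch | wm)) if (patch | wm).any() else None

    csf = np.zeros(grid.shape, dtype=bool)
    hub = np.asarray(network.nodes[0].center)
    for off in ((4, 4, 4), (-4, 4, 4), (4, -4, 4), (4, 4, -4),
                (-4, -4, 4), (-4, 4, -4), (4, -4, -4), (-4, -4, -4)):
        c = hub + np.asarray(off)
        if not bool(grid.contains(c)) or not brain[tuple(c)]:
            continue
        if occupied is not None:
            if np.linalg.norm(occupied - c, axis=1).min() <= 2.5:
                continue
        ball = dist_ball(grid.shape, c, 1.5)
        if (ball & ~brain).any():
            continue
        csf = ball
        break

    gm = brain & ~wm & ~csf
    return Masks(brain=brain, gm=gm, wm=wm, csf=csf)


def dist_ball(shape, center, radius: float) -> np.ndarray:
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    c = np.asarray(center)
    d = np.sqrt((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2)
    return d <= radius


def place_electrodes(
    network: GroundTruthNetwork,
    grid: VolumeGrid,
    n_contacts: int,
    gm_mask: np.ndarray,
    rng: np.random.Generator,
    jitter_mm: float = 0.0,
) -> ElectrodeTable:
    """Implant contacts: a stim pair on the hub, one per node patch, rest in GM.

    The stimulating pair occupies two adjacent voxels of the hub (node 0)
    patch; every other node patch gets one recording contact at its center;
    remaining contacts land on random gray-matter voxels on the same
    spherical shell (distance from the hub) as the satellite nodes, emulating
    a grid array at uniform distance from the stimulation site — this keeps
    the seed-distance profile, which every seed-based measure shares, flat
    across targets.  ``jitter_mm`` displaces the *recorded* world coordinates
    (emulating registration error / brain shift) while the true placement
    voxel still drives the simulated signals.
    """
    n_nodes = len(network.nodes)
    if n_contacts < n_nodes + 1:
        raise ConfigError(
            f"need >= {n_nodes + 1} contacts to cover {n_nodes} node patches "
            "plus the stim pair"
        )
    hub = np.asarray(network.nodes[0].center)
    placements: list[tuple[np.ndarray, str]] = [
        (hub, "stim"),
        (hub + np.array([1, 0, 0]), "stim"),
    ]
    for n in network.nodes[1:]:
        placements.append((np.asarray(n.center), "record"))

    gm_idx = np.column_stack(np.nonzero(gm_mask))
    taken = {tuple(p) for p, _ in placements}
    sat_dist = [np.linalg.norm(np.asarray(n.center) - hub) for n in network.nodes[1:]]
    free = np.array([v for v in map(tuple, gm_idx) if v not in taken], dtype=int)
    if sat_dist and len(free):
        shell_r = float(np.mean(sat_dist))
        d = np.linalg.norm(free - hub, axis=1)
        on_shell = np.abs(d - shell_r) <= 1.5
        if on_shell.sum() >= n_contacts:  # fall back to all GM on tiny grids
            free = free[on_shell]
    n_extra = n_contacts - len(placements)
    if n_extra > len(free):
        raise PlacementError("not enough gray-matter voxels for the requested contacts")
    if n_extra > 0:
        picks = rng.choice(len(free), size=n_extra, replace=False)
        for i in picks:
            placements.append((free[i], "record"))

    contacts = []
    for i, (vox, role) in enumerate(placements):
        true_world = grid.voxel_to_world(vox)
        if jitter_mm > 0:
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            recorded = true_world + rng.uniform(0, jitter_mm) * direction
        else:
            recorded = true_world
        rec_vox = grid.world_to_index(recorded)
        rec_vox = np.clip(rec_vox, 0, np.asarray(grid.shape) - 1)
        contacts.append(
            Contact(
                contact_id=f"C{i + 1:03d}",
                world_mm=tuple(float(x) for x in recorded),
                voxel=tuple(int(x) for x in rec_vox),
                role=role,
                true_voxel=tuple(int(x) for x in vox),
            )
        )
    return ElectrodeTable(contacts)


def render_fod_field(
    network: GroundTruthNetwork, grid: VolumeGrid, kappa: float
) -> FODField:
    """FOD field concentrated along bundle tangents, isotropic elsewhere.

    On-bundle voxels get an antipodally symmetric Watson-like lobe
    ``a_d ∝ ω_d · exp(κ·w · (u_d·t)²)`` along the bundle chord tangent ``t``
    (ω_d the solid-angle fraction of direction d, so κ = 0 reduces to the
    isotropic cell masses); voxels crossed by several bundles mix the lobes
    in proportion to the edge weights.
    """
    units, omega = neighbor_directions(grid.voxel_size)
    amp = np.tile(omega, grid.shape + (1,))

    lobe_sum: dict[tuple, np.ndarray] = {}
    lobe_w: dict[tuple, float] = {}
    for e in network.edges:
        if not grid.contains(e.bundle).all():
            raise ConfigError(f"bundle {e.node_a}-{e.node_b} leaves the grid")
        chord = grid.voxel_to_world(e.bundle[-1]) - grid.voxel_to_world(e.bundle[0])
        t = chord / max(np.linalg.norm(chord), 1e-12)
        cos2 = (units @ t) ** 2
        expo = kappa * e.weight * cos2
        lobe = omega * np.exp(expo - expo.max())
        lobe = lobe / lobe.sum()
        for vox in map(tuple, e.bundle):
            lobe_sum[vox] = lobe_sum.get(vox, 0.0) + e.weight * lobe
            lobe_w[vox] = lobe_w.get(vox, 0.0) + e.weight
    for vox, acc in lobe_sum.items():
        amp[vox] = acc / lobe_w[vox]
    return FODField(grid, amp)


@dataclass
class Phantom:
    """The full synthetic dataset derived from one ground-truth network."""

    config: PhantomConfig
    grid: VolumeGrid
    network: GroundTruthNetwork
    masks: Masks
    electrodes: ElectrodeTable
    fod: FODField
    stim_node: int = 0

    rest_bold: object = None
    des_bold: object = None
    des_signs: object = None
    ccep: object = None

    @property
    def seed_world_mm(self) -> np.ndarray:
        return self.electrodes.stim_midpoint_mm

    @property
    def seed_voxel(self) -> tuple[int, int, int]:
        idx = self.grid.world_to_index(self.seed_world_mm)
        return tuple(int(x) for x in idx)


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan one global seed out to independent per-stage generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def build_phantom(config: PhantomConfig, with_signals: bool = True) -> Phantom:
    """Generate the phantom; per-stage RNGs are spawned from ``rng_seed``.

    With ``with_signals=False`` only geometry (network, masks, electrodes,
    FOD) is produced, which is enough for the structural measure.
    """
    from . import simulate  # deferred: simulate imports this module's types

    grid = config.grid
    rng_net, rng_elec, rng_rest, rng_des, rng_ccep = _child_rngs(config.rng_seed, 5)
    network = generate_network(
        config.n_nodes, config.n_edges, config.weight_range, grid, rng_net,
        hub_distance=config.hub_distance, patch_radius=config.patch_radius,
        hub_jitter=config.hub_jitter_vox,
    )
    masks = build_masks(network, grid)
    electrodes = place_electrodes(
        network, grid, config.n_contacts, masks.gm, rng_elec, config.jitter_mm
    )
    fod = render_fod_field(network, grid, config.kappa)
    ph = Phantom(config=config, grid=grid, network=network, masks=masks,
                 electrodes=electrodes, fod=fod, stim_node=0)
    if with_signals:
        ph.rest_bold = simulate.simulate_rsfmri(network, grid, masks, config, rng_rest)
        ph.des_bold, ph.des_signs = simulate.simulate_des_fmri(
            network, grid, masks, ph.stim_node, config, rng_des
        )
        a, b = electrodes.stim_pair
        ph.ccep = simulate.simulate_ccep(
            network, electrodes, (a.contact_id, b.contact_id), config, rng_ccep
        )
    return ph
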