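"""Signal simulators of the multimodal phantom.

All three simulators draw their signal strength from the same latent
quantity — the ground-truth path strength from the stimulated (hub) node —
so that, at zero noise, every modality ranks the target nodes identically.
"""

from __future__ import annotations

import numpy as np

from . import desfmri
from .errors import ConfigError
from .grid import VolumeGrid
from .network import GroundTruthNetwork
from .phantom import ElectrodeTable, Masks, PhantomConfig
from .ccep import CCEPTrialSet, ContactEpochs
from .rsfmri import BOLDSeries


def ar1_series(rng: np.random.Generator, n: int, t: int, rho: float) -> np.ndarray:
    """(n, t) independent AR(1) series with unit marginal variance."""
    x = np.empty((n, t))
    x[:, 0] = rng.standard_normal(n)
    innov_sd = np.sqrt(1.0 - rho**2)
    for i in range(1, t):
        x[:, i] = rho * x[:, i - 1] + innov_sd * rng.standard_normal(n)
    return x


def _latent_factor(strength: np.ndarray) -> np.ndarray:
    """Mixing matrix L with L L^T = the (PSD-clipped) strength matrix.

    The target inter-node correlation matrix is the path-strength matrix
    itself (exactly realizable for trees; clipped to the nearest PSD matrix
    otherwise), rescaled so every latent keeps unit variance.
    """
    r = np.asarray(strength, dtype=float)
    vals, vecs = np.linalg.eigh((r + r.T) / 2.0)
    vals = np.clip(vals, 1e-9, None)
    l = vecs * np.sqrt(vals)
    norm = np.sqrt((l**2).sum(axis=1, keepdims=True))
    return l / norm


def simulate_rsfmri(
    network: GroundTruthNetwork,
    grid: VolumeGrid,
    masks: Masks,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> BOLDSeries:
    """Resting BOLD whose inter-node correlations equal the path strengths.

    Node patches carry correlated unit-variance AR(1) latents (correlation
    matrix = path-strength matrix); all other brain voxels carry independent
    AR(1) fluctuations; white noise of sd ``sigma_bold`` is added everywhere
    in the brain.
    """
    t = config.rest_volumes
    n_nodes = len(network.nodes)
    l = _latent_factor(network.strength_matrix())
    z = ar1_series(rng, n_nodes, t, config.ar_rho)
    latents = l @ z  # (n_nodes, t), unit variance, corr = strengths

    data = np.zeros(grid.shape + (t,))
    in_patch = np.zeros(grid.shape, dtype=bool)
    for n in network.nodes:
        vox = network.patch_voxels(n.node_id, grid)
        data[tuple(vox.T)] = latents[n.node_id]
        in_patch[tuple(vox.T)] = True

    background = masks.brain & ~in_patch
    n_bg = int(background.sum())
    if n_bg:
        data[background] = ar1_series(rng, n_bg, t, config.ar_rho)
    if config.sigma_bold > 0:
        data[masks.brain] += config.sigma_bold * rng.standard_normal(
            (int(masks.brain.sum()), t)
        )
    return BOLDSeries(grid, data, config.tr_s)


def simulate_des_fmri(
    network: GroundTruthNetwork,
    grid: VolumeGrid,
    masks: Masks,
    stim_node: int,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> tuple[BOLDSeries, dict[int, int]]:
    """Block-design stimulation BOLD: activation amplitude ∝ path strength.

    Each connected node patch responds with the HRF-convolved boxcar scaled
    by ``des_amp * path_strength``; the response sign is drawn per node from
    a positive/negative mixture (``negative_fraction``) to emulate robust
    deactivation.  The stimulated node itself always responds positively.
    White noise of sd ``sigma_bold`` covers the brain.  Returns the series
    and the per-node signs.
    """
    design = desfmri.build_design(
        config.block_s, config.tr_s, config.n_blocks, config.des_total_s
    )
    task = design.task
    t = design.n_volumes

    signs: dict[int, int] = {}
    data = np.zeros(grid.shape + (t,))
    for n in network.nodes:
        s = network.path_strength(stim_node, n.node_id)
        if s <= 0:
            continue
        sign = 1 if n.node_id == stim_node else (
            -1 if rng.random() < config.negative_fraction else 1
        )
        signs[n.node_id] = sign
        vox = network.patch_voxels(n.node_id, grid)
        # no activation is ever written into CSF
        keep = ~masks.csf[tuple(vox.T)]
        data[tuple(vox[keep].T)] = sign * config.des_amp * s * task
    if config.sigma_bold > 0:
        data[masks.brain] += config.sigma_bold * rng.standard_normal(
            (int(masks.brain.sum()), t)
        )
    return BOLDSeries(grid, data, config.tr_s), signs


def evoked_template(t_ms: np.ndarray, latency_ms: float = 100.0) -> np.ndarray:
    """Fixed biphasic evoked waveform, unit trough magnitude.

    A downward peak at ``latency_ms`` followed by an upward peak 130 ms
    later, mimicking the typical averaged evoked response shape.
    """
    t = np.asarray(t_ms, dtype=float)
    wave = -np.exp(-0.5 * ((t - latency_ms) / 30.0) ** 2) + 0.45 * np.exp(
        -0.5 * ((t - latency_ms - 130.0) / 50.0) ** 2
    )
    return wave / np.abs(wave).max()


def stimulation_artifact(t_ms: np.ndarray, amp_uv: float, tau_ms: float = 3.0) -> np.ndarray:
    """Decaying stimulation transient starting at t = 0 (polarity applied by caller)."""
    t = np.asarray(t_ms, dtype=float)
    return np.where(t >= 0.0, amp_uv * np.exp(-np.maximum(t, 0.0) / tau_ms), 0.0)


def simulate_ccep(
    network: GroundTruthNetwork,
    electrodes: ElectrodeTable,
    stim_pair: tuple[str, str],
    config: PhantomConfig,
    rng: np.random.Generator,
) -> CCEPTrialSet:
    """Stimulus-locked epochs at every recording contact.

    Each of the ``n_trials`` pulses (alternating polarity) produces a
    polarity-signed decaying stimulation artifact at every contact plus, at
    contacts whose nearest node is connected to the stimulated node, a fixed
    biphasic evoked waveform with peak amplitude ``ccep_amp_uv * path
    strength`` and latency growing by ``latency_per_edge_ms`` per extra edge
    on the strongest path.  A fraction of trials is corrupted by
    large-amplitude motion-like transients, recorded in the provenance.
    """
    try:
        sa = electrodes[stim_pair[0]]
        sb = electrodes[stim_pair[1]]
    except KeyError as err:
        raise KeyError(f"stim pair {stim_pair} not in the electrode table") from err
    stim_node = network.node_containing(sa.true_voxel)
    if stim_node is None:
        stim_node = network.node_containing(sb.true_voxel)
    if stim_node is None:
        raise ConfigError("stimulating pair does not sit on any node patch")

    fs = config.sampling_rate_hz
    pre = int(round(config.epoch_pre_ms * fs / 1000.0))
    post = int(round(config.epoch_post_ms * fs / 1000.0))
    n_samp = pre + post
    t_ms = (np.arange(n_samp) - pre) * 1000.0 / fs
    polarity = np.where(np.arange(config.n_trials) % 2 == 0, 1, -1)
    artifact = stimulation_artifact(t_ms, config.artifact_amp_uv)

    n_out = int(round(config.outlier_fraction * config.n_trials))
    corrupted = np.sort(rng.choice(config.n_trials, size=n_out, replace=False)) if n_out else np.array([], dtype=int)

    contacts: dict[str, ContactEpochs] = {}
    for c in electrodes.recording_contacts():
        node = network.node_containing(c.true_voxel)
        if node is None:
            strength, hops = 0.0, 0
        else:
            strength = network.path_strength(stim_node, node)
            hops = network.path_hops(stim_node, node)
        latency = config.latency_ms + max(hops - 1, 0) * config.latency_per_edge_ms
        evoked = (
            config.ccep_amp_uv * strength * evoked_template(t_ms, latency)
            if strength > 0
            else np.zeros(n_samp)
        )
        epochs = polarity[:, None] * artifact[None, :] + evoked[None, :]
        if config.sigma_ccep > 0:
            epochs = epochs + config.sigma_ccep * rng.standard_normal(epochs.shape)
        for trial in corrupted:
            onset = rng.integers(0, n_samp - 50)
            burst = 20.0 * config.ccep_amp_uv * np.hanning(50)
            epochs[trial, onset : onset + 50] += burst * rng.choice([-1.0, 1.0])
        contacts[c.contact_id] = ContactEpochs(epochs, polarity)

    return CCEPTrialSet(
        sampling_rate=fs,
        stim_index=pre,
        contacts=contacts,
        provenance={
            "stim_pair": list(stim_pair),
            "stim_node": int(stim_node),
            "corrupted_trials": corrupted.tolist(),
        },
    )
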