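"""Cortico-cortical evoked potential (CCEP) scoring.

Low-frequency (1 Hz) unipolar pulses with alternating polarity are delivered
across one electrode pair while voltage is recorded at every other implanted
contact at 1 kHz.  Connectivity at a recording contact is a scalar score of
the trial-averaged, baseline-subtracted waveform over a post-stimulus window:
a short early window (10-15 ms) reflecting fast first-pass excitation, or a
longer window (20-120 ms) reflecting integrative responses.

Because the stimulation artifact flips sign with the pulse polarity while the
evoked response does not, a plain mean over balanced trials cancels the
artifact exactly; outlier trials (motion and similar transients) are removed
beforehand with a robust median/MAD rule on per-trial RMS deviation.

All voltages are in microvolts (uV); all windows are in milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataUnusableError, EpochingError


@dataclass
class ContactEpochs:
    """Stimulus-locked epochs for one recording contact.

    ``epochs`` is (n_trials, n_samples) in uV; ``polarity`` is the per-trial
    stimulation polarity (+1/-1), same length as the trial axis.
    """

    epochs: np.ndarray
    polarity: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.polarity = np.asarray(self.polarity, dtype=int)
        if self.epochs.ndim != 2:
            raise ConfigError("epochs must be 2D (n_trials, n_samples)")
        if self.polarity.shape != (self.epochs.shape[0],):
            raise ConfigError("polarity length must equal the number of trials")
        if not np.isin(self.polarity, (-1, 1)).all():
            raise ConfigError("polarity entries must be +1 or -1")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]


@dataclass
class CCEPTrialSet:
    """Epochs for all recording contacts of one stimulation session.

    All contacts share the epoch geometry: sampling rate, number of samples
    and the sample index of the stimulus within each epoch.
    """

    sampling_rate: float
    stim_index: int
    contacts: dict[str, ContactEpochs]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.contacts:
            raise ConfigError("trial set has no contacts")
        n_samples = {c.epochs.shape[1] for c in self.contacts.values()}
        if len(n_samples) != 1:
            raise ConfigError("all contacts must share the epoch geometry")
        ns = n_samples.pop()
        if not 0 <= self.stim_index < ns:
            raise ConfigError("stim_index must fall inside the epoch")

    @property
    def n_samples(self) -> int:
        return next(iter(self.contacts.values())).epochs.shape[1]


@dataclass
class CCEPAverage:
    """Trial-averaged waveform for one contact (uV)."""

    waveform: np.ndarray
    sampling_rate: float
    stim_index: int
    n_used: int
    baseline_value: float = 0.0
    polarity_imbalance: int = 0  # sum of retained polarities; 0 = balanced


@dataclass(frozen=True)
class ScoreWindow:
    """Post-stimulus scoring window (offsets in ms after the stimulus)."""

    start_ms: float
    duration_ms: float
    purpose: str = "functional"

    def __post_init__(self) -> None:
        # averaged responses are reliable no earlier than ~5 ms post stimulus
        if self.start_ms < 5:
            raise ConfigError("score window must start at least 5 ms after the stimulus")
        if self.duration_ms <= 0:
            raise ConfigError("score window duration must be positive")
        if self.purpose not in ("structural", "functional"):
            raise ConfigError("window purpose must be 'structural' or 'functional'")


#: 5 ms window starting 10 ms post stimulus: fast first-pass excitation,
#: used against structural connectivity.
STRUCTURAL_WINDOW = ScoreWindow(10.0, 5.0, "structural")
#: 100 ms window starting 20 ms post stimulus: integrative response,
#: used against resting-state connectivity.
FUNCTIONAL_WINDOW = ScoreWindow(20.0, 100.0, "functional")


def extract_epochs(
    recording: dict[str, np.ndarray],
    stim_onsets: np.ndarray,
    pre_ms: float,
    post_ms: float,
    sampling_rate: float = 1000.0,
    polarity: np.ndarray | None = None,
) -> CCEPTrialSet:
    """Cut continuous per-contact recordings into stimulus-locked epochs.

    Epochs span ``[onset - pre_ms, onset + post_ms)`` so the stimulus lands at
    the same sample index in every trial.  ``polarity`` defaults to strict
    alternation starting at +1.
    """
    onsets = np.asarray(stim_onsets, dtype=int)
    if onsets.size == 0:
        raise EpochingError("no stimulus onsets supplied")
    pre = int(round(pre_ms * sampling_rate / 1000.0))
    post = int(round(post_ms * sampling_rate / 1000.0))
    if polarity is None:
        polarity = np.where(np.arange(onsets.size) % 2 == 0, 1, -1)
    polarity = np.asarray(polarity, dtype=int)
    if polarity.shape != onsets.shape:
        raise ConfigError("polarity must match the number of onsets")

    contacts: dict[str, ContactEpochs] = {}
    for name, trace in recording.items():
        trace = np.asarray(trace, dtype=float)
        n = trace.shape[-1]
        epochs = np.empty((onsets.size, pre + post))
        for t, onset in enumerate(onsets):
            lo, hi = onset - pre, onset + post
            if lo < 0 or hi > n:
                raise EpochingError(
                    f"trial {t} (onset sample {onset}) needs samples [{lo}, {hi}) "
                    f"but the recording has {n}"
                )
            epochs[t] = trace[lo:hi]
        contacts[name] = ContactEpochs(epochs, polarity)
    return CCEPTrialSet(sampling_rate, pre, contacts)


def reject_outlier_trials(trials: CCEPTrialSet, k: float = 5.0) -> CCEPTrialSet:
    """Drop trials whose RMS deviation from the per-sample median trace is extreme.

    For each contact, every trial's RMS deviation from the per-sample median
    waveform of *its own polarity group* is computed (the group-wise median
    keeps the huge polarity-locked stimulation artifact out of every
    deviation, so the statistics stay robust even when a transient overlaps
    the artifact); trials beyond ``median + k * MAD`` of the pooled deviation
    distribution are discarded.  At most 50% of trials are ever removed (the
    worst offenders are kept flagged, with a warning); if the rule would flag
    every trial the data are unusable and an error is raised.
    """
    new_contacts: dict[str, ContactEpochs] = {}
    removed: dict[str, list[int]] = {}
    for name, ce in trials.contacts.items():
        n = ce.n_trials
        if n < 4:
            raise ConfigError(f"contact {name}: need >= 4 trials for outlier rejection, got {n}")
        dev = np.empty(n)
        for pol in np.unique(ce.polarity):
            grp = ce.polarity == pol
            median_trace = np.median(ce.epochs[grp], axis=0)
            dev[grp] = np.sqrt(np.mean((ce.epochs[grp] - median_trace) ** 2, axis=1))
        med = np.median(dev)
        mad = np.median(np.abs(dev - med))
        flagged = dev > med + k * mad
        if flagged.all():
            raise DataUnusableError(f"contact {name}: every trial flagged as outlier")
        if flagged.sum() > n // 2:
            warnings.warn(
                f"contact {name}: outlier rule flagged {int(flagged.sum())}/{n} trials; "
                "capping removal at 50%",
                stacklevel=2,
            )
            worst = np.argsort(dev)[::-1][: n // 2]
            flagged = np.zeros(n, dtype=bool)
            flagged[worst] = True
        keep = ~flagged
        new_contacts[name] = ContactEpochs(ce.epochs[keep], ce.polarity[keep])
        removed[name] = np.flatnonzero(flagged).tolist()
    prov = dict(trials.provenance)
    prov["rejected_trials"] = removed
    prov["rejection_k"] = k
    return CCEPTrialSet(trials.sampling_rate, trials.stim_index, new_contacts, prov)


def average_with_polarity(trials: CCEPTrialSet) -> dict[str, CCEPAverage]:
    """Plain mean across retained trials per contact.

    The evoked response is polarity-independent while the stimulation artifact
    flips sign with polarity, so with balanced polarities the mean cancels the
    artifact exactly.  Residual imbalance (sum of retained polarities) is
    recorded per contact.
    """
    out: dict[str, CCEPAverage] = {}
    for name, ce in trials.contacts.items():
        if ce.n_trials == 0:
            raise DataUnusableError(f"contact {name}: no trials to average")
        imbalance = int(ce.polarity.sum())
        out[name] = CCEPAverage(
            waveform=ce.epochs.mean(axis=0),
            sampling_rate=trials.sampling_rate,
            stim_index=trials.stim_index,
            n_used=ce.n_trials,
            polarity_imbalance=imbalance,
        )
    return out


def subtract_baseline(
    avg: CCEPAverage, baseline_ms: float = 40.0, gap_ms: float = 5.0
) -> CCEPAverage:
    """Subtract the scalar pre-stimulus baseline from an averaged waveform.

    The baseline is the mean over the window
    ``[stim - gap_ms - baseline_ms, stim - gap_ms)``; the gap keeps any
    residual artifact bleed out of the estimate.
    """
    fs = avg.sampling_rate
    n_base = int(round(baseline_ms * fs / 1000.0))
    n_gap = int(round(gap_ms * fs / 1000.0))
    lo = avg.stim_index - n_gap - n_base
    hi = avg.stim_index - n_gap
    if lo < 0 or n_base < 1:
        raise EpochingError(
            f"epoch has only {avg.stim_index} pre-stimulus samples; "
            f"{n_base + n_gap} needed for a {baseline_ms} ms baseline + {gap_ms} ms gap"
        )
    baseline = float(avg.waveform[lo:hi].mean())
    return CCEPAverage(
        waveform=avg.waveform - baseline,
        sampling_rate=fs,
        stim_index=avg.stim_index,
        n_used=avg.n_used,
        baseline_value=baseline,
        polarity_imbalance=avg.polarity_imbalance,
    )


def score_window(
    avg: CCEPAverage, window: ScoreWindow, statistic: str = "mean"
) -> float:
    """Scalar connectivity score of a waveform over a post-stimulus window.

    ``statistic`` is ``"mean"`` (signed mean voltage, matching a mean-voltage
    score) or ``"abs_mean"`` (mean of absolute voltage, the rectified variant
    used when polarity is irrelevant to the comparison).
    """
    fs = avg.sampling_rate
    lo = avg.stim_index + int(round(window.start_ms * fs / 1000.0))
    hi = lo + int(round(window.duration_ms * fs / 1000.0))
    if hi > avg.waveform.size or lo < 0:
        raise EpochingError(
            f"score window [{window.start_ms}, {window.start_ms + window.duration_ms}) ms "
            "falls outside the epoch"
        )
    seg = avg.waveform[lo:hi]
    if statistic == "mean":
        return float(seg.mean())
    if statistic == "abs_mean":
        return float(np.abs(seg).mean())
    raise ConfigError(f"unknown statistic {statistic!r}")


def score_contacts(
    trials: CCEPTrialSet,
    window: ScoreWindow,
    statistic: str = "mean",
    k: float = 5.0,
    baseline_ms: float = 40.0,
    gap_ms: float = 5.0,
) -> dict[str, float]:
    """Full per-contact scoring chain: reject -> average -> baseline -> score."""
    cleaned = reject_outlier_trials(trials, k=k)
    averages = average_with_polarity(cleaned)
    return {
        name: score_window(subtract_baseline(avg, baseline_ms, gap_ms), window, statistic)
        for name, avg in averages.items()
    }
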