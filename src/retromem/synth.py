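"""Synthetic epoched EEG and behavior with controllable effect sizes.

The generator emulates the statistical structure the downstream analyses
assume, so that every stage of the pipeline (ERP cluster statistics,
location decoding, behavioral battery) can be exercised and calibrated
without real recordings:

* a condition-graded positivity over the left-parietal channels
  (Pz, P1, P3, P5) in the retrieval phase — the old-new effect;
* four location-specific multichannel patterns, active inside phase-specific
  time windows, whose similarity across phases is a tunable parameter
  ``rho`` (1 = identical format across phases, 0 = orthogonal formats);
* spatially correlated 1/f noise;
* per-condition Bernoulli accuracy and log-normal response times with
  participant-level heterogeneity.

All effect sizes may be set to zero, which turns the generator into a null
model for false-positive-rate calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .scheduler import LOCATIONS, PhaseSchedule, ObjectSpec, count_probe_instances

# 64-channel extended 10/20 layout (easycap style, FCz reference not recorded)
CHANNELS_64 = (
    "Fp1 Fp2 AF7 AF3 AF4 AF8 F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT9 FT7 FC5 FC3 FC1 FC2 FC4 FC6 FT8 FT10 "
    "T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP9 TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 TP10 "
    "P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO9 PO7 PO3 POz PO4 PO8 PO10 O1 Oz O2"
).split()

PARIETAL_CLUSTER = ("Pz", "P1", "P3", "P5")

EPOCH_WINDOWS_MS = {
    "encoding": (-500.0, 1000.0),
    "wm": (-500.0, 3000.0),
    "retrieval": (-500.0, 2500.0),
}

# phase-specific windows in which the location signal is active (ms)
PHASE_SIGNAL_WINDOWS_MS = {
    "encoding": (60.0, 1000.0),
    "wm": (70.0, 1460.0),
    "retrieval": (330.0, 1360.0),
}

# retrieval-phase accuracy / response-time parameters per condition
ACCURACY_EXP1 = {"PT": 0.8168, "NP": 0.7112, "ABS": 0.6591}
ACCURACY_EXP2 = {"PT": 0.7965, "NPT": 0.7147, "NP": 0.6775, "ABS": 0.6461}
RT_MEAN_SD_EXP1 = {
    "PT": (1060.80, 294.63),
    "NP": (1166.81, 342.96),
    "ABS": (1206.22, 350.33),
}
RT_MEAN_SD_EXP2 = {
    "PT": (1108.37, 273.99),
    "NPT": (1164.54, 291.11),
    "NP": (1220.77, 342.00),
    "ABS": (1229.77, 369.52),
}


_POSITION_CACHE: dict = {}


def channel_positions(labels=CHANNELS_64) -> np.ndarray:
    """3-D head positions (meters) for the given 10/20-style labels."""
    key = tuple(labels)
    if key in _POSITION_CACHE:
        return _POSITION_CACHE[key]
    import warnings

    import mne

    with warnings.catch_warnings():
        # montage naming is in transition upstream; either name resolves to
        # the same colin27-based 10-05 positions
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    arr = np.array([pos[ch] for ch in labels])
    _POSITION_CACHE[key] = arr
    return arr


@dataclass
class GeneratorParams:
    """All knobs of the synthetic experiment.

    Amplitudes are in μV; windows in ms. ``oldnew_amplitude`` orders the
    retrieval-phase parietal positivity by condition; setting every entry to
    zero yields the global null. ``cross_phase_similarity`` is the cosine
    similarity of a location's pattern between any two phases.
    """

    experiment: int = 1
    n_participants: int = 43
    n_objects: int | None = None  # default: 180 (Exp 1) / 300 (Exp 2)
    n_channels: int = 64
    srate: float = 250.0
    oldnew_amplitude: dict = field(
        default_factory=lambda: {"PT": 1.5, "NPT": 1.0, "NP": 0.5, "ABS": 0.0}
    )
    oldnew_window: tuple = (430.0, 670.0)
    location_signal_amplitude: float = 2.0
    cross_phase_similarity: float = 0.8
    noise_sd: float = 5.0
    noise_spectral_exponent: float = 1.0
    spatial_mixing_scale: float = 0.12  # meters; noise correlation decay
    participant_amplitude_sd: float = 0.3  # log-scale SD of per-subject gain
    behavior_accuracy: dict | None = None  # default per experiment
    behavior_rt: dict | None = None  # condition -> (mean ms, sd ms)
    participant_accuracy_sd: float = 0.10
    participant_rt_sd: float = 0.12  # log-scale SD of per-subject RT gain
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cross_phase_similarity <= 1.0:
            raise ValueError("cross_phase_similarity must lie in [0, 1]")
        if self.n_objects is None:
            self.n_objects = 180 if self.experiment == 1 else 300
        if self.behavior_accuracy is None:
            self.behavior_accuracy = dict(
                ACCURACY_EXP1 if self.experiment == 1 else ACCURACY_EXP2
            )
        if self.behavior_rt is None:
            self.behavior_rt = dict(
                RT_MEAN_SD_EXP1 if self.experiment == 1 else RT_MEAN_SD_EXP2
            )
        for p in self.behavior_accuracy.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("accuracy probabilities must lie in [0, 1]")


@dataclass
class EEGEpochs:
    """Epoched data for one participant: (trial, channel, time) in μV."""

    data: np.ndarray
    times: np.ndarray  # ms
    srate: float
    channel_labels: list
    metadata: pd.DataFrame  # one row per trial

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.metadata):
            raise ValueError("metadata length must equal the number of trials")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels length must equal data.shape[1]")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EEGEpochs":
        return EEGEpochs(
            self.data.copy(),
            self.times.copy(),
            self.srate,
            list(self.channel_labels),
            self.metadata.copy(),
        )


def phase_times(phase: str, srate: float) -> np.ndarray:
    t0, t1 = EPOCH_WINDOWS_MS[phase]
    dt = 1000.0 / srate
    return np.arange(t0, t1 + dt / 2, dt)


def half_cosine_envelope(times: np.ndarray, window: tuple) -> np.ndarray:
    """Smooth positive bump: sin(π x) on the window, 0 outside, peak 1."""
    t0, t1 = window
    x = (times - t0) / (t1 - t0)
    env = np.sin(np.pi * np.clip(x, 0.0, 1.0))
    env[(x < 0) | (x > 1)] = 0.0
    return env


def generate_location_patterns(
    n_channels: int,
    n_locations: int,
    rho: float,
    seed: int,
    phases: tuple = ("encoding", "wm", "retrieval"),
) -> dict:
    """Per-phase location patterns with exact cross-phase cosine ``rho``.

    A shared orthonormal block S (channels × locations) and one
    phase-specific orthonormal block P_phase per phase are drawn so that all
    blocks are mutually orthogonal; the pattern for location l in a phase is
    ``sqrt(rho)·S_l + sqrt(1-rho)·P_l``. Consequences, exactly by
    construction: within each phase the pattern Gram matrix is the identity;
    the cosine between one location's patterns in two phases is ``rho``;
    patterns of different locations are orthogonal across phases.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if n_locations < 2:
        raise ValueError("need at least 2 locations")
    n_blocks = (1 + len(phases)) * n_locations
    if n_channels < n_blocks:
        raise ValueError(
            f"n_channels={n_channels} too small for {n_blocks} orthogonal components"
        )
    rng = np.random.default_rng(seed)
    basis, _ = np.linalg.qr(rng.standard_normal((n_channels, n_blocks)))
    shared = basis[:, :n_locations]
    out = {}
    for i, phase in enumerate(phases):
        spec = basis[:, (i + 1) * n_locations : (i + 2) * n_locations]
        out[phase] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * spec
    return out


def parietal_topography(labels=CHANNELS_64, cluster=PARIETAL_CLUSTER, scale=0.06):
    """Old-new component weights: Gaussian falloff around the cluster centroid.

    Normalized so that the mean weight over the cluster channels is 1, which
    makes injected cluster-averaged amplitudes equal the nominal μV value.
    """
    pos = channel_positions(labels)
    idx = [labels.index(ch) for ch in cluster]
    center = pos[idx].mean(axis=0)
    d = np.linalg.norm(pos - center, axis=1)
    w = np.exp(-0.5 * (d / scale) ** 2)
    return w / w[idx].mean()


def spatial_mixing_matrix(labels=CHANNELS_64, scale=0.12) -> np.ndarray:
    """Cholesky factor of a distance-decaying channel correlation matrix."""
    pos = channel_positions(labels)
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    corr = np.exp(-d / scale)
    corr += 1e-9 * np.eye(len(labels))
    return np.linalg.cholesky(corr)


def one_over_f_noise(
    rng: np.random.Generator,
    shape: tuple,
    srate: float,
    exponent: float,
    sd: float,
    mixing: np.ndarray | None = None,
) -> np.ndarray:
    """Spatially mixed 1/f^exponent noise, unit-variance scaled to ``sd`` μV.

    ``shape`` is (..., n_channels, n_times); mixing (a Cholesky factor of a
    channel correlation matrix) is applied over the channel axis.
    """
    n_times = shape[-1]
    freqs = np.fft.rfftfreq(n_times, d=1.0 / srate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = rng.standard_normal(shape[:-1] + (len(freqs),)) + 1j * rng.standard_normal(
        shape[:-1] + (len(freqs),)
    )
    x = np.fft.irfft(spec * amp, n=n_times, axis=-1)
    # analytic per-sample std of the irfft of a Hermitian complex-normal
    # spectrum: (2/n) * sqrt(sum(amp^2)) (DC/Nyquist terms are zero/negligible)
    x *= sd * n_times / (2.0 * np.sqrt(np.sum(amp**2)))
    if mixing is not None:
        x = np.einsum("ij,...jt->...it", mixing, x)
    return x


def _participant_rng(params: GeneratorParams, participant: int, stream: str):
    import zlib

    ss = np.random.SeedSequence(
        entropy=params.seed,
        spawn_key=(participant, zlib.crc32(stream.encode()) % (2**31)),
    )
    return np.random.default_rng(ss)


def _trial_location_labels(
    phase: str, schedule: PhaseSchedule, objects: list, rng
) -> tuple[list, list, list]:
    """Per-trial (object_id, location, condition) for any phase schedule."""
    by_id = {o.object_id: o for o in objects}
    oids, locs, conds = [], [], []
    if phase == "wm":
        for t in schedule.trials:
            if t.cue_type == "selective":
                h = by_id[t.object_on_horizontal_axis]
                v = by_id[t.object_on_vertical_axis]
                obj = h if h.condition == "PT" else v
            else:
                pick = rng.integers(2)
                obj = by_id[
                    (t.object_on_horizontal_axis, t.object_on_vertical_axis)[pick]
                ]
            oids.append(obj.object_id)
            locs.append(obj.location)
            conds.append(obj.condition)
    else:
        for oid in schedule.trials:
            obj = by_id[oid]
            oids.append(obj.object_id)
            locs.append(obj.location)
            conds.append(obj.condition)
    return oids, locs, conds


def simulate_phase_epochs(
    phase: str,
    schedule: PhaseSchedule,
    params: GeneratorParams,
    objects: list,
    patterns: dict | None = None,
    participant: int = 0,
    probing_counts: dict | None = None,
    mixing: np.ndarray | None = None,
    channel_labels=None,
    topography: np.ndarray | None = None,
) -> EEGEpochs:
    """One participant's epochs for one phase.

    Each trial is ``amplitude × location pattern × temporal envelope`` inside
    the phase's signal window, plus (retrieval only) the condition-scaled
    parietal old-new component, plus spatially mixed 1/f noise. Deterministic
    given (params.seed, participant, phase).
    """
    if schedule.phase != phase:
        raise ValueError(f"schedule is for phase {schedule.phase!r}, not {phase!r}")
    labels = list(channel_labels) if channel_labels is not None else list(CHANNELS_64[: params.n_channels])
    n_ch = len(labels)
    times = phase_times(phase, params.srate)
    rng = _participant_rng(params, participant, phase)
    if patterns is None:
        patterns = generate_location_patterns(n_ch, len(LOCATIONS), params.cross_phase_similarity, params.seed)
    oids, locs, conds = _trial_location_labels(phase, schedule, objects, rng)
    n_trials = len(oids)

    gain = float(np.exp(rng.normal(0.0, params.participant_amplitude_sd)))
    env = half_cosine_envelope(times, PHASE_SIGNAL_WINDOWS_MS[phase])
    loc_idx = np.array([LOCATIONS.index(l) for l in locs])
    pat = patterns[phase][:, loc_idx].T  # (trial, channel)
    data = (
        gain
        * params.location_signal_amplitude
        * pat[:, :, None]
        * env[None, None, :]
    )

    if phase == "retrieval" and any(params.oldnew_amplitude.get(c, 0.0) for c in conds):
        if topography is None:
            topography = parietal_topography(labels)
        env_on = half_cosine_envelope(times, params.oldnew_window)
        amp = np.array([params.oldnew_amplitude.get(c, 0.0) for c in conds])
        data = data + gain * amp[:, None, None] * topography[None, :, None] * env_on[None, None, :]

    if params.noise_sd > 0:
        if mixing is None:
            mixing = spatial_mixing_matrix(labels, params.spatial_mixing_scale)
        data = data + one_over_f_noise(
            rng,
            (n_trials, n_ch, len(times)),
            params.srate,
            params.noise_spectral_exponent,
            params.noise_sd,
            mixing,
        )

    probing_counts = probing_counts or {}
    meta = pd.DataFrame(
        {
            "phase": phase,
            "trial_index": np.arange(n_trials),
            "object_id": oids,
            "condition": conds,
            "location": locs,
            "probing_count": [probing_counts.get(o, 0) for o in oids],
        }
    )
    return EEGEpochs(data=data, times=times, srate=params.srate, channel_labels=labels, metadata=meta)


def simulate_retrieval_erp(
    schedule: PhaseSchedule,
    params: GeneratorParams,
    objects: list,
    participant: int = 0,
    probing_counts: dict | None = None,
    **kwargs,
) -> EEGEpochs:
    """Retrieval-phase epochs including the condition-scaled old-new component."""
    return simulate_phase_epochs(
        "retrieval", schedule, params, objects, participant=participant,
        probing_counts=probing_counts, **kwargs,
    )


def simulate_behavior(
    schedule: PhaseSchedule,
    params: GeneratorParams,
    objects: list,
    participant: int = 0,
    probing_counts: dict | None = None,
) -> pd.DataFrame:
    """Retrieval-phase behavior: Bernoulli accuracy, log-normal RT per trial.

    Per-participant heterogeneity: the accuracy probability of every
    condition is shifted by a common normal deviate (clipped to [0.02,
    0.98]) and RTs share a log-normal participant gain, so between-subject
    spread resembles the empirical tables while condition *means* across
    many participants converge to the configured parameters.
    """
    if schedule.phase != "retrieval":
        raise ValueError("behavior is defined on the retrieval schedule")
    rng = _participant_rng(params, participant, "behavior")
    by_id = {o.object_id: o for o in objects}
    shift = rng.normal(0.0, params.participant_accuracy_sd)
    rt_gain = np.exp(rng.normal(0.0, params.participant_rt_sd) - params.participant_rt_sd**2 / 2)
    probing_counts = probing_counts or {}
    rows = []
    for i, oid in enumerate(schedule.trials):
        obj = by_id[oid]
        p = float(np.clip(params.behavior_accuracy[obj.condition] + shift, 0.02, 0.98))
        m, s = params.behavior_rt[obj.condition]
        sigma2 = np.log(1.0 + (s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        rt = float(np.exp(rng.normal(mu, np.sqrt(sigma2)))) * rt_gain
        rows.append(
            {
                "participant": participant,
                "trial_index": i,
                "object_id": oid,
                "condition": obj.condition,
                "probing_count": probing_counts.get(oid, 0),
                "accuracy": int(rng.random() < p),
                "rt": rt,
            }
        )
    return pd.DataFrame(rows)


class SyntheticExperiment:
    """Schedules + generator for a full multi-participant experiment.

    Schedules are drawn once (all participants share the design layout, as
    in a yoked design); EEG and behavior are drawn per participant from
    deterministic substreams of ``params.seed``.
    """

    def __init__(self, params: GeneratorParams):
        from . import scheduler as sch

        self.params = params
        seed = params.seed
        self.objects = sch.assign_conditions(params.n_objects, params.experiment, seed)
        self.encoding = sch.build_encoding_schedule(self.objects, seed + 1)
        self.wm = sch.build_wm_schedule(self.objects, params.experiment, seed + 2)
        self.retrieval = sch.build_retrieval_schedule(self.objects, seed + 3)
        self.probing_counts = count_probe_instances(self.wm)
        self.channel_labels = list(CHANNELS_64[: params.n_channels])
        self.patterns = generate_location_patterns(
            params.n_channels, len(LOCATIONS), params.cross_phase_similarity, seed
        )
        self._mixing = None
        self._topo = None

    def _lazy_spatial(self):
        if self._mixing is None:
            self._mixing = spatial_mixing_matrix(
                self.channel_labels, self.params.spatial_mixing_scale
            )
            self._topo = parietal_topography(self.channel_labels)
        return self._mixing, self._topo

    def epochs(self, participant: int, phase: str) -> EEGEpochs:
        mixing, topo = self._lazy_spatial()
        schedule = {"encoding": self.encoding, "wm": self.wm, "retrieval": self.retrieval}[phase]
        return simulate_phase_epochs(
            phase,
            schedule,
            self.params,
            self.objects,
            patterns=self.patterns,
            participant=participant,
            probing_counts=self.probing_counts,
            mixing=mixing,
            channel_labels=self.channel_labels,
            topography=topo,
        )

    def behavior(self, participant: int) -> pd.DataFrame:
        return simulate_behavior(
            self.retrieval,
            self.params,
            self.objects,
            participant=participant,
            probing_counts=self.probing_counts,
        )

    def behavior_table(self) -> pd.DataFrame:
        """Stacked behavior of all participants."""
        return pd.concat(
            [self.behavior(p) for p in range(self.params.n_participants)],
            ignore_index=True,
        )
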