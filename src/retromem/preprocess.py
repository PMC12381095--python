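"""Minimal EEG preprocessing: FIR filtering, baseline, epoch rejection.

Only the steps the synthetic pipeline actually exercises are implemented:
Hamming windowed-sinc FIR design, zero-phase application, baseline
correction, integer-factor downsampling, and an iterative automated epoch
rejection. Channel rejection, ICA and spline interpolation are out of
scope — imported data are assumed cleaned upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synth import EEGEpochs


@dataclass(frozen=True)
class FirSpec:
    """Windowed-sinc FIR description. ``cutoff`` is the −6 dB frequency."""

    kind: str  # highpass | lowpass
    cutoff: float  # Hz, -6 dB point
    transition_bandwidth: float  # Hz
    order: int  # number of taps; odd, so the filter is symmetric type-I
    srate: float

    def __post_init__(self) -> None:
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError(f"kind must be highpass/lowpass, got {self.kind!r}")
        if self.order < 3 or self.order % 2 == 0:
            raise ValueError("order (tap count) must be odd and >= 3")
        if not 0.0 < self.cutoff < self.srate / 2.0:
            raise ValueError("cutoff must lie in (0, srate/2)")


@dataclass(frozen=True)
class RejectionConfig:
    """Iterative amplitude + improbability epoch rejection parameters."""

    abs_threshold: float = 500.0  # μV
    sd_threshold: float = 5.0  # max |z| of trial summary statistics
    max_reject_fraction_per_iteration: float = 0.05
    max_iterations: int = 20

    def __post_init__(self) -> None:
        if min(self.abs_threshold, self.sd_threshold, self.max_iterations) <= 0:
            raise ValueError("rejection parameters must be positive")
        if not 0.0 < self.max_reject_fraction_per_iteration <= 1.0:
            raise ValueError("max_reject_fraction_per_iteration must lie in (0, 1]")


def design_windowed_sinc_fir(spec: FirSpec) -> np.ndarray:
    """Hamming windowed-sinc linear-phase FIR coefficients.

    ``firwin`` scales the window so the half-amplitude (−6 dB) point sits at
    the requested cutoff, matching the convention of common EEG toolboxes
    that report "cutoff frequency at −6 dB".
    """
    return signal.firwin(
        spec.order,
        spec.cutoff,
        window="hamming",
        pass_zero=(spec.kind == "lowpass"),
        fs=spec.srate,
    )


def fir_frequency_response(coeffs: np.ndarray, srate: float, freqs) -> np.ndarray:
    """|H(f)| of a FIR filter at the requested frequencies (Hz)."""
    w, h = signal.freqz(coeffs, worN=2.0 * np.pi * np.atleast_1d(freqs) / srate)
    return np.abs(h)


def apply_filter_zero_phase(data, coeffs: np.ndarray):
    """Forward–backward FIR filtering with reflection ("odd") padding.

    Accepts an array whose last axis is time, or :class:`EEGEpochs` (filtered
    copy returned). Zero net group delay; a constant input maps to
    constant × (DC gain)².
    """
    if isinstance(data, EEGEpochs):
        out = data.copy()
        out.data = apply_filter_zero_phase(out.data, coeffs)
        return out
    x = np.asarray(data, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    padlen = min(x.shape[-1] - 1, 3 * len(coeffs))
    return signal.filtfilt(coeffs, [1.0], x, axis=-1, padtype="odd", padlen=padlen)


def baseline_correct(epochs: EEGEpochs, window=(-200.0, 0.0)) -> EEGEpochs:
    """Subtract each trial/channel's mean over the baseline window."""
    t0, t1 = window
    mask = (epochs.times >= t0) & (epochs.times <= t1)
    if not mask.any():
        raise ValueError(f"baseline window {window} outside epoch times")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, mask].mean(axis=-1, keepdims=True)
    return out


def downsample(epochs: EEGEpochs, target_srate: float) -> EEGEpochs:
    """Anti-alias lowpass then decimate by an integer factor."""
    ratio = epochs.srate / target_srate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"srate ratio {epochs.srate}/{target_srate} is not an integer factor"
        )
    if factor == 1:
        return epochs.copy()
    n_times = epochs.data.shape[-1]
    order = min(201, (n_times // 4) | 1)
    if order < 3:
        raise ValueError("epoch too short to design the anti-alias filter")
    spec = FirSpec(
        kind="lowpass",
        cutoff=0.8 * target_srate / 2.0,
        transition_bandwidth=0.2 * target_srate / 2.0,
        order=order,
        srate=epochs.srate,
    )
    filtered = apply_filter_zero_phase(epochs.data, design_windowed_sinc_fir(spec))
    out = epochs.copy()
    out.data = filtered[:, :, ::factor]
    out.times = epochs.times[::factor]
    out.srate = target_srate
    return out


def _trial_scores(data: np.ndarray) -> np.ndarray:
    """Per-trial improbability score: max |z| over summary statistics.

    Summaries per trial: mean, log-variance, and peak-to-peak range (each
    computed over all channels and samples), z-scored across trials.
    """
    flat = data.reshape(data.shape[0], -1)
    stats = np.column_stack(
        [
            flat.mean(axis=1),
            np.log(flat.var(axis=1) + 1e-24),
            flat.max(axis=1) - flat.min(axis=1),
        ]
    )
    sd = stats.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    z = (stats - stats.mean(axis=0)) / sd
    return np.abs(z).max(axis=1)


def reject_epochs(epochs: EEGEpochs, config: RejectionConfig):
    """Iterative automated epoch rejection.

    Per iteration: flag trials whose absolute amplitude exceeds
    ``abs_threshold`` or whose improbability score exceeds ``sd_threshold``;
    reject at most ``max_reject_fraction_per_iteration`` of the currently
    kept trials (worst scores first); repeat until no flags remain or
    ``max_iterations`` is reached.

    Returns ``(kept_epochs, rejected_indices)``; indices refer to the input
    trial order. Raises if every trial would be rejected.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    keep = np.arange(epochs.n_trials)
    rejected: list[int] = []
    for _ in range(config.max_iterations):
        data = epochs.data[keep]
        absmax = np.abs(data).max(axis=(1, 2))
        scores = _trial_scores(data)
        flags = (absmax > config.abs_threshold) | (scores > config.sd_threshold)
        if not flags.any():
            break
        budget = max(1, int(np.ceil(config.max_reject_fraction_per_iteration * len(keep))))
        # worst first: amplitude violations ranked above score violations
        severity = np.where(absmax > config.abs_threshold, 1e6 + absmax, scores)
        order = np.argsort(-severity)
        to_drop = [i for i in order if flags[i]][:budget]
        rejected.extend(int(keep[i]) for i in to_drop)
        keep = np.delete(keep, to_drop)
        if len(keep) == 0:
            raise RuntimeError("all trials rejected")
        if len(keep) < 2:
            break
    kept = EEGEpochs(
        data=epochs.data[keep],
        times=epochs.times.copy(),
        srate=epochs.srate,
        channel_labels=list(epochs.channel_labels),
        metadata=epochs.metadata.iloc[keep].reset_index(drop=True),
    )
    return kept, sorted(rejected)
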