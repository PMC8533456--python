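"""Preprocessing: band-pass + notch filtering, resampling, epoching,
amplitude-based epoch rejection.

Filtering is zero-phase (forward-backward) so the Hjorth mobility of the
epochs is not biased by phase distortion: a 4th-order Butterworth
band-pass (default 0.1-100 Hz) plus a quality-factor-30 IIR notch
(default 50 Hz) with >= 30 dB attenuation at the mains line, followed by
polyphase anti-aliased resampling (default to 200 Hz).  Sample indices
are 0-based and epoch windows half-open [onset, onset + length).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import EpochSet, Recording

__all__ = ["filter_resample", "segment_epochs", "reject_epochs", "RejectionLog"]


def filter_resample(
    rec: Recording,
    low: float = 0.1,
    high: float = 100.0,
    notch: float | None = 50.0,
    target_rate: float = 200.0,
) -> Recording:
    """Band-pass, notch-filter and resample a recording.

    Events are remapped to the new sample indices.  Upsampling is refused.

    Raises
    ------
    ValueError
        If ``high`` exceeds the Nyquist frequency or ``target_rate``
        exceeds the recording rate.
    """
    nyq = rec.rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high > nyq:
        raise ValueError(f"high cut {high} Hz exceeds Nyquist {nyq} Hz")
    if target_rate > rec.rate:
        raise ValueError("no upsampling: target_rate must not exceed the recording rate")

    # The 0.1 Hz high-pass and the narrow notch have impulse responses far
    # longer than scipy's default forward-backward padding; pad generously
    # (several seconds) to keep edge transients out of the record.
    padlen = min(rec.data.shape[-1] - 1, int(10 * rec.rate))
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rec.rate, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=-1, padlen=padlen)
    if notch is not None:
        if notch >= nyq:
            raise ValueError(f"notch {notch} Hz exceeds Nyquist {nyq} Hz")
        b, a = signal.iirnotch(notch, Q=30.0, fs=rec.rate)
        data = signal.filtfilt(b, a, data, axis=-1, padlen=padlen)

    if target_rate != rec.rate:
        frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
        ratio = target_rate / rec.rate
    else:
        ratio = 1.0
    n_out = data.shape[1]
    events = [(min(int(round(on * ratio)), n_out - 1), lab) for on, lab in rec.events]
    return Recording(data=data, rate=target_rate, events=events, montage=rec.montage)


def segment_epochs(
    rec: Recording,
    epoch_duration: float = 1.0,
    stimulus_duration: float | None = None,
) -> EpochSet:
    """Cut each stimulus interval into non-overlapping labeled epochs.

    Each stimulus yields ``floor(stimulus_duration / epoch_duration)``
    epochs inheriting the stimulus label, in chronological order.  With
    ``stimulus_duration=None`` each stimulus extends to the next event
    onset (or the end of the recording).

    Raises
    ------
    ValueError
        If the recording has no events or a stimulus is shorter than one
        epoch.
    """
    if not rec.events:
        raise ValueError("recording has no stimulus events")
    n_ep_samp = int(round(epoch_duration * rec.rate))
    if n_ep_samp <= 0:
        raise ValueError("epoch duration too short for the sampling rate")

    onsets = [on for on, _ in rec.events]
    bounds = onsets[1:] + [rec.n_samples]
    epochs, labels, blocks = [], [], []
    for stim_idx, ((onset, label), next_bound) in enumerate(zip(rec.events, bounds)):
        if stimulus_duration is None:
            extent = next_bound - onset
        else:
            extent = min(int(round(stimulus_duration * rec.rate)), rec.n_samples - onset)
        n_epochs = extent // n_ep_samp
        if n_epochs == 0:
            raise ValueError(
                f"stimulus {stim_idx} ({extent} samples) shorter than one epoch ({n_ep_samp})"
            )
        for k in range(n_epochs):
            start = onset + k * n_ep_samp
            epochs.append(rec.data[:, start : start + n_ep_samp])
            labels.append(label)
            blocks.append(stim_idx)
    return EpochSet(
        data=np.stack(epochs),
        rate=rec.rate,
        labels=np.array(labels),
        order=np.arange(len(epochs)),
        block=np.array(blocks),
        montage=rec.montage,
    )


@dataclass(frozen=True)
class RejectionLog:
    """Outcome of amplitude-based epoch rejection."""

    n_removed: int
    removed_order: tuple[int, ...]
    threshold: float


def reject_epochs(
    es: EpochSet, peak_to_peak_max: float = np.inf
) -> tuple[EpochSet, RejectionLog]:
    """Drop epochs whose any-channel peak-to-peak amplitude exceeds a threshold.

    Surviving epochs keep their original chronological ``order`` indices.

    Raises
    ------
    ValueError
        If the threshold is not positive or every epoch is rejected.
    """
    if not peak_to_peak_max > 0:
        raise ValueError("peak_to_peak_max must be positive (use inf to disable)")
    ptp = es.data.max(axis=-1) - es.data.min(axis=-1)  # epochs x channels
    bad = (ptp > peak_to_peak_max).any(axis=-1)
    if bad.all():
        raise ValueError(
            "all epochs exceed the peak-to-peak threshold; review the threshold"
        )
    log = RejectionLog(
        n_removed=int(bad.sum()),
        removed_order=tuple(es.order[bad].tolist()),
        threshold=float(peak_to_peak_max),
    )
    return es.subset(~bad), log
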