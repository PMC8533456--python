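"""Synthetic EEG sessions with the statistical structure of the
three-class automobile-sound listening paradigm.

A session presents 3 sound classes (comfort = -1, powerfulness = 0,
acceleration = 1) x 3 sounds per class x 27 repetitions = 243 stimuli of
5 s each, in seeded random order, recorded at 1000 Hz over a 62-channel
montage.  Within a stimulus every channel receives a sum of five
band-limited noise processes whose power follows the class signature
(rhythm-band gains plus signed left/right offsets per scalp region), on
top of a 1/f background and white sensor noise.  The rhythm components
are exactly band-limited (spectral masking with the same half-open band
convention the feature stage bins with), so injected and measured band
power agree by construction.

The generator models ongoing band-power modulation only: no evoked
potentials, no eye/muscle artifacts, no acoustic content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Recording
from .features import BandScheme, default_bands
from .montage import Montage

__all__ = [
    "ParadigmConfig",
    "ClassSignature",
    "default_signatures",
    "gamma_contrast_signatures",
    "simulate_session",
]

DEFAULT_CLASS_LABELS = {"comfort": -1, "powerfulness": 0, "acceleration": 1}


@dataclass(frozen=True)
class ParadigmConfig:
    """Stimulus schedule of one listening session.

    Defaults reproduce the study paradigm: 3 sounds per class played 27
    times each, 5-s stimuli later cut into 1-s epochs (1,215 epochs per
    session), raw sampling at 1000 Hz.  ``gap_duration`` is the
    inter-stimulus interval containing background signal only; the
    original protocol used prompt/feedback pauses whose in-record length
    is not part of the analysed data, so the gap is an explicit knob
    (default 1 s keeps sessions compact).
    """

    n_sounds_per_class: int = 3
    n_repetitions: int = 27
    stimulus_duration: float = 5.0
    epoch_duration: float = 1.0
    raw_rate: float = 1000.0
    gap_duration: float = 1.0
    class_labels: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_LABELS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sounds_per_class <= 0 or self.n_repetitions <= 0:
            raise ValueError("counts must be positive")
        if self.stimulus_duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.epoch_duration <= 0:
            raise ValueError("epoch duration must be positive")
        ratio = self.stimulus_duration / self.epoch_duration
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("stimulus duration must be an integer multiple of epoch duration")
        if self.raw_rate <= 0:
            raise ValueError("raw rate must be positive")
        if self.gap_duration < 0:
            raise ValueError("gap duration cannot be negative")

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def n_stimuli(self) -> int:
        return self.n_classes * self.n_sounds_per_class * self.n_repetitions


@dataclass(frozen=True)
class ClassSignature:
    """Band-power fingerprint of one sound class.

    ``band_gain`` multiplies the per-band power, ``overall_scale`` (µV²)
    sets the total per-band power of an unmodulated channel, and
    ``asym_gain[band][region]`` is a signed hemispheric offset: a left
    channel in that region gets power scaled by (1 + a/2) and its right
    homologue by (1 - a/2), so ``a`` is the fractional left-minus-right
    power difference.
    """

    band_gain: dict
    asym_gain: dict
    overall_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.overall_scale <= 0:
            raise ValueError("overall_scale must be positive")
        if any(g <= 0 for g in self.band_gain.values()):
            raise ValueError("band gains must be strictly positive")

    def channel_band_power(self, band: str, side: str, region: str) -> float:
        base = self.overall_scale * self.band_gain.get(band, 1.0)
        a = self.asym_gain.get(band, {}).get(region, 0.0)
        if side == "left":
            factor = 1.0 + a / 2.0
        elif side == "right":
            factor = 1.0 - a / 2.0
        else:
            factor = 1.0
        return base * max(factor, 0.05)


def default_signatures() -> dict[int, ClassSignature]:
    """Default class fingerprints for the three sound qualities.

    Comfort is low-power and hemispherically balanced; powerfulness has
    elevated overall and low-band (delta/theta) power with a strong
    frontal left-dominant asymmetry; acceleration has the highest
    broadband power with elevated beta/gamma and a frontal right-dominant
    beta/gamma asymmetry.  Distinct asymmetry patterns are what make the
    classes recoverable from DASM/RASM features, which are blind to
    hemispherically symmetric power changes.
    """
    uniform = {b: 1.0 for b in ("delta", "theta", "alpha", "beta", "gamma")}
    comfort = ClassSignature(band_gain=dict(uniform), asym_gain={}, overall_scale=10.0)
    powerfulness = ClassSignature(
        band_gain={**uniform, "delta": 1.5, "theta": 1.5},
        asym_gain={
            "delta": {"frontal": 0.6, "temporal": 0.3},
            "theta": {"frontal": 0.6, "temporal": 0.3},
        },
        overall_scale=20.0,
    )
    acceleration = ClassSignature(
        band_gain={**uniform, "beta": 1.5, "gamma": 1.5},
        asym_gain={
            "beta": {"frontal": -0.5, "central": -0.25},
            "gamma": {"frontal": -0.5, "central": -0.25},
        },
        overall_scale=25.0,
    )
    return {-1: comfort, 0: powerfulness, 1: acceleration}


def gamma_contrast_signatures() -> dict[int, ClassSignature]:
    """Signatures differing only in gamma-band asymmetry.

    Used to probe band-specific decoding: every class has identical power
    and identical delta/theta/alpha/beta symmetry, so only gamma-band
    features carry class information.
    """
    uniform = {b: 1.0 for b in ("delta", "theta", "alpha", "beta", "gamma")}

    def sig(a: float) -> ClassSignature:
        asym = {"gamma": {"frontal": a, "central": a / 2.0}} if a else {}
        return ClassSignature(band_gain=dict(uniform), asym_gain=asym, overall_scale=15.0)

    return {-1: sig(0.0), 0: sig(0.7), 1: sig(-0.7)}


def _pink_noise(rng: np.random.Generator, n: int, exponent: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f^exponent noise of length n via spectral shaping."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    shaped = np.fft.irfft(spectrum * scale, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _band_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    band: tuple[float, float],
    rate: float,
    chunk: int | None = None,
) -> np.ndarray:
    """Exactly band-limited noise with unit variance per chunk of each row.

    White noise is masked in the rFFT domain to ``low <= f < high`` (the
    same half-open convention the Welch band-power estimator bins with),
    so the injected power of each rhythm component lies entirely in its
    nominal band and injected vs measured band power agree by
    construction.
    """
    low, high = band
    n = shape[-1]
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spectrum[..., ~((freqs >= low) & (freqs < high))] = 0.0
    x = np.fft.irfft(spectrum, n=n, axis=-1)
    if chunk is None:
        chunk = n
    # Normalize power per epoch-length chunk, not over the whole stimulus:
    # an exact whole-stimulus constraint would anticorrelate the power of
    # sibling epochs (a high-power epoch forces its blockmates low), which
    # is an artifactual cue no real recording has.
    n_chunks = n // chunk
    head = x[..., : n_chunks * chunk].reshape(*shape[:-1], n_chunks, chunk)
    sd = head.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    head /= sd
    x[..., : n_chunks * chunk] = head.reshape(*shape[:-1], n_chunks * chunk)
    if n_chunks * chunk < n:
        tail = x[..., n_chunks * chunk :]
        sd_t = tail.std(axis=-1, keepdims=True)
        sd_t[sd_t == 0] = 1.0
        x[..., n_chunks * chunk :] = tail / sd_t
    return x


def simulate_session(
    montage: Montage,
    paradigm: ParadigmConfig | None = None,
    signatures: dict[int, ClassSignature] | None = None,
    noise_level: float = 1.0,
    background_amp: float = 2.0,
    background_exponent: float = 1.0,
    scheme: BandScheme | None = None,
) -> Recording:
    """Simulate one continuous listening session.

    Parameters
    ----------
    montage
        Electrode layout; side/region tags drive the asymmetry offsets.
    paradigm
        Stimulus schedule (default: the study paradigm).
    signatures
        Per-class-label band-power fingerprints (default:
        :func:`default_signatures`).
    noise_level
        Standard deviation (µV) of additive white sensor noise.
    background_amp
        Standard deviation (µV) of the 1/f background.
    background_exponent
        Spectral exponent of the background (1.0 = pink noise).

    Returns
    -------
    Recording
        Continuous recording at ``paradigm.raw_rate`` with one event per
        stimulus; identical seeds give bit-identical output.
    """
    paradigm = paradigm or ParadigmConfig()
    signatures = signatures if signatures is not None else default_signatures()
    scheme = scheme or default_bands()
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    missing = [lab for lab in paradigm.class_labels.values() if lab not in signatures]
    if missing:
        raise ValueError(f"missing ClassSignature for class label(s) {missing}")

    rng = np.random.default_rng(paradigm.seed)
    rate = paradigm.raw_rate
    n_ch = montage.n_channels
    n_stim_samp = int(round(paradigm.stimulus_duration * rate))
    n_epoch_samp = int(round(paradigm.epoch_duration * rate))
    n_gap_samp = int(round(paradigm.gap_duration * rate))
    if n_stim_samp == 0:
        raise ValueError("zero-duration stimulus")

    # Seeded random stimulus order: each (class, sound) played n_repetitions times.
    schedule = [
        label
        for label in paradigm.class_labels.values()
        for _sound in range(paradigm.n_sounds_per_class)
        for _rep in range(paradigm.n_repetitions)
    ]
    schedule = [schedule[i] for i in rng.permutation(len(schedule))]

    n_total = n_gap_samp + len(schedule) * (n_stim_samp + n_gap_samp)
    data = np.empty((n_ch, n_total))
    for ch in range(n_ch):
        data[ch] = background_amp * _pink_noise(rng, n_total, background_exponent)
    if noise_level > 0:
        data += noise_level * rng.standard_normal((n_ch, n_total))

    # Per-channel standard-deviation templates per (class, band).
    sd_templates = {
        (label, band): np.array(
            [
                np.sqrt(sig.channel_band_power(band, montage.side[c], montage.region[c]))
                for c in range(n_ch)
            ]
        )
        for label, sig in signatures.items()
        for band in scheme.names
    }

    events: list[tuple[int, int]] = []
    cursor = n_gap_samp
    for label in schedule:
        seg = np.zeros((n_ch, n_stim_samp))
        for name, low, high in scheme.bands:
            noise = _band_noise(
                rng, (n_ch, n_stim_samp), (low, high), rate, chunk=n_epoch_samp
            )
            seg += sd_templates[(label, name)][:, None] * noise
        data[:, cursor : cursor + n_stim_samp] += seg
        events.append((cursor, label))
        cursor += n_stim_samp + n_gap_samp

    return Recording(data=data, rate=rate, events=events, montage=montage)
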