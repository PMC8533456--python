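"""Rhythm-band EEG features and hemispheric asymmetry indices.

Per 1-s epoch and electrode the base features are band power from a Welch
periodogram (rectangular 1-s window, 50% overlap; for 1-s epochs this
degenerates to a single periodogram), the three Hjorth parameters of the
band-filtered signal, and the Gaussian differential entropy (DE) of the
band-filtered signal, ``0.5*ln(2*pi*e*var)`` in nats.  Asymmetry features
contrast homologous electrode pairs: DASM is the left-minus-right
difference, RASM the left/right ratio.  With the default 26-pair montage
and five rhythm bands this yields 130 features for the scalar bases
(PSD, DE) and 390 for the three Hjorth components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet, FeatureDescriptor, FeatureMatrix

__all__ = [
    "BandScheme",
    "default_bands",
    "band_filter",
    "band_power",
    "hjorth",
    "diff_entropy",
    "asymmetry_features",
    "class_topography",
    "BASE_COMPONENTS",
]

#: Expansion of each requested base family into feature components.
BASE_COMPONENTS = {
    "PSD": ("PSD",),
    "Hjorth": ("Hjorth-activity", "Hjorth-mobility", "Hjorth-complexity"),
    "DE": ("DE",),
}

#: Guard added to RASM numerator and denominator so equal inputs keep
#: RASM == 1 even at zero power.
RASM_EPS = 1e-12


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping rhythm bands (name, low Hz, high Hz)."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_high = 0.0
        for name, low, high in self.bands:
            if not low < high:
                raise ValueError(f"band {name}: low must be < high")
            if low < prev_high:
                raise ValueError(f"band {name} overlaps the previous band")
            prev_high = high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    def edges(self, name: str) -> tuple[float, float]:
        for n, low, high in self.bands:
            if n == name:
                return low, high
        raise KeyError(name)

    @property
    def span(self) -> tuple[float, float]:
        return self.bands[0][1], self.bands[-1][2]


def default_bands() -> BandScheme:
    """The five canonical EEG rhythms.

    Gamma is capped at 49 Hz: recordings are notch-filtered at 50 Hz and
    resampled to 200 Hz, so the band stops just below the excised mains line.
    """
    return BandScheme(
        bands=(
            ("delta", 1.0, 4.0),
            ("theta", 4.0, 8.0),
            ("alpha", 8.0, 12.0),
            ("beta", 12.0, 30.0),
            ("gamma", 30.0, 49.0),
        )
    )


def band_filter(x: np.ndarray, band: tuple[float, float], rate: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    low, high = band
    nyq = rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band ({low}, {high}) Hz must lie inside (0, {nyq}) Hz")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def band_power(
    x: np.ndarray,
    rate: float,
    band: tuple[float, float],
    window_duration: float = 1.0,
    overlap: float = 0.5,
) -> np.ndarray:
    """Welch band power (µV²) along the last axis.

    Modified periodograms with a rectangular window of ``window_duration``
    seconds and the given overlap fraction are averaged; the band power is
    the sum of the power-density bins with ``low <= f < high`` times the
    bin width.  For epochs exactly one window long this is a single
    periodogram.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_duration * rate))
    if x.shape[-1] < nperseg:
        raise ValueError("epoch shorter than the Welch window")
    freqs, pxx = signal.welch(
        x,
        fs=rate,
        window="boxcar",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend=False,
        axis=-1,
    )
    low, high = band
    mask = (freqs >= low) & (freqs < high)
    if not mask.any():
        raise ValueError(f"band ({low}, {high}) Hz contains no frequency bins")
    df = freqs[1] - freqs[0]
    return pxx[..., mask].sum(axis=-1) * df


def hjorth(x: np.ndarray, rate: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hjorth activity, mobility and complexity along the last axis.

    Activity is the signal variance; mobility the square root of the
    variance ratio of the derivative to the signal (approximately the
    dominant angular frequency, rad/s); complexity the mobility of the
    derivative relative to that of the signal.  Derivatives are first
    differences scaled by the sampling rate.  Zero-variance input returns
    (0, 0, 0).
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("Hjorth parameters need at least 3 samples")
    d1 = np.diff(x, axis=-1) * rate
    d2 = np.diff(d1, axis=-1) * rate
    v0 = x.var(axis=-1)
    v1 = d1.var(axis=-1)
    v2 = d2.var(axis=-1)
    mobility = np.where(v0 > 0, np.sqrt(v1 / np.where(v0 > 0, v0, 1.0)), 0.0)
    mob_d1 = np.where(v1 > 0, np.sqrt(v2 / np.where(v1 > 0, v1, 1.0)), 0.0)
    complexity = np.where(mobility > 0, mob_d1 / np.where(mobility > 0, mobility, 1.0), 0.0)
    return v0, mobility, complexity


def diff_entropy(x: np.ndarray) -> np.ndarray:
    """Gaussian differential entropy 0.5*ln(2*pi*e*var) in nats.

    The variance is the unbiased sample variance along the last axis;
    zero variance yields ``-inf``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("differential entropy needs at least 2 samples")
    var = x.var(axis=-1, ddof=1)
    with np.errstate(divide="ignore"):
        return 0.5 * np.log(2.0 * math.pi * math.e * var)


def _base_features(es: EpochSet, scheme: BandScheme, bases: set[str]) -> dict:
    """Per-(band, component) matrices of shape epochs x channels."""
    out: dict[tuple[str, str], np.ndarray] = {}
    for name, low, high in scheme.bands:
        if "PSD" in bases:
            out[(name, "PSD")] = band_power(es.data, es.rate, (low, high))
        if "Hjorth" in bases or "DE" in bases:
            bf = band_filter(es.data, (low, high), es.rate)
            if "Hjorth" in bases:
                act, mob, comp = hjorth(bf, es.rate)
                out[(name, "Hjorth-activity")] = act
                out[(name, "Hjorth-mobility")] = mob
                out[(name, "Hjorth-complexity")] = comp
            if "DE" in bases:
                out[(name, "DE")] = diff_entropy(bf)
    return out


def asymmetry_features(
    es: EpochSet,
    scheme: BandScheme | None = None,
    bases: set[str] = frozenset({"PSD", "Hjorth", "DE"}),
    modes: set[str] = frozenset({"DASM", "RASM"}),
) -> FeatureMatrix:
    """Differential/rational asymmetry features over homologous pairs.

    Column order is deterministic: mode (DASM before RASM), then pair in
    montage order, then band, then base component.  RASM guards zero
    denominators by adding ``RASM_EPS`` to numerator and denominator.
    """
    if es.montage is None or not es.montage.pairs:
        raise ValueError("asymmetry features require a montage with a non-empty pair table")
    bad = set(bases) - set(BASE_COMPONENTS)
    if bad:
        raise ValueError(f"unknown bases {sorted(bad)}; supported: {sorted(BASE_COMPONENTS)}")
    bad = set(modes) - {"DASM", "RASM"}
    if bad:
        raise ValueError(f"unknown asymmetry modes {sorted(bad)}")
    scheme = scheme or default_bands()
    base_maps = _base_features(es, scheme, set(bases))
    components = [c for b in ("PSD", "Hjorth", "DE") if b in bases for c in BASE_COMPONENTS[b]]
    pair_idx = es.montage.pair_indices()

    columns: list[np.ndarray] = []
    descriptors: list[FeatureDescriptor] = []
    for mode in [m for m in ("DASM", "RASM") if m in modes]:
        for (left, right), (li, ri) in zip(es.montage.pairs, pair_idx):
            for band in scheme.names:
                for comp in components:
                    vals = base_maps[(band, comp)]
                    lv, rv = vals[:, li], vals[:, ri]
                    if mode == "DASM":
                        col = lv - rv
                    else:
                        col = (lv + RASM_EPS) / (rv + RASM_EPS)
                    columns.append(col)
                    descriptors.append(
                        FeatureDescriptor(mode=mode, pair=(left, right), band=band, base=comp)
                    )
    return FeatureMatrix(
        values=np.column_stack(columns),
        descriptors=descriptors,
        labels=es.labels,
        order=es.order,
        block=es.block,
    )


def class_topography(
    es: EpochSet,
    scheme: BandScheme | None = None,
    classes: tuple[int, ...] = (-1, 0, 1),
) -> pd.DataFrame:
    """Per-class mean band power per electrode (long-format table).

    Columns: channel, band, class, power (µV²).  This is the tabular form
    of a scalp power topography, one row per electrode/band/class.
    """
    if es.montage is None:
        raise ValueError("topography requires a montage")
    missing = [c for c in classes if c not in set(es.labels.tolist())]
    if missing:
        raise ValueError(f"no epochs for class(es) {missing}")
    scheme = scheme or default_bands()
    rows = []
    for name, low, high in scheme.bands:
        power = band_power(es.data, es.rate, (low, high))  # epochs x channels
        for cls in classes:
            mean_power = power[es.labels == cls].mean(axis=0)
            for ch, p in zip(es.montage.channels, mean_power):
                rows.append({"channel": ch, "band": name, "class": cls, "power": p})
    return pd.DataFrame(rows)
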