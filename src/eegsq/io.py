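"""File interchange for recordings, epochs and feature matrices.

Recordings and epoch sets are written as NumPy ``.npz`` archives next to
delimited-text metadata (a CSV event file ``<stem>.events.csv`` with
columns ``onset_sample,label``, or a CSV label file for epochs); feature
matrices are written as a CSV whose header row holds the feature
descriptor strings, with a JSON sidecar spelling out each descriptor.
An optional European Data Format reader is provided through MNE when it
is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet, FeatureDescriptor, FeatureMatrix, Recording
from .montage import make_montage

__all__ = [
    "save_recording",
    "load_recording",
    "save_epochs",
    "load_epochs",
    "save_features",
    "load_features",
    "read_edf",
]

_META_COLS = ("label", "order", "block")


def save_recording(rec: Recording, stem: str | Path) -> None:
    """Write ``<stem>.npz`` (data, rate, channels) and ``<stem>.events.csv``."""
    stem = Path(stem)
    channels = list(rec.montage.channels) if rec.montage else []
    np.savez(stem.with_suffix(".npz"), data=rec.data, rate=rec.rate, channels=channels)
    pd.DataFrame(rec.events, columns=["onset_sample", "label"]).to_csv(
        stem.with_suffix(".events.csv"), index=False
    )


def load_recording(stem: str | Path) -> Recording:
    stem = Path(stem)
    with np.load(stem.with_suffix(".npz"), allow_pickle=False) as npz:
        data = npz["data"]
        rate = float(npz["rate"])
        channels = [str(c) for c in npz["channels"]]
    events_df = pd.read_csv(stem.with_suffix(".events.csv"))
    events = list(zip(events_df["onset_sample"].astype(int), events_df["label"].astype(int)))
    montage = make_montage(channels=channels) if channels else None
    return Recording(data=data, rate=rate, events=events, montage=montage)


def save_epochs(es: EpochSet, stem: str | Path) -> None:
    """Write ``<stem>.npz`` (data, rate, channels) and ``<stem>.labels.csv``."""
    stem = Path(stem)
    channels = list(es.montage.channels) if es.montage else []
    np.savez(stem.with_suffix(".npz"), data=es.data, rate=es.rate, channels=channels)
    pd.DataFrame({"label": es.labels, "order": es.order, "block": es.block}).to_csv(
        stem.with_suffix(".labels.csv"), index=False
    )


def load_epochs(stem: str | Path) -> EpochSet:
    stem = Path(stem)
    with np.load(stem.with_suffix(".npz"), allow_pickle=False) as npz:
        data = npz["data"]
        rate = float(npz["rate"])
        channels = [str(c) for c in npz["channels"]]
    meta = pd.read_csv(stem.with_suffix(".labels.csv"))
    montage = make_montage(channels=channels) if channels else None
    return EpochSet(
        data=data,
        rate=rate,
        labels=meta["label"].to_numpy(),
        order=meta["order"].to_numpy(),
        block=meta["block"].to_numpy(),
        montage=montage,
    )


def save_features(fm: FeatureMatrix, path: str | Path) -> None:
    """Write the feature CSV (descriptor-string header plus label/order/block
    columns) and a ``.json`` sidecar listing the structured descriptors."""
    path = Path(path)
    df = pd.DataFrame(fm.values, columns=[str(d) for d in fm.descriptors])
    for col, vals in zip(_META_COLS, (fm.labels, fm.order, fm.block)):
        df.insert(0, col, vals)
    df.to_csv(path, index=False)
    sidecar = [
        {"mode": d.mode, "pair": list(d.pair), "band": d.band, "base": d.base}
        for d in fm.descriptors
    ]
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_features(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    descriptors = [
        FeatureDescriptor(mode=d["mode"], pair=tuple(d["pair"]), band=d["band"], base=d["base"])
        for d in sidecar
    ]
    values = df.drop(columns=list(_META_COLS)).to_numpy(dtype=float)
    return FeatureMatrix(
        values=values,
        descriptors=descriptors,
        labels=df["label"].to_numpy(),
        order=df["order"].to_numpy(),
        block=df["block"].to_numpy(),
    )


def read_edf(path: str | Path, label_map: dict[str, int] | None = None) -> Recording:
    """Read a European Data Format recording via MNE (optional dependency).

    Annotations become events; ``label_map`` translates annotation
    descriptions into integer class labels (unmapped annotations are
    skipped).  The montage is reconstructed from the channel names when
    they follow 10-20 conventions, otherwise left unset.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    rate = float(raw.info["sfreq"])
    events: list[tuple[int, int]] = []
    for ann in raw.annotations:
        desc = str(ann["description"])
        if label_map is not None:
            if desc not in label_map:
                continue
            label = label_map[desc]
        else:
            try:
                label = int(desc)
            except ValueError:
                continue
        events.append((int(round(ann["onset"] * rate)), label))
    try:
        montage = make_montage(channels=list(raw.ch_names))
    except ValueError:
        montage = None
    return Recording(data=data, rate=rate, events=events, montage=montage)
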