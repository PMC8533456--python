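"""Scalp electrode montages and the homologous left/right pair table.

The asymmetry features (DASM/RASM) contrast band power between homologous
electrodes of the two hemispheres, so a montage here carries, besides the
channel order, a per-channel hemisphere tag, a coarse scalp-region tag and
an explicit list of (left, right) electrode pairs.  The default 62-channel
extended 10-20 layout ships with the package as an editable YAML file
(``_data/montage62.yaml``) providing 26 pairs; midline electrodes (names
ending in ``z``) never enter a pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import yaml

__all__ = ["Montage", "make_montage", "channel_side", "channel_region"]

#: Prefix -> scalp region, longest prefixes first so e.g. "FC3" resolves to
#: central rather than frontal.
_REGION_PREFIXES = [
    ("FP", "frontal"),
    ("AF", "frontal"),
    ("FT", "temporal"),
    ("FC", "central"),
    ("CP", "parietal"),
    ("TP", "temporal"),
    ("PO", "occipital"),
    ("F", "frontal"),
    ("C", "central"),
    ("T", "temporal"),
    ("P", "parietal"),
    ("O", "occipital"),
    ("I", "occipital"),
]


def channel_side(name: str) -> str:
    """Hemisphere of a 10-20 style channel name.

    Names ending in ``z`` (or ``Z``) are midline; otherwise the trailing
    number decides: odd numbers are left-hemisphere, even numbers right.
    """
    if name[-1] in "zZ":
        return "midline"
    digits = ""
    for ch in reversed(name):
        if ch.isdigit():
            digits = ch + digits
        else:
            break
    if not digits:
        raise ValueError(f"cannot infer hemisphere from channel name {name!r}")
    return "left" if int(digits) % 2 == 1 else "right"


def channel_region(name: str) -> str:
    """Coarse scalp region (frontal/central/temporal/parietal/occipital)."""
    upper = name.upper()
    for prefix, region in _REGION_PREFIXES:
        if upper.startswith(prefix):
            return region
    raise ValueError(f"cannot infer scalp region from channel name {name!r}")


@dataclass(frozen=True)
class Montage:
    """Electrode layout with lateralization tags and homologous pairs.

    Parameters
    ----------
    channels
        Channel names in recording order.
    side
        Per-channel hemisphere tag in {"left", "right", "midline"}.
    region
        Per-channel region tag in {"frontal", "central", "temporal",
        "parietal", "occipital"}.
    pairs
        Ordered (left-channel, right-channel) homologous pairs.
    """

    channels: tuple[str, ...]
    side: tuple[str, ...]
    region: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names in montage")
        if not (len(self.channels) == len(self.side) == len(self.region)):
            raise ValueError("channels, side and region must have equal length")
        index = {name: i for i, name in enumerate(self.channels)}
        object.__setattr__(self, "_index", index)
        seen: set[str] = set()
        for left, right in self.pairs:
            for name in (left, right):
                if name not in index:
                    raise ValueError(f"paired channel {name!r} not in montage")
                if name in seen:
                    raise ValueError(f"channel {name!r} appears in two pairs")
                seen.add(name)
            if self.side[index[left]] != "left" or self.side[index[right]] != "right":
                raise ValueError(f"pair ({left}, {right}) must couple a left and a right channel")
        n_lateral = sum(1 for s in self.side if s != "midline")
        if 2 * len(self.pairs) != n_lateral:
            raise ValueError(
                f"{len(self.pairs)} pairs cannot cover {n_lateral} lateral channels"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, name: str) -> int:
        return self._index[name]

    def pair_indices(self) -> list[tuple[int, int]]:
        """(left, right) channel indices for every homologous pair."""
        return [(self._index[l], self._index[r]) for l, r in self.pairs]


def _load_default_62() -> Montage:
    text = resources.files("eegsq").joinpath("_data/montage62.yaml").read_text()
    spec = yaml.safe_load(text)
    channels = tuple(spec["channels"])
    pairs = tuple((l, r) for l, r in spec["pairs"])
    side = tuple(channel_side(c) for c in channels)
    region = tuple(channel_region(c) for c in channels)
    return Montage(channels=channels, side=side, region=region, pairs=pairs)


def _pair_by_name(channels: Sequence[str]) -> tuple[tuple[str, str], ...]:
    """Pair odd-numbered channels with their even homologue (F3 with F4)."""
    names = set(channels)
    pairs = []
    for name in channels:
        if channel_side(name) != "left":
            continue
        digits = ""
        for ch in reversed(name):
            if ch.isdigit():
                digits = ch + digits
            else:
                break
        prefix = name[: len(name) - len(digits)]
        mate = f"{prefix}{int(digits) + 1}"
        if mate in names:
            pairs.append((name, mate))
    return tuple(pairs)


def make_montage(n_channels: int = 62, channels: Sequence[str] | None = None) -> Montage:
    """Build a montage, either the shipped 62-channel layout or a toy one.

    With ``channels`` given, a toy montage is built from the explicit names:
    hemisphere and region are inferred from 10-20 naming and each
    odd-numbered channel is paired with its even-numbered homologue when
    present; unpaired lateral channels are not allowed.

    Raises
    ------
    ValueError
        If ``n_channels`` does not correspond to a supported layout.
    """
    if channels is not None:
        channels = tuple(channels)
        side = tuple(channel_side(c) for c in channels)
        region = tuple(channel_region(c) for c in channels)
        pairs = _pair_by_name(channels)
        return Montage(channels=channels, side=side, region=region, pairs=pairs)
    if n_channels == 62:
        return _load_default_62()
    raise ValueError(
        f"no built-in layout with {n_channels} channels; supported: 62 "
        "(or pass explicit channel names for a toy layout)"
    )
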