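"""64-channel 10-20/10-10 scalp montage: electrode positions and lobe mapping.

Positions come from MNE's idealized standard montage, re-centred and
projected onto the unit sphere, which is the geometry the spherical-spline
interpolation and the scalp-map projection assume.  Channels are assigned
to one of five lobes (frontal, central, temporal, parietal, occipital) by
their 10-10 label prefix; the mapping is editable by passing an explicit
``regions`` dict wherever a montage is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = ["ChannelMontage", "default_montage", "CHANNELS_64", "REGIONS", "region_for_channel"]

#: Standard 64-channel 10-10 electrode set (left-to-right within each row,
#: anterior to posterior).
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)

REGIONS: tuple[str, ...] = ("frontal", "central", "temporal", "parietal", "occipital")

# Prefix rules, checked in order (two-letter prefixes before one-letter so
# that e.g. FT7 is temporal, not frontal).
_PREFIX_RULES: tuple[tuple[str, str], ...] = (
    ("Fp", "frontal"),
    ("AF", "frontal"),
    ("FT", "temporal"),
    ("FC", "central"),
    ("TP", "temporal"),
    ("CP", "parietal"),
    ("PO", "occipital"),
    ("F", "frontal"),
    ("C", "central"),
    ("T", "temporal"),
    ("P", "parietal"),
    ("O", "occipital"),
    ("I", "occipital"),
)


class MappingError(KeyError):
    """A channel could not be assigned to a brain region."""


def region_for_channel(name: str) -> str:
    """Map a 10-10 channel label to its lobe by prefix convention."""
    for prefix, region in _PREFIX_RULES:
        if name.startswith(prefix):
            return region
    raise MappingError(f"channel {name!r} has no known lobe prefix")


@dataclass(frozen=True)
class ChannelMontage:
    """Electrode layout on an idealized unit sphere.

    Attributes
    ----------
    names
        Ordered channel labels.
    positions
        ``(n_channels, 3)`` unit vectors (head frame: +x right, +y anterior,
        +z superior).
    regions
        Channel label -> lobe name.
    """

    names: tuple[str, ...]
    positions: np.ndarray
    regions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate channel names in montage")
        if self.positions.shape != (len(self.names), 3):
            raise ValueError("positions must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def region_of(self, name: str) -> str:
        if name in self.regions:
            return self.regions[name]
        return region_for_channel(name)

    def channels_in(self, region: str) -> list[str]:
        return [n for n in self.names if self.region_of(n) == region]

    def positions_2d(self) -> np.ndarray:
        """Azimuthal-equidistant projection onto the x-y plane.

        The vertex (Cz direction, +z) maps to the origin; arc distance from
        the vertex becomes the planar radius, so the scalp maps into a disc
        of radius pi/2 at the equator (ear level) and slightly beyond for
        channels below it.
        """
        p = self.positions
        theta = np.arccos(np.clip(p[:, 2], -1.0, 1.0))
        az = np.arctan2(p[:, 1], p[:, 0])
        return np.column_stack([theta * np.cos(az), theta * np.sin(az)])


@lru_cache(maxsize=4)
def _standard_positions(names: tuple[str, ...]) -> np.ndarray:
    import mne

    for montage_name in ("colin27_1005", "standard_1005"):
        try:
            mont = mne.channels.make_standard_montage(montage_name)
            break
        except ValueError:  # pragma: no cover - depends on MNE version
            continue
    pos = mont.get_positions()["ch_pos"]
    pts = np.array([pos[n] for n in names], dtype=float)
    # Re-centre on the best-fit sphere centre, then normalize to unit radius.
    centre = pts.mean(axis=0)
    for _ in range(20):
        r = np.linalg.norm(pts - centre, axis=1)
        grad = ((r - r.mean())[:, None] * (pts - centre) / r[:, None]).mean(axis=0)
        centre = centre + grad
    pts = pts - centre
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def default_montage(names: tuple[str, ...] | None = None) -> ChannelMontage:
    """The 64-channel unit-sphere montage with the default lobe mapping."""
    names = tuple(names) if names is not None else CHANNELS_64
    positions = _standard_positions(names).copy()
    regions = {n: region_for_channel(n) for n in names}
    return ChannelMontage(names=names, positions=positions, regions=regions)
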