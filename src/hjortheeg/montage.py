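"""The 19-channel 10–20 montage and its 2-D scalp projection.

Positions are the standard polar projection of 10–20 electrode angles
onto the unit disc (nose at the top, +y anterior, +x right). The outer
ring (Fp, F7/F8, T, T5/T6, O) sits on the unit circle at multiples of
18 degrees; the intermediate frontal/parietal and central electrodes
sit at half radius. Coordinates are constants of this package — they
are used for exporting topographic channel maps, not for any inference.
"""

from dataclasses import dataclass, field
from math import cos, radians, sin
from typing import Dict, Tuple

from .errors import ChannelMismatchError


def _ring(angle_deg: float, r: float) -> Tuple[float, float]:
    # angle measured from the anterior (+y) axis, positive to the left
    a = radians(angle_deg)
    return (-r * sin(a), r * cos(a))


_POSITIONS: Dict[str, Tuple[float, float]] = {
    "Fp1": _ring(18, 1.0),
    "Fp2": _ring(-18, 1.0),
    "F7": _ring(54, 1.0),
    "F8": _ring(-54, 1.0),
    "T3": _ring(90, 1.0),
    "T4": _ring(-90, 1.0),
    "T5": _ring(126, 1.0),
    "T6": _ring(-126, 1.0),
    "O1": _ring(162, 1.0),
    "O2": _ring(-162, 1.0),
    "F3": _ring(39, 0.5),
    "F4": _ring(-39, 0.5),
    "C3": _ring(90, 0.5),
    "C4": _ring(-90, 0.5),
    "P3": _ring(141, 0.5),
    "P4": _ring(-141, 0.5),
    "Fz": _ring(0, 0.5),
    "Cz": (0.0, 0.0),
    "Pz": _ring(180, 0.5),
}

#: Canonical channel order for this artifact (asserted, not taken from data).
CHANNELS_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)


@dataclass(frozen=True)
class Montage:
    channels: Tuple[str, ...]
    positions: Dict[str, Tuple[float, float]] = field(repr=False)

    def __post_init__(self):
        if len(set(self.channels)) != len(self.channels):
            raise ChannelMismatchError(unknown=["<duplicate labels>"])
        for ch in self.channels:
            x, y = self.positions[ch]
            if x * x + y * y > 1.0 + 1e-9:
                raise ValueError(f"channel {ch} position outside unit disc")

    def position(self, channel: str) -> Tuple[float, float]:
        return self.positions[channel]

    def normalize_label(self, raw: str) -> str:
        """Map a raw EDF label to the canonical montage label.

        Case-insensitive; an ``EEG `` prefix and trailing reference
        suffixes (``-REF``, ``-LE``, ``-A1`` …) are stripped.
        """
        label = raw.strip()
        if label.upper().startswith("EEG "):
            label = label[4:]
        label = label.split("-")[0].strip()
        lower = {c.lower(): c for c in self.channels}
        return lower.get(label.lower(), label)


MONTAGE_19 = Montage(channels=CHANNELS_19, positions=dict(_POSITIONS))
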