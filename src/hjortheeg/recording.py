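"""In-memory containers: continuous recordings and fixed-length epoch sets."""

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .bands import Band

GROUPS = ("patient", "control")


@dataclass
class EEGRecording:
    """A continuous multi-channel EEG signal in microvolts.

    ``data`` is a (channel, sample) float array; ``channels`` gives the
    label of each row.
    """

    subject_id: str
    group: str
    fs: float
    channels: Tuple[str, ...]
    data: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with {len(self.channels)} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "EEGRecording":
        fields = dict(
            subject_id=self.subject_id,
            group=self.group,
            fs=self.fs,
            channels=self.channels,
            data=self.data,
        )
        fields.update(kwargs)
        return EEGRecording(**fields)


@dataclass
class EpochSet:
    """Fixed-length epochs of one subject: (epoch, channel, sample) tensor."""

    data: np.ndarray = field(repr=False)
    fs: float = 250.0
    epoch_length: float = 4.0
    subject_id: str = ""
    group: str = ""
    channels: Tuple[str, ...] = ()
    band: Optional[Band] = None

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"epoch tensor must be 3-D, got shape {self.data.shape}")
        expected = int(round(self.fs * self.epoch_length))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch sample count {self.data.shape[2]} != fs*epoch_length = {expected}"
            )
        if self.channels and self.data.shape[1] != len(self.channels):
            raise ValueError("channel label count does not match tensor")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch tensor contains non-finite samples")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]
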