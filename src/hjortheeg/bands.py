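"""Frequency band definitions.

The five conventional EEG sub-bands — delta (0.5–4), theta (4–8),
alpha (8–13), beta (13–30) and gamma (30–45 Hz) — are the canonical
decomposition used throughout the pipeline.
"""

from dataclasses import dataclass

from .errors import InvalidBandError


@dataclass(frozen=True)
class Band:
    """A frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise InvalidBandError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high}]"
            )

    def validate_for_fs(self, fs: float) -> None:
        """Raise if the band exceeds the Nyquist frequency for ``fs``."""
        if self.high > fs / 2:
            raise InvalidBandError(
                f"band {self.name!r} upper edge {self.high} Hz exceeds Nyquist {fs / 2} Hz"
            )


CANONICAL_BANDS = (
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("beta", 13.0, 30.0),
    Band("gamma", 30.0, 45.0),
)

BAND_ORDER = {b.name: i for i, b in enumerate(CANONICAL_BANDS)}


def band_by_name(name: str) -> Band:
    for b in CANONICAL_BANDS:
        if b.name == name:
            return b
    raise InvalidBandError(f"unknown band {name!r}; known: {sorted(BAND_ORDER)}")


def sort_band_names(names) -> list:
    """Canonical (delta→gamma) ordering of band names; unknown names last, alphabetically."""
    return sorted(names, key=lambda n: (BAND_ORDER.get(n, len(BAND_ORDER)), n))
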