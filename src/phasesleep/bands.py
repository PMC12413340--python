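"""Canonical EEG frequency-band definitions.

The four bands are deliberately separated by gaps of at least 1 Hz
(e.g. delta ends at 3.5 Hz, theta starts at 4.5 Hz) so that phase
information leaking across band-pass filter edges is not counted twice.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low_hz must be < high_hz")
        if self.low_hz <= 0:
            raise ValueError(f"band {self.name}: low_hz must be positive")

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)


DELTA = BandDefinition("delta", 1.0, 3.5)
THETA = BandDefinition("theta", 4.5, 7.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 13.0, 30.0)

#: Band-major ordering used everywhere features are serialised.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (DELTA, THETA, ALPHA, BETA)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def band_by_name(name: str) -> BandDefinition:
    for band in DEFAULT_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}; expected one of {BAND_NAMES}")


def validate_band_set(bands: tuple[BandDefinition, ...], min_gap_hz: float = 1.0) -> None:
    """Check that bands are ordered, non-overlapping and gapped.

    Raises ValueError if two adjacent bands are closer than ``min_gap_hz``.
    """
    ordered = sorted(bands, key=lambda b: b.low_hz)
    for lo, hi in zip(ordered, ordered[1:]):
        if hi.low_hz - lo.high_hz < min_gap_hz:
            raise ValueError(
                f"bands {lo.name} and {hi.name} are separated by less than "
                f"{min_gap_hz} Hz ({lo.high_hz}-{hi.low_hz})"
            )
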