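"""Container for one labelled, continuous multichannel EEG segment."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: AASM stage labels covered by the pipeline (wake plus the NREM stages).
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3")

#: Fixed 30-label subset of the extended 10-10 system used by the synthetic
#: generator.  Real recordings may carry any montage; this one is the
#: package's declared default.
CHANNELS_10_10: tuple[str, ...] = (
    "Fp1", "Fp2", "AFz", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "POz", "O1", "Oz", "O2",
)

# Schematic 2-D electrode positions on the unit disc (nose up, +y anterior).
# Used only by the synthetic generator's distance-decaying source mixing.
CHANNEL_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95), "AFz": (0.0, 0.80),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.55), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.63, 0.28), "FC1": (-0.22, 0.26), "FC2": (0.22, 0.26),
    "FC6": (0.63, 0.28),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.63, -0.28), "CP1": (-0.22, -0.26), "CP2": (0.22, -0.26),
    "CP6": (0.63, -0.28),
    "P7": (-0.81, -0.59), "P3": (-0.40, -0.55), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.55), "P8": (0.81, -0.59),
    "POz": (0.0, -0.80), "O1": (-0.31, -0.95), "Oz": (0.0, -1.0),
    "O2": (0.31, -0.95),
}


def default_channel_names(n_channels: int) -> tuple[str, ...]:
    """First ``n_channels`` labels of the default 10-10 subset.

    For counts above 30 synthetic labels ``ch<i>`` are appended.
    """
    if n_channels <= len(CHANNELS_10_10):
        return CHANNELS_10_10[:n_channels]
    extra = tuple(f"ch{i}" for i in range(len(CHANNELS_10_10), n_channels))
    return CHANNELS_10_10 + extra


def channel_positions(channel_names: tuple[str, ...]) -> np.ndarray:
    """(n, 2) array of schematic positions; unknown labels get ring slots."""
    pos = np.zeros((len(channel_names), 2))
    for k, name in enumerate(channel_names):
        if name in CHANNEL_POSITIONS:
            pos[k] = CHANNEL_POSITIONS[name]
        else:
            ang = 2 * np.pi * k / max(len(channel_names), 1)
            pos[k] = (0.7 * np.cos(ang), 0.7 * np.sin(ang))
    return pos


@dataclass
class EEGRecording:
    """One continuous multichannel EEG segment with a single stage label.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Potentials in arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Ordered channel labels.
    stage : str
        AASM label, one of ``W, N1, N2, N3``.
    subject_id : str
    edge_pad_s : float
        Extra signal generated (or retained) at each end purely to absorb
        filter and Hilbert transients; the preprocessing chain trims exactly
        this much before epoching, so the *nominal* segment length is
        ``duration_s - 2 * edge_pad_s``.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = field(default=())
    stage: str = "W"
    subject_id: str = "S0"
    edge_pad_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x time)")
        if self.stage not in STAGES:
            raise ValueError(f"invalid stage label {self.stage!r}; expected one of {STAGES}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if not self.channel_names:
            self.channel_names = default_channel_names(self.data.shape[0])
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        """Full duration including edge padding."""
        return self.n_samples / self.fs

    @property
    def nominal_duration_s(self) -> float:
        """Duration of the analysis segment, excluding edge padding."""
        return self.duration_s - 2.0 * self.edge_pad_s

    def copy_with(self, **kwargs) -> "EEGRecording":
        return replace(self, **kwargs)
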