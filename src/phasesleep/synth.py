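"""Surrogate sleep-EEG generator with stage- and band-dependent phase coupling.

The generator emulates the statistical structure the downstream analysis
assumes, not biophysics.  Each stage is summarised by a :class:`StageProfile`:
per band, a narrowband common source (band-passed Gaussian noise, so coupling
is graded rather than saturating) is mixed into every channel with
distance-decaying weights over a schematic 2-D montage, optionally shifted by
a per-channel phase lag; independent 1/f background noise is added per
channel, and N2 additionally receives transient sigma-band (13-15 Hz) bursts
mimicking sleep spindles.

Stage structure of the defaults: alpha-band coupling is strongest in wake and
decays through N1/N2; delta-band coupling grows from N2 into N3; spindle
bursts raise beta-band coupling in N2.  These orderings are what the
stage-difference statistics and the classifier are expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .bands import BAND_NAMES, DEFAULT_BANDS, BandDefinition
from .recording import (
    STAGES,
    EEGRecording,
    channel_positions,
    default_channel_names,
)

__all__ = [
    "StageProfile",
    "CohortSpec",
    "TABLE1_SEGMENT_LENGTHS",
    "default_profiles",
    "generate_stage_recording",
    "generate_cohort",
]

#: Per-subject segment lengths (seconds) of the reference cohort: 14 subjects,
#: one artefact-free segment per NREM stage, minimum 100 s.  The 56 lengths
#: sum to 11376 s.
TABLE1_SEGMENT_LENGTHS: dict[str, tuple[int, ...]] = {
    "W": (180, 183, 210, 120, 270, 300, 181, 120, 270, 240, 150, 150, 300, 184),
    "N1": (188, 123, 210, 120, 270, 300, 185, 120, 270, 240, 150, 150, 300, 180),
    "N2": (183, 182, 210, 120, 270, 300, 183, 120, 270, 240, 150, 150, 300, 181),
    "N3": (181, 181, 210, 120, 270, 300, 180, 120, 270, 240, 150, 150, 300, 181),
}

# Schematic source locations per band on the unit disc (+y anterior):
# alpha posterior, delta/theta frontal, beta and spindle sources central.
_SOURCE_POSITIONS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 0.55),
    "theta": (0.0, 0.40),
    "alpha": (0.0, -0.75),
    "beta": (0.0, 0.0),
    "spindle": (0.0, 0.15),
}

# Dipole orientation of each source (unit vector in the 2-D plane).  The
# signed lead-field pattern puts opposite polarities on opposite sides of
# the source, so the common-mode content of the mixed signal is small and
# average referencing leaves the coupling structure intact.
_SOURCE_ORIENTATIONS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 1.0),
    "theta": (0.0, 1.0),
    "alpha": (0.0, 1.0),
    "beta": (1.0, 0.0),
    "spindle": (1.0, 0.0),
}

#: Spatial decay length of source mixing, in units of the head radius.
#: Large enough that every source reaches most channels (coupling is
#: spatially widespread, as scalp EEG volume conduction makes it).
_MIXING_DECAY = 1.2


@dataclass
class StageProfile:
    """Generative description of one sleep stage.

    coupling_strength
        Band name -> mixing weight in [0, 1] of that band's common source.
    source_lag
        Band name -> per-channel phase lag in radians.  ``None`` means
        propagation-like lags proportional to distance from the band's
        source (max ``lag_scale`` rad); a scalar is broadcast to all
        channels; an array gives explicit per-channel lags.  Zero lags
        everywhere reproduce a pure volume-conduction (instantaneous
        mixing) scenario.
    burst_rate
        Spindle-band burst events per minute (used for N2).
    noise_sd
        Amplitude of the independent 1/f channel noise (arbitrary units).
    lag_scale
        Maximum propagation lag in radians when ``source_lag`` is ``None``.
    """

    stage: str
    coupling_strength: dict[str, float]
    source_lag: dict[str, object] = field(default_factory=dict)
    burst_rate: float = 0.0
    noise_sd: float = 1.0
    lag_scale: float = 0.6
    burst_amplitude: float = 2.0
    mixing: str = "dipolar"  # or "uniform": identical source into every channel
    #: overall amplitude of a fully-coupled source relative to the unit-SD
    #: channel noise; sets how strongly coupling_strength=1 stands out of
    #: the 1/f background within its band
    source_gain: float = 3.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"invalid stage label {self.stage!r}")
        missing = [b for b in BAND_NAMES if b not in self.coupling_strength]
        if missing:
            raise ValueError(f"profile {self.stage}: missing coupling for bands {missing}")
        for band, c in self.coupling_strength.items():
            if not 0.0 <= float(c) <= 1.0:
                raise ValueError(f"coupling_strength[{band}]={c} outside [0, 1]")
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CohortSpec:
    """Size and sampling parameters of a synthetic cohort.

    ``segment_length_s`` is either a single number applied to every
    recording or a mapping stage -> per-subject sequence (e.g.
    :data:`TABLE1_SEGMENT_LENGTHS`).  Segments must be at least 100 s, the
    minimum the analysis assumes.  ``edge_pad_s`` seconds of extra signal
    are generated at each end and trimmed again after filtering, so the
    nominal length is what the epoching sees.
    """

    n_subjects: int = 14
    segment_length_s: object = 200.0
    fs: float = 250.0
    n_channels: int = 30
    seed: int = 0
    edge_pad_s: float = 2.0
    coupling_jitter_sd: float = 0.10  # fractional, truncated at 2 sd

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        highest_edge = max(b.high_hz for b in DEFAULT_BANDS)
        if self.fs <= 2.0 * highest_edge:
            raise ValueError(
                f"fs={self.fs} too low: need fs > {2 * highest_edge} Hz to "
                "resolve the beta band"
            )
        for length in self.iter_lengths():
            if length < 100.0:
                raise ValueError("segment_length_s must be >= 100 s")

    def iter_lengths(self):
        if isinstance(self.segment_length_s, dict):
            for stage in STAGES:
                seq = self.segment_length_s[stage]
                if len(seq) != self.n_subjects:
                    raise ValueError(
                        f"segment_length_s[{stage}] must list {self.n_subjects} values"
                    )
                yield from (float(v) for v in seq)
        else:
            yield float(self.segment_length_s)

    def length_for(self, stage: str, subject_index: int) -> float:
        if isinstance(self.segment_length_s, dict):
            return float(self.segment_length_s[stage][subject_index])
        return float(self.segment_length_s)


def default_profiles(noise_sd: float = 1.0) -> dict[str, StageProfile]:
    """Stage profiles encoding the qualitative sleep-stage structure.

    Alpha coupling decreases monotonically W > N1 > N2 > N3; delta coupling
    increases W < N1 < N2 < N3; N2 carries spindle bursts (raising beta
    coupling); theta is a weak, stage-flat background band.
    """
    strengths = {
        "W": {"delta": 0.10, "theta": 0.15, "alpha": 0.80, "beta": 0.20},
        "N1": {"delta": 0.25, "theta": 0.30, "alpha": 0.50, "beta": 0.20},
        "N2": {"delta": 0.50, "theta": 0.30, "alpha": 0.30, "beta": 0.35},
        "N3": {"delta": 0.80, "theta": 0.25, "alpha": 0.15, "beta": 0.15},
    }
    bursts = {"W": 0.0, "N1": 0.0, "N2": 4.0, "N3": 0.0}
    return {
        stage: StageProfile(
            stage=stage,
            coupling_strength=strengths[stage],
            burst_rate=bursts[stage],
            noise_sd=noise_sd,
        )
        for stage in STAGES
    }


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, fs: float) -> np.ndarray:
    """Independent 1/f-shaped noise, unit standard deviation per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    # amplitude ~ f^{-1/2} (power ~ 1/f), flattened below 0.5 Hz to keep
    # finite low-frequency power
    shape = 1.0 / np.sqrt(np.maximum(freqs, 0.5))
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _narrowband_source(
    rng: np.random.Generator, band: BandDefinition, n_samples: int, fs: float
) -> np.ndarray:
    """Complex analytic narrowband source with unit real-part RMS."""
    sos = butter(4, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n_samples))
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x = x / rms
    return hilbert(x)


def _mixing_weights(band_key: str, positions: np.ndarray, mixing: str = "dipolar") -> np.ndarray:
    """Signed, distance-decaying lead-field weights of a band's source.

    ``dipolar`` (default): exp(-d / decay) times the cosine of the angle
    between the source-to-channel vector and the dipole orientation — the
    polarity flips across the source, as for a tangential cortical dipole,
    keeping the montage mean (common mode) small.  ``uniform``: all ones
    (every channel sees the identical source), for controlled tests.
    """
    if mixing == "uniform":
        return np.ones(positions.shape[0])
    src = np.asarray(_SOURCE_POSITIONS.get(band_key, (0.0, 0.0)))
    u = np.asarray(_SOURCE_ORIENTATIONS.get(band_key, (0.0, 1.0)))
    delta = positions - src
    dist = np.linalg.norm(delta, axis=1)
    cosang = (delta @ u) / np.maximum(dist, 1e-9)
    # keep a floor on |cos| so no channel is exactly in the null plane
    signed = np.sign(cosang) * np.maximum(np.abs(cosang), 0.25)
    w = np.exp(-dist / _MIXING_DECAY) * signed
    return w / np.max(np.abs(w))


def _resolve_lags(
    spec_lag: object, band_key: str, positions: np.ndarray, lag_scale: float
) -> np.ndarray:
    n = positions.shape[0]
    if spec_lag is None:
        src = np.asarray(_SOURCE_POSITIONS.get(band_key, (0.0, 0.0)))
        dist = np.linalg.norm(positions - src, axis=1)
        dmax = dist.max()
        return lag_scale * dist / dmax if dmax > 0 else np.zeros(n)
    lag = np.asarray(spec_lag, dtype=float)
    if lag.ndim == 0:
        return np.full(n, float(lag))
    if lag.shape != (n,):
        raise ValueError(f"source_lag for band {band_key} must be scalar or length {n}")
    return lag


def generate_stage_recording(
    profile: StageProfile,
    spec: CohortSpec,
    subject_id: str = "S0",
    seed: object = 0,
    subject_index: int = 0,
) -> EEGRecording:
    """Generate one stage-labelled surrogate recording.

    Deterministic given ``(profile, spec, seed)``.  ``seed`` may be an int
    or a sequence of ints (numpy SeedSequence entropy).
    """
    rng = np.random.default_rng(seed)
    fs = spec.fs
    nominal_s = spec.length_for(profile.stage, subject_index)
    n_samples = int(round((nominal_s + 2.0 * spec.edge_pad_s) * fs))
    names = default_channel_names(spec.n_channels)
    positions = channel_positions(names)

    data = np.zeros((spec.n_channels, n_samples))
    for band in DEFAULT_BANDS:
        strength = float(profile.coupling_strength[band.name])
        if strength == 0.0:
            continue
        z = _narrowband_source(rng, band, n_samples, fs)
        w = _mixing_weights(band.name, positions, profile.mixing)
        lags = _resolve_lags(
            profile.source_lag.get(band.name), band.name, positions, profile.lag_scale
        )
        # channel i receives the source rotated by its lag: for a narrowband
        # analytic signal, multiplying by exp(-i*lag) delays the phase.
        data += (profile.source_gain * strength * w[:, None]
                 * np.real(z[None, :] * np.exp(-1j * lags)[:, None]))

    if profile.burst_rate > 0:
        _add_spindle_bursts(rng, data, profile, spec, positions)

    if profile.noise_sd > 0:
        data += profile.noise_sd * _pink_noise(rng, spec.n_channels, n_samples, fs)

    return EEGRecording(
        data=data,
        fs=fs,
        channel_names=names,
        stage=profile.stage,
        subject_id=subject_id,
        edge_pad_s=spec.edge_pad_s,
    )


def _add_spindle_bursts(
    rng: np.random.Generator,
    data: np.ndarray,
    profile: StageProfile,
    spec: CohortSpec,
    positions: np.ndarray,
) -> None:
    """Add transient 13-15 Hz bursts shared across channels (in place)."""
    fs = spec.fs
    n_samples = data.shape[1]
    duration_min = n_samples / fs / 60.0
    n_bursts = rng.poisson(profile.burst_rate * duration_min)
    if n_bursts == 0:
        return
    w = _mixing_weights("spindle", positions, profile.mixing)
    burst_len = int(round(1.0 * fs))  # ~1 s spindles
    t = np.arange(burst_len) / fs
    env = np.hanning(burst_len)
    for _ in range(n_bursts):
        f0 = rng.uniform(13.0, 15.0)
        phi0 = rng.uniform(0, 2 * np.pi)
        start = rng.integers(0, max(n_samples - burst_len, 1))
        burst = profile.burst_amplitude * env * np.cos(2 * np.pi * f0 * t + phi0)
        data[:, start : start + burst_len] += w[:, None] * burst[None, :]


def _jitter_profile(
    profile: StageProfile, rng: np.random.Generator, sd: float
) -> StageProfile:
    """Truncated-normal multiplicative jitter on coupling strengths."""
    if sd <= 0:
        return profile
    jittered = {}
    for band, c in profile.coupling_strength.items():
        eps = np.clip(rng.normal(0.0, sd), -2.0 * sd, 2.0 * sd)
        jittered[band] = float(np.clip(c * (1.0 + eps), 0.0, 1.0))
    return StageProfile(
        stage=profile.stage,
        coupling_strength=jittered,
        source_lag=profile.source_lag,
        burst_rate=profile.burst_rate,
        noise_sd=profile.noise_sd,
        lag_scale=profile.lag_scale,
        burst_amplitude=profile.burst_amplitude,
        mixing=profile.mixing,
        source_gain=profile.source_gain,
    )


def generate_cohort(
    profiles: dict[str, StageProfile] | None = None,
    spec: CohortSpec | None = None,
) -> list[EEGRecording]:
    """Generate ``n_subjects x 4`` recordings, one per stage per subject.

    Coupling strengths are jittered per subject (truncated normal,
    fractional sd ``spec.coupling_jitter_sd``) so subject-wise train/test
    splits face genuine between-subject variance.  All randomness derives
    reproducibly from ``spec.seed``.
    """
    if spec is None:
        spec = CohortSpec()
    if profiles is None:
        profiles = default_profiles()
    missing = [s for s in STAGES if s not in profiles]
    if missing:
        raise ValueError(f"profiles missing for stages {missing}")

    recordings: list[EEGRecording] = []
    for si in range(spec.n_subjects):
        subject_id = f"S{si + 1:02d}"
        jitter_rng = np.random.default_rng([spec.seed, 7919, si])
        for gi, stage in enumerate(STAGES):
            profile = _jitter_profile(profiles[stage], jitter_rng, spec.coupling_jitter_sd)
            rec = generate_stage_recording(
                profile,
                spec,
                subject_id=subject_id,
                seed=[spec.seed, si, gi],
                subject_index=si,
            )
            recordings.append(rec)
    return recordings
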