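"""Six Hilbert-based phase-coupling metrics and their feature assembly.

All metrics are time-domain functionals of the per-sample cross spectrum

    S_ij(t) = A_i(t) A_j(t) exp(+i (phi_i(t) - phi_j(t)))

between the analytic signals of two channels, averaged over one 10 s epoch
(denoted ``<.>``):

    COH   = |<S_ij>| / sqrt(<S_ii><S_jj>)          amplitude- and zero-lag-sensitive
    iCOH  = Im(<S_ij> / sqrt(<S_ii><S_jj>))        zero-lag-insensitive, signed
    PLV   = |<S_ij / |S_ij|>| = |<exp(i dphi)>|    amplitude-agnostic
    ciPLV = |<Im e^{i dphi}>| / sqrt(1 - <Re e^{i dphi}>^2)
    PLI   = |<sign(Im S_ij)>|                      lag-sign asymmetry
    wPLI  = |<Im S_ij>| / <|Im S_ij|>              noise-robust PLI variant

Sign convention: the exponent carries +i(phi_i - phi_j), so a channel i that
*leads* j by a quarter cycle gives iCOH = +1.  Only the sign of iCOH depends
on this choice; all magnitude metrics are unaffected.  Conventions for
degenerate inputs: sign(0) = 0 in PLI; a vanishing denominator in wPLI or
ciPLV yields 0 (the continuous limit of the noise-free zero-lag case).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, DEFAULT_BANDS, BandDefinition
from .preprocess import AnalyticEpoch, analytic_epochs
from .recording import EEGRecording

__all__ = [
    "METRICS",
    "CrossSpectrumSeries",
    "ConnectivityMatrix",
    "FeatureVector",
    "coh",
    "icoh",
    "plv",
    "ciplv",
    "pli",
    "wpli",
    "connectivity_matrix",
    "vectorize",
    "devectorize",
    "power_features",
    "feature_names",
    "power_feature_names",
    "compute_feature_tables",
    "compute_power_table",
]

#: Canonical metric ordering used in tables and file names.
METRICS: tuple[str, ...] = ("COH", "iCOH", "PLV", "ciPLV", "PLI", "wPLI")

_AMP_EPS = 1e-12  # amplitude below this counts as a zero-amplitude sample


@dataclass
class CrossSpectrumSeries:
    """Per-sample cross and power spectra for one channel pair and epoch."""

    s_ij: np.ndarray  # complex, A_i A_j exp(+i dphi)
    s_ii: np.ndarray  # real, A_i^2
    s_jj: np.ndarray  # real, A_j^2

    @classmethod
    def from_analytic(cls, z_i: np.ndarray, z_j: np.ndarray) -> "CrossSpectrumSeries":
        z_i = np.asarray(z_i, dtype=complex)
        z_j = np.asarray(z_j, dtype=complex)
        return cls(s_ij=z_i * np.conj(z_j), s_ii=np.abs(z_i) ** 2, s_jj=np.abs(z_j) ** 2)

    @classmethod
    def from_phase(cls, dphi: np.ndarray, a_i: float | np.ndarray = 1.0,
                   a_j: float | np.ndarray = 1.0) -> "CrossSpectrumSeries":
        """Build from a phase-difference series with given amplitudes."""
        dphi = np.asarray(dphi, dtype=float)
        a_i = np.broadcast_to(np.asarray(a_i, dtype=float), dphi.shape)
        a_j = np.broadcast_to(np.asarray(a_j, dtype=float), dphi.shape)
        return cls(s_ij=a_i * a_j * np.exp(1j * dphi), s_ii=a_i**2, s_jj=a_j**2)

    @property
    def dphi(self) -> np.ndarray:
        return np.angle(self.s_ij)

    @property
    def n_samples(self) -> int:
        return self.s_ij.shape[-1]


def _unit_phasors(css: CrossSpectrumSeries) -> np.ndarray:
    """S_ij / |S_ij| with zero-amplitude samples excluded (warned)."""
    mag = np.abs(css.s_ij)
    valid = mag > _AMP_EPS
    n_bad = int(np.size(mag) - np.count_nonzero(valid))
    if n_bad:
        warnings.warn(f"{n_bad} zero-amplitude samples excluded from phase metrics",
                      stacklevel=3)
    if not np.any(valid):
        raise ValueError("all samples have zero amplitude; phase undefined")
    return css.s_ij[valid] / mag[valid]


def coh(css: CrossSpectrumSeries) -> float:
    """Coherence: |<S_ij>| / sqrt(<S_ii><S_jj>), in [0, 1]."""
    denom = np.sqrt(np.mean(css.s_ii) * np.mean(css.s_jj))
    if denom <= _AMP_EPS:
        warnings.warn("zero-power channel: COH undefined", stacklevel=2)
        return float("nan")
    return float(np.abs(np.mean(css.s_ij)) / denom)


def icoh(css: CrossSpectrumSeries) -> float:
    """Imaginary part of coherency, in [-1, 1]; positive when i leads j."""
    denom = np.sqrt(np.mean(css.s_ii) * np.mean(css.s_jj))
    if denom <= _AMP_EPS:
        warnings.warn("zero-power channel: iCOH undefined", stacklevel=2)
        return float("nan")
    return float(np.imag(np.mean(css.s_ij)) / denom)


def plv(css: CrossSpectrumSeries) -> float:
    """Phase-locking value: |<exp(i dphi)>|, in [0, 1]."""
    return float(np.abs(np.mean(_unit_phasors(css))))


def ciplv(css: CrossSpectrumSeries) -> float:
    """Corrected imaginary PLV: |<Im e^{i dphi}>| / sqrt(1 - <Re e^{i dphi}>^2)."""
    u = _unit_phasors(css)
    re = np.mean(np.real(u))
    im = np.mean(np.imag(u))
    denom_sq = 1.0 - re**2
    if denom_sq <= _AMP_EPS:
        # |<Re>| = 1 forces Im = 0 for every sample: zero-lag limit
        return 0.0
    return float(np.abs(im) / np.sqrt(denom_sq))


def _thresholded_sign(im: np.ndarray, scale: float) -> np.ndarray:
    """sign(Im) with |Im| below a relative tolerance treated as exact 0.

    Zero-lag coupling leaves floating-point residue of order eps * |S| in
    the imaginary part; counting its sign would turn the sign(0) = 0
    convention into coin flips.
    """
    tol = 1e-12 * scale
    return np.sign(im) * (np.abs(im) > tol)


def pli(css: CrossSpectrumSeries) -> float:
    """Phase lag index: |<sign(Im S_ij)>| with sign(0) = 0, in [0, 1]."""
    im = np.imag(css.s_ij)
    scale = float(np.mean(np.abs(css.s_ij)))
    return float(np.abs(np.mean(_thresholded_sign(im, scale))))


def wpli(css: CrossSpectrumSeries) -> float:
    """Weighted phase lag index: |<Im S_ij>| / <|Im S_ij|>, in [0, 1]."""
    im = np.imag(css.s_ij)
    denom = np.mean(np.abs(im))
    if denom <= _AMP_EPS:
        # purely real cross-spectrum: no lag information
        return 0.0
    return float(np.abs(np.mean(im)) / denom)


METRIC_FUNCS = {"COH": coh, "iCOH": icoh, "PLV": plv, "ciPLV": ciplv,
                "PLI": pli, "wPLI": wpli}


@lru_cache(maxsize=32)
def _triu(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel coupling values for one (epoch, band, metric).

    The diagonal is NaN (self-coupling undefined).  For the signed iCOH the
    i<j value is mirrored symmetrically so that vectorisation reads a
    consistent upper triangle.
    """

    values: np.ndarray
    metric: str
    band: str
    epoch_index: int = 0
    subject_id: str = "S0"
    stage: str = "W"

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_pairs(self) -> int:
        n = self.n_channels
        return n * (n - 1) // 2

    def pair_values(self) -> np.ndarray:
        """Upper-triangle (i < j, row-major) values, length n_pairs."""
        return self.values[_triu(self.n_channels)]


def _epoch_metric_matrices(z: np.ndarray, metrics: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Vectorised all-pairs metrics for one epoch's analytic signals.

    ``z`` is complex (n_channels, n_samples).  Equivalent, pair by pair, to
    the scalar metric functions (asserted in the tests); the diagonal is NaN.
    """
    n_ch, n_t = z.shape
    out: dict[str, np.ndarray] = {}

    s_bar = (z @ z.conj().T) / n_t                      # <S_ij>
    power = np.mean(np.abs(z) ** 2, axis=1)             # <S_ii>
    denom = np.sqrt(np.outer(power, power))
    safe = denom > _AMP_EPS

    if "COH" in metrics or "iCOH" in metrics:
        coherency = np.full_like(s_bar, np.nan + 0j)
        coherency[safe] = s_bar[safe] / denom[safe]
        if "COH" in metrics:
            out["COH"] = np.abs(coherency)
        if "iCOH" in metrics:
            # antisymmetric: mirror the i<j sign so the matrix is symmetric
            ic = np.imag(coherency)
            out["iCOH"] = np.triu(ic, k=1) + np.triu(ic, k=1).T

    if any(m in metrics for m in ("PLV", "ciPLV")):
        mag = np.abs(z)
        u = np.where(mag > _AMP_EPS, z / np.where(mag > _AMP_EPS, mag, 1.0), 0.0)
        n_valid = (mag > _AMP_EPS).astype(float)
        counts = n_valid @ n_valid.T  # per-pair count of jointly valid samples
        counts = np.maximum(counts, 1.0)
        u_bar = (u @ u.conj().T) / counts
        if "PLV" in metrics:
            out["PLV"] = np.abs(u_bar)
        if "ciPLV" in metrics:
            re, im = np.real(u_bar), np.imag(u_bar)
            denom_sq = 1.0 - re**2
            ci = np.zeros_like(re)
            ok = denom_sq > _AMP_EPS
            ci[ok] = np.abs(im[ok]) / np.sqrt(denom_sq[ok])
            out["ciPLV"] = ci

    if "PLI" in metrics or "wPLI" in metrics:
        # per-sample Im(S_ij): (n_ch, n_ch, n_t) — fine at 30 channels
        im_s = np.imag(z[:, None, :] * z.conj()[None, :, :])
        if "PLI" in metrics:
            abs_z = np.abs(z)
            scale = (abs_z @ abs_z.T) / n_t  # per-pair mean |S_ij|
            signs = np.sign(im_s) * (np.abs(im_s) > 1e-12 * scale[:, :, None])
            out["PLI"] = np.abs(np.mean(signs, axis=2))
        if "wPLI" in metrics:
            num = np.abs(np.mean(im_s, axis=2))
            den = np.mean(np.abs(im_s), axis=2)
            wp = np.zeros((n_ch, n_ch))
            ok = den > _AMP_EPS
            wp[ok] = num[ok] / den[ok]
            out["wPLI"] = wp

    for m in out:
        np.fill_diagonal(out[m], np.nan)
    return out


def connectivity_matrix(epoch: AnalyticEpoch, metric: str) -> ConnectivityMatrix:
    """All-pairs coupling matrix for one epoch and one metric."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    values = _epoch_metric_matrices(epoch.analytic, (metric,))[metric]
    return ConnectivityMatrix(
        values=values,
        metric=metric,
        band=epoch.band.name,
        epoch_index=epoch.epoch_index,
        subject_id=epoch.subject_id,
        stage=epoch.stage,
    )


@dataclass
class FeatureVector:
    """Ordered coupling coefficients for one epoch and metric.

    Ordering is band-major (delta, theta, alpha, beta), within a band the
    upper-triangle pairs (i, j), i < j, row-major — 4 x C(n, 2) entries,
    i.e. 1740 for the 30-channel montage.
    """

    coefficients: np.ndarray
    label: str
    subject_id: str
    epoch_index: int
    metric: str
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("feature vector contains non-finite values")


def vectorize(matrices: dict[str, ConnectivityMatrix],
              band_order: tuple[str, ...] = BAND_NAMES) -> FeatureVector:
    """Concatenate one matrix per band into the canonical feature vector."""
    missing = [b for b in band_order if b not in matrices]
    if missing:
        raise ValueError(f"missing connectivity matrices for bands {missing}")
    first = matrices[band_order[0]]
    metrics = {m.metric for m in matrices.values()}
    if len(metrics) != 1:
        raise ValueError(f"mixed metrics in one feature vector: {sorted(metrics)}")
    coeffs = np.concatenate([matrices[b].pair_values() for b in band_order])
    names = feature_names(first.n_channels, band_order=band_order)
    return FeatureVector(
        coefficients=coeffs,
        label=first.stage,
        subject_id=first.subject_id,
        epoch_index=first.epoch_index,
        metric=first.metric,
        names=names,
    )


def devectorize(vec: FeatureVector, n_channels: int,
                band_order: tuple[str, ...] = BAND_NAMES) -> dict[str, np.ndarray]:
    """Inverse of :func:`vectorize` (upper triangle mirrored, NaN diagonal)."""
    n_pairs = n_channels * (n_channels - 1) // 2
    if vec.coefficients.size != n_pairs * len(band_order):
        raise ValueError("coefficient length inconsistent with n_channels")
    iu = _triu(n_channels)
    out = {}
    for k, band in enumerate(band_order):
        m = np.full((n_channels, n_channels), np.nan)
        vals = vec.coefficients[k * n_pairs : (k + 1) * n_pairs]
        m[iu] = vals
        m[(iu[1], iu[0])] = vals
        out[band] = m
    return out


@lru_cache(maxsize=64)
def feature_names(n_channels: int, channel_names: tuple[str, ...] | None = None,
                  band_order: tuple[str, ...] = BAND_NAMES) -> tuple[str, ...]:
    """Stable column names ``<band>_<ch_i>-<ch_j>`` in vectorisation order."""
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(n_channels))
    iu = _triu(n_channels)
    pair_labels = [f"{channel_names[i]}-{channel_names[j]}" for i, j in zip(*iu)]
    return tuple(f"{b}_{p}" for b in band_order for p in pair_labels)


def power_feature_names(n_channels: int, channel_names: tuple[str, ...] | None = None,
                        band_order: tuple[str, ...] = BAND_NAMES) -> tuple[str, ...]:
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(n_channels))
    return tuple(f"pow_{b}_{c}" for b in band_order for c in channel_names[:n_channels])


def power_features(epochs: dict[str, AnalyticEpoch],
                   band_order: tuple[str, ...] = BAND_NAMES) -> np.ndarray:
    """Per-channel band power: mean of A(t)^2 over the epoch, band-major.

    A unit-amplitude analytic signal (A = 1) yields feature 1.0; the
    corresponding real sinusoid has mean-square 0.5 — the A^2 definition is
    the one used here.
    """
    missing = [b for b in band_order if b not in epochs]
    if missing:
        raise ValueError(f"missing epochs for bands {missing}")
    return np.concatenate(
        [np.mean(epochs[b].amplitude**2, axis=1) for b in band_order]
    )


def _epoch_rows(
    rec: EEGRecording,
    metrics: tuple[str, ...],
    bands: tuple[BandDefinition, ...],
    window_s: float,
    order: int,
    max_excluded_frac: float = 0.01,
):
    """Yield per-epoch feature rows (one per metric) plus a power row."""
    by_band = analytic_epochs(rec, bands=bands, window_s=window_s, order=order)
    band_names = tuple(b.name for b in bands)
    n_epochs = len(by_band[band_names[0]])
    for k in range(n_epochs):
        epochs_k = {b: by_band[b][k] for b in band_names}
        # drop epochs with too many (near-)zero-amplitude samples
        excluded = max(
            float(np.mean(e.amplitude <= _AMP_EPS)) for e in epochs_k.values()
        )
        if excluded > max_excluded_frac:
            continue
        per_metric = {}
        for b in band_names:
            z = epochs_k[b].analytic
            mats = _epoch_metric_matrices(z, metrics)
            for m in metrics:
                per_metric.setdefault(m, {})[b] = ConnectivityMatrix(
                    values=mats[m], metric=m, band=b, epoch_index=k,
                    subject_id=rec.subject_id, stage=rec.stage,
                )
        vectors = {m: vectorize(per_metric[m], band_order=band_names) for m in metrics}
        pow_row = power_features(epochs_k, band_order=band_names)
        yield k, vectors, pow_row


def compute_feature_tables(
    recordings: list[EEGRecording],
    metrics: tuple[str, ...] = METRICS,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    window_s: float = 10.0,
    order: int = 6,
) -> dict[str, pd.DataFrame]:
    """One feature table per metric: a row per epoch, 4 x C(n,2) columns.

    Each DataFrame carries ``subject``, ``stage``, ``epoch`` index columns
    followed by the named coupling features in canonical order.
    """
    rows: dict[str, list] = {m: [] for m in metrics}
    meta: list[tuple[str, str, int]] = []
    names = None
    ch_names = None
    for rec in recordings:
        if ch_names is None:
            ch_names = rec.channel_names
        for k, vectors, _pow in _epoch_rows(rec, metrics, bands, window_s, order):
            meta.append((rec.subject_id, rec.stage, k))
            for m in metrics:
                rows[m].append(vectors[m].coefficients)
    if names is None and ch_names is not None:
        names = feature_names(len(ch_names), ch_names, tuple(b.name for b in bands))
    out = {}
    meta_df = pd.DataFrame(meta, columns=["subject", "stage", "epoch"])
    for m in metrics:
        feat = pd.DataFrame(np.asarray(rows[m]), columns=list(names))
        out[m] = pd.concat([meta_df.reset_index(drop=True), feat], axis=1)
    return out


def compute_power_table(
    recordings: list[EEGRecording],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    window_s: float = 10.0,
    order: int = 6,
) -> pd.DataFrame:
    """Spectral-power baseline features: n_channels x n_bands per epoch."""
    rows, meta = [], []
    ch_names = None
    for rec in recordings:
        if ch_names is None:
            ch_names = rec.channel_names
        for k, _vectors, pow_row in _epoch_rows(rec, ("COH",), bands, window_s, order):
            meta.append((rec.subject_id, rec.stage, k))
            rows.append(pow_row)
    names = power_feature_names(len(ch_names), ch_names, tuple(b.name for b in bands))
    meta_df = pd.DataFrame(meta, columns=["subject", "stage", "epoch"])
    feat = pd.DataFrame(np.asarray(rows), columns=list(names))
    return pd.concat([meta_df, feat], axis=1)
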