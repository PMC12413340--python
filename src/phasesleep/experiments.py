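"""Reusable study-condition experiments.

Each function runs one calibration or validation experiment end to end
through the package — null type-I calibration of the omnibus tests,
chance-level and high-contrast classification, Welch cross-validation of
the time-domain coherence — at cohort sizes small enough for routine runs.
The experiment conditions (cohort sizes, sampling rates, profiles) are
fixed choices documented in the methods note, not tunables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sg

from .bands import ALPHA, BAND_NAMES
from .classify import (
    AggregateResult,
    ClassifierConfig,
    aggregate,
    fit_evaluate,
    make_splits,
    run_classification,
)
from .connectivity import CrossSpectrumSeries, coh, compute_feature_tables
from .recording import STAGES
from .stats import bonferroni, friedman, stage_tables_from_features
from .synth import CohortSpec, StageProfile, default_profiles, generate_cohort

__all__ = [
    "null_type1_rate",
    "high_contrast_profiles",
    "alpha_contrast_profiles",
    "classification_experiment",
    "chance_level_accuracy",
    "welch_coherence_deviation",
]


def _flat_profiles(noise_sd: float = 1.0) -> dict[str, StageProfile]:
    """Stage profiles with no stage effect: all couplings zero."""
    zero = {b: 0.0 for b in BAND_NAMES}
    return {
        stage: StageProfile(stage=stage, coupling_strength=dict(zero),
                            noise_sd=noise_sd)
        for stage in STAGES
    }


def null_type1_rate(
    n_cohorts: int = 200,
    seed: int = 0,
    n_subjects: int = 14,
    n_channels: int = 3,
    fs: float = 80.0,
    segment_length_s: float = 100.0,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Fraction of significant omnibus tests on stage-effect-free cohorts.

    Each cohort is pure 1/f noise (all couplings zero), run through the
    full feature pipeline; all 6 x 4 Friedman tests are evaluated at the
    Bonferroni-adjusted threshold alpha / 24.  Returns ``(fraction,
    n_tests)``; a calibrated pipeline keeps the fraction at or below alpha.
    """
    profiles = _flat_profiles()
    alpha_adj = bonferroni(alpha, len(BAND_NAMES) * 6)
    n_sig = 0
    n_tests = 0
    for c in range(n_cohorts):
        spec = CohortSpec(
            n_subjects=n_subjects, segment_length_s=segment_length_s,
            fs=fs, n_channels=n_channels, seed=int(seed + 1000 * c) % (2**31),
        )
        cohort = generate_cohort(profiles, spec)
        tables = compute_feature_tables(cohort)
        stage_tables = stage_tables_from_features(tables)
        for table in stage_tables.values():
            _, p = friedman(table)
            n_sig += p < alpha_adj
            n_tests += 1
    return n_sig / n_tests, n_tests


def high_contrast_profiles() -> dict[str, StageProfile]:
    """High-SNR variant of the default stage profiles.

    Same qualitative structure, stronger sources (gain 4) — the condition
    under which the classifier is expected to recover stages almost
    perfectly.
    """
    profiles = default_profiles()
    for p in profiles.values():
        p.source_gain = 4.0
    return profiles


def alpha_contrast_profiles() -> dict[str, StageProfile]:
    """Profiles whose only stage contrast is alpha-band coupling.

    Alpha coupling falls monotonically with sleep depth while every other
    band keeps a stage-constant coupling and no bursts — so any stage
    information the classifier uses must come from alpha-band features.
    """
    alpha_by_stage = {"W": 0.85, "N1": 0.60, "N2": 0.35, "N3": 0.10}
    return {
        stage: StageProfile(
            stage=stage,
            coupling_strength={"delta": 0.3, "theta": 0.2,
                               "alpha": alpha_by_stage[stage], "beta": 0.2},
            source_gain=4.0,
        )
        for stage in STAGES
    }


@dataclass
class ClassificationOutcome:
    aggregate: AggregateResult
    features: pd.DataFrame
    subjects: list[str]


def classification_experiment(
    seed: int = 0,
    metric: str = "PLV",
    n_subjects: int = 8,
    n_channels: int = 8,
    fs: float = 100.0,
    segment_length_s: float = 100.0,
    n_splits: int = 5,
    test_n: int = 2,
    coupling_jitter_sd: float = 0.05,
    profiles: dict[str, StageProfile] | None = None,
    config: ClassifierConfig | None = None,
) -> ClassificationOutcome:
    """Subject-wise classification on a synthetic cohort, one metric.

    Defaults are the reduced-scale high-contrast condition: 8 subjects,
    8 channels, 100 s segments at 100 Hz, high-SNR profiles, 5 splits with
    the reduced grid.
    """
    if profiles is None:
        profiles = high_contrast_profiles()
    spec = CohortSpec(
        n_subjects=n_subjects, segment_length_s=segment_length_s, fs=fs,
        n_channels=n_channels, seed=seed, coupling_jitter_sd=coupling_jitter_sd,
    )
    cohort = generate_cohort(profiles, spec)
    features = compute_feature_tables(cohort, metrics=(metric,))[metric]
    subjects = sorted(features["subject"].unique())
    scheme = make_splits(subjects, n_splits=n_splits, test_n=test_n, seed=seed)
    if config is None:
        config = ClassifierConfig(grid_mode="reduced")
    runs = run_classification(features, scheme, config, metric=metric, seed=seed)
    return ClassificationOutcome(
        aggregate=aggregate(runs), features=features, subjects=subjects
    )


def chance_level_accuracy(
    features: pd.DataFrame,
    n_permutations: int = 20,
    seed: int = 0,
    hyperparams: tuple[float, int, int] = (0.1, 100, 3),
    test_n: int = 2,
) -> np.ndarray:
    """Held-out accuracies after destroying the label-feature association.

    Stage labels are permuted across all epochs; for each permutation one
    subject-wise split is evaluated with fixed hyperparameters.  Returns
    the accuracy per permutation; the mean sits at the 4-class chance
    level of 0.25.
    """
    rng = np.random.default_rng(seed)
    subjects = sorted(features["subject"].unique())
    schemes = make_splits(subjects, n_splits=n_permutations, test_n=test_n,
                          seed=seed)
    accs = []
    for k, split in enumerate(schemes.splits):
        shuffled = features.copy()
        shuffled["stage"] = rng.permutation(shuffled["stage"].to_numpy())
        run = fit_evaluate(split, shuffled, hyperparams, metric="shuffled",
                           split_index=k, seed=int(rng.integers(2**31)))
        accs.append(run.accuracy)
    return np.asarray(accs)


def welch_coherence_deviation(
    seed: int = 0,
    fs: float = 250.0,
    duration_s: float = 120.0,
    snr_weight: float = 0.7,
) -> float:
    """Time-domain COH vs band-averaged Welch coherence on stationary input.

    Two channels share a band-passed common source (weight ``snr_weight``)
    plus independent noise of complementary weight.  Returns the absolute
    difference between the Hilbert-based COH (whole-segment average) and
    the magnitude-squared Welch coherence averaged over the alpha band
    (square-rooted to the same scale as COH).
    """
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    sos = sg.butter(4, [ALPHA.low_hz, ALPHA.high_hz], btype="bandpass",
                    fs=fs, output="sos")
    src = sg.sosfiltfilt(sos, rng.standard_normal(n))
    x1 = snr_weight * src + (1 - snr_weight) * sg.sosfiltfilt(
        sos, rng.standard_normal(n))
    x2 = snr_weight * src + (1 - snr_weight) * sg.sosfiltfilt(
        sos, rng.standard_normal(n))
    z1, z2 = sg.hilbert(x1), sg.hilbert(x2)
    coh_time = coh(CrossSpectrumSeries.from_analytic(z1, z2))
    f, cxy = sg.coherence(x1, x2, fs=fs, nperseg=int(4 * fs))
    in_band = (f >= ALPHA.low_hz) & (f <= ALPHA.high_hz)
    coh_welch = float(np.sqrt(np.mean(cxy[in_band])))
    return abs(coh_time - coh_welch)
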