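"""Model/Results surface tying the pipeline together.

:class:`StageConnectivityModel` is built from labelled recordings (real or
synthetic); :meth:`~StageConnectivityModel.fit` runs feature extraction,
the nonparametric stage-difference statistics and (optionally) the
subject-wise classification, returning a :class:`StageConnectivityResults`
that carries the tables, runs and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, DEFAULT_BANDS, BandDefinition
from .classify import (
    AggregateResult,
    ClassifierConfig,
    ClassifierRun,
    aggregate,
    compare_metrics,
    make_splits,
    run_classification,
)
from .connectivity import METRICS, compute_feature_tables, compute_power_table
from .recording import EEGRecording
from .stats import (
    normality_screen,
    stage_difference_analysis,
    stage_tables_from_features,
)
from .synth import CohortSpec, StageProfile, generate_cohort

__all__ = ["StageConnectivityModel", "StageConnectivityResults"]


@dataclass
class StageConnectivityResults:
    """Fitted results: features, stage statistics, classification."""

    feature_tables: dict[str, pd.DataFrame]
    stage_tables: dict[tuple[str, str], pd.DataFrame]
    omnibus: pd.DataFrame
    normality: pd.DataFrame | None = None
    runs: dict[str, list[ClassifierRun]] = field(default_factory=dict)
    aggregates: dict[str, AggregateResult] = field(default_factory=dict)
    accuracy_table: pd.DataFrame | None = None
    anova: tuple[float, float] | None = None
    tukey: pd.DataFrame | None = None
    power_runs: list[ClassifierRun] = field(default_factory=list)

    @property
    def mean_accuracies(self) -> dict[str, float]:
        return {m: a.mean_accuracy for m, a in self.aggregates.items()}

    def summary(self) -> str:
        lines = ["Stage connectivity analysis", "=" * 40]
        n_sig = int(self.omnibus["significant"].sum())
        lines.append(
            f"Omnibus Friedman tests: {len(self.omnibus)} "
            f"(alpha_adj = {self.omnibus.attrs.get('alpha_adjusted', float('nan')):.5f}), "
            f"{n_sig} significant"
        )
        sig = self.omnibus[self.omnibus["significant"]]
        for _, row in sig.iterrows():
            lines.append(
                f"  {row['metric']:>5s} / {row['band']:<5s} "
                f"chi2 = {row['friedman_chi2']:7.2f}  p = {row['p']:.2e}"
            )
        if self.aggregates:
            lines.append("")
            lines.append("Classification (mean accuracy over splits):")
            for m, agg in self.aggregates.items():
                lines.append(
                    f"  {m:>5s}: {agg.mean_accuracy:.3f} "
                    f"(n_splits = {len(agg.accuracies)})"
                )
            if self.anova is not None:
                f_stat, p = self.anova
                lines.append(f"  ANOVA across metrics: F = {f_stat:.2f}, p = {p:.2e}")
        return "\n".join(lines)


class StageConnectivityModel:
    """Phase-coupling sleep-stage analysis of a labelled EEG cohort."""

    def __init__(
        self,
        recordings: list[EEGRecording],
        bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
        metrics: tuple[str, ...] = METRICS,
        window_s: float = 10.0,
        filter_order: int = 6,
    ):
        if not recordings:
            raise ValueError("no recordings given")
        unknown = [m for m in metrics if m not in METRICS]
        if unknown:
            raise ValueError(f"unknown metrics {unknown}; expected subset of {METRICS}")
        self.recordings = recordings
        self.bands = bands
        self.metrics = tuple(metrics)
        self.window_s = window_s
        self.filter_order = filter_order
        self._feature_tables: dict[str, pd.DataFrame] | None = None

    @classmethod
    def from_synthetic(
        cls,
        profiles: dict[str, StageProfile] | None = None,
        spec: CohortSpec | None = None,
        **kwargs,
    ) -> "StageConnectivityModel":
        return cls(generate_cohort(profiles, spec), **kwargs)

    @classmethod
    def from_features(
        cls, feature_tables: dict[str, pd.DataFrame], **kwargs
    ) -> "StageConnectivityModel":
        """Build directly from precomputed per-epoch feature tables."""
        model = cls.__new__(cls)
        model.recordings = []
        model.bands = kwargs.get("bands", DEFAULT_BANDS)
        model.metrics = tuple(feature_tables.keys())
        model.window_s = kwargs.get("window_s", 10.0)
        model.filter_order = kwargs.get("filter_order", 6)
        model._feature_tables = feature_tables
        return model

    @property
    def subjects(self) -> list[str]:
        if self.recordings:
            return sorted({r.subject_id for r in self.recordings})
        table = next(iter(self.feature_tables.values()))
        return sorted(table["subject"].unique())

    @property
    def feature_tables(self) -> dict[str, pd.DataFrame]:
        if self._feature_tables is None:
            self._feature_tables = compute_feature_tables(
                self.recordings, metrics=self.metrics, bands=self.bands,
                window_s=self.window_s, order=self.filter_order,
            )
        return self._feature_tables

    def power_table(self) -> pd.DataFrame:
        return compute_power_table(
            self.recordings, bands=self.bands, window_s=self.window_s,
            order=self.filter_order,
        )

    def fit(
        self,
        classify: bool = True,
        n_splits: int = 30,
        test_n: int = 3,
        classifier_config: ClassifierConfig | None = None,
        alpha: float = 0.05,
        seed: int = 0,
    ) -> StageConnectivityResults:
        """Run statistics (always) and classification (optional)."""
        feature_tables = self.feature_tables
        band_names = tuple(b.name for b in self.bands) if self.bands else BAND_NAMES
        stage_tables = stage_tables_from_features(feature_tables, bands=band_names)
        omnibus = stage_difference_analysis(stage_tables, alpha=alpha)

        # normality screen (gate to the nonparametric route): one test per
        # metric and band on the per-epoch pair-mean values pooled over all
        # subjects and stages
        norm_rows = []
        for metric, table in feature_tables.items():
            for band in band_names:
                cols = [c for c in table.columns if c.startswith(f"{band}_")]
                pooled = table[cols].mean(axis=1).to_numpy()
                try:
                    p = normality_screen(pooled)
                except ValueError:
                    p = np.nan
                norm_rows.append({"metric": metric, "band": band,
                                  "shapiro_p": p})
        normality = pd.DataFrame(norm_rows)

        results = StageConnectivityResults(
            feature_tables=feature_tables,
            stage_tables=stage_tables,
            omnibus=omnibus,
            normality=normality,
        )
        if classify:
            scheme = make_splits(self.subjects, n_splits=n_splits, test_n=test_n,
                                 seed=seed)
            if classifier_config is None:
                classifier_config = ClassifierConfig(grid_mode="reduced")
            for metric in self.metrics:
                runs = run_classification(
                    feature_tables[metric], scheme, classifier_config,
                    metric=metric, seed=seed,
                )
                results.runs[metric] = runs
                results.aggregates[metric] = aggregate(runs, band_order=band_names)
            results.accuracy_table = pd.DataFrame(
                {m: results.aggregates[m].accuracies for m in self.metrics}
            )
            if len(self.metrics) >= 2:
                f_stat, p, tukey = compare_metrics(results.accuracy_table)
                results.anova = (f_stat, p)
                results.tukey = tukey
        return results
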