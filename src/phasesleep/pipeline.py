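"""End-to-end orchestration: synth -> preprocess -> connectivity -> stats -> classify.

A single :class:`PipelineConfig` (YAML- or JSON-serialisable, round-trip
stable) holds every tunable constant; operations never hard-code them.
:func:`run_pipeline` executes all stages, writes CSV/JSON outputs and a
manifest with the config hash and SHA-256 of every file, so identical
configs reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bands import BandDefinition, validate_band_set
from .classify import ClassifierConfig
from .connectivity import METRICS
from .io import load_cohort, save_cohort
from .model import StageConnectivityModel
from .recording import STAGES
from .synth import CohortSpec, default_profiles, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every pipeline constant in one serialisable object."""

    # data source: synthetic cohort spec, or a directory of saved recordings
    cohort: dict = field(default_factory=dict)
    input_dir: str | None = None
    # analysis settings (defaults are the reference analysis settings)
    bands: list = field(
        default_factory=lambda: [
            ["delta", 1.0, 3.5], ["theta", 4.5, 7.0],
            ["alpha", 8.0, 12.0], ["beta", 13.0, 30.0],
        ]
    )
    filter_order: int = 6
    window_s: float = 10.0
    metrics: list = field(default_factory=lambda: list(METRICS))
    alpha: float = 0.05
    classify: bool = True
    n_splits: int = 30
    test_n: int = 3
    grid_mode: str = "reduced"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [m for m in self.metrics if m not in METRICS]
        if unknown:
            raise ValueError(
                f"config field 'metrics' contains unknown names {unknown}; "
                f"expected a subset of {METRICS}"
            )
        validate_band_set(self.band_definitions())

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        return tuple(BandDefinition(str(n), float(lo), float(hi))
                     for n, lo, hi in self.bands)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrap

    # --- data ---------------------------------------------------------
    if config.input_dir is not None:
        recordings = _stage("load")(load_cohort, config.input_dir)
    else:
        spec = CohortSpec(seed=config.seed, **config.cohort)
        recordings = _stage("synth")(generate_cohort, default_profiles(), spec)
        rec_dir = out / "recordings"
        written += save_cohort(recordings, rec_dir)
        written += [p.with_suffix(".json") for p in written if p.suffix == ".npy"]

    # --- features + stats + classification ----------------------------
    model = StageConnectivityModel(
        recordings,
        bands=config.band_definitions(),
        metrics=tuple(config.metrics),
        window_s=config.window_s,
        filter_order=config.filter_order,
    )
    clf_config = ClassifierConfig(grid_mode=config.grid_mode)
    results = _stage("fit")(
        model.fit,
        classify=config.classify,
        n_splits=config.n_splits,
        test_n=config.test_n,
        classifier_config=clf_config,
        alpha=config.alpha,
        seed=config.seed,
    )

    for metric, table in results.feature_tables.items():
        p = out / f"features_{metric}.csv"
        table.to_csv(p, index=False)
        written.append(p)

    stats_path = out / "stage_stats.csv"
    results.omnibus.to_csv(stats_path, index=False)
    written.append(stats_path)

    summary: dict = {
        "package_version": __version__,
        "n_recordings": len(recordings),
        "subjects": model.subjects,
        "stages": list(STAGES),
        "alpha_adjusted": results.omnibus.attrs.get("alpha_adjusted"),
        "n_omnibus_tests": int(results.omnibus.attrs.get("n_tests", 0)),
    }
    if config.classify:
        acc_path = out / "accuracies.csv"
        results.accuracy_table.to_csv(acc_path, index=False)
        written.append(acc_path)
        for metric, agg in results.aggregates.items():
            cp = out / f"confusion_{metric}.csv"
            pd.DataFrame(agg.mean_confusion, index=list(STAGES),
                         columns=list(STAGES)).to_csv(cp)
            written.append(cp)
            ip = out / f"importances_{metric}.csv"
            first = results.feature_tables[metric]
            feat_cols = [c for c in first.columns
                         if c not in ("subject", "stage", "epoch")]
            pd.Series(agg.mean_importances, index=feat_cols,
                      name="importance").to_csv(ip)
            written.append(ip)
        summary["mean_accuracies"] = results.mean_accuracies
        if results.anova is not None:
            summary["anova_F"], summary["anova_p"] = results.anova

    sum_path = out / "summary.json"
    sum_path.write_text(json.dumps(summary, indent=1, default=str))
    written.append(sum_path)

    manifest = {
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "seed": config.seed,
        "outputs": {str(p.relative_to(out)): _sha256(p)
                    for p in sorted(set(written)) if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
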