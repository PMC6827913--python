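"""End-to-end orchestration of the two experiments.

``run_machine_experiment`` reproduces the machine-observer study:
generate the synthetic edge dataset, extract the six image properties,
and for every feature subset and stratum (per size and pooled; color vs
luminance-only condition) fit the linear discriminant, evaluate d', and
attach parametric-bootstrap confidence intervals.

``run_human_analysis`` reproduces the psychophysical analysis: read
trial-level responses, compute per-observer hit/false-alarm rates, d'
and bias, and aggregate across observers.

Both are deterministic given (config, seed): every RNG is derived from
the master seed, and tables are written with a fixed float format.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import CHROMATIC_FEATURES, FEATURE_NAMES, LUMINANCE_FEATURES, feature_table
from .lda import evaluate, fit_lda, incremental_curves, parametric_bootstrap, rank_features
from .sdt import aggregate_group, read_trials, summarize_observers
from .synth import GeneratorParams, generate_dataset

__all__ = ["ExperimentConfig", "run_machine_experiment", "run_human_analysis"]

_FLOAT_FMT = "%.10g"

#: Fig-8-style default subsets: the full luminance classifier and its color
#: augmentations.
DEFAULT_SUBSETS = (
    LUMINANCE_FEATURES,
    LUMINANCE_FEATURES + ("d_LM",),
    LUMINANCE_FEATURES + ("d_Sop",),
    LUMINANCE_FEATURES + CHROMATIC_FEATURES,
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a machine-observer run."""

    n_per_class_per_size: int = 50
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    feature_subsets: tuple[tuple[str, ...], ...] = DEFAULT_SUBSETS
    protocol: str = "resub"
    n_boot: int = 1000
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        for subset in self.feature_subsets:
            unknown = [f for f in subset if f not in FEATURE_NAMES]
            if unknown:
                raise ValueError(f"unknown feature names in config: {unknown}")
        if self.protocol not in ("resub", "kfold"):
            raise ValueError(f"unknown protocol {self.protocol!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = dataclasses.asdict(self.generator)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            gen = dict(d["generator"])
            for key in ("sizes", "shadow_attenuation", "illuminant"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            d["generator"] = GeneratorParams(**gen)
        if "feature_subsets" in d:
            d["feature_subsets"] = tuple(tuple(s) for s in d["feature_subsets"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _strata(table: pd.DataFrame):
    sizes = ["all"] + sorted(table["size_class"].unique())
    for condition in sorted(table["condition"].unique()):
        for size in sizes:
            sel = table["condition"] == condition
            if size != "all":
                sel &= table["size_class"] == size
            yield condition, size, table[sel]


def run_machine_experiment(config: ExperimentConfig, dataset=None):
    """Run the full machine-observer experiment.

    Returns a dict with the report DataFrame (one row per feature subset x
    condition x size stratum, with d' and bootstrap CI), the individual
    feature ranking per condition, the feature table, and a provenance
    manifest.  If ``config.out_dir`` is set, report.csv, ranking.csv,
    features.csv and manifest.json are written there.
    """
    config.validate()
    if dataset is None:
        dataset = generate_dataset(
            config.n_per_class_per_size, config.generator, seed=config.seed
        )
    table = feature_table(dataset.patches)

    ss = np.random.SeedSequence([config.seed, 0xB007])
    rows = []
    rank_rows = []
    for condition, size, sub in _strata(table):
        X_all = sub[list(FEATURE_NAMES)].to_numpy()
        y = sub["category"].to_numpy()
        ranking = rank_features(X_all, y, FEATURE_NAMES, protocol=config.protocol)
        ranking.insert(0, "condition", condition)
        ranking.insert(1, "size_class", size)
        rank_rows.append(ranking)
        for subset in config.feature_subsets:
            X = sub[list(subset)].to_numpy()
            ci = parametric_bootstrap(
                X, y, n_boot=config.n_boot,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                protocol=config.protocol,
            )
            cm = evaluate(None, X, y, protocol=config.protocol)
            rows.append(
                {
                    "feature_set": "+".join(subset),
                    "condition": condition,
                    "size_class": size,
                    "protocol": config.protocol,
                    "n": len(sub),
                    "pH": cm.pH,
                    "pFA": cm.pFA,
                    "dprime": cm.dprime,
                    "ci_lo": ci.lo,
                    "ci_hi": ci.hi,
                    "correction_applied": cm.correction_applied,
                }
            )
    report = pd.DataFrame(rows)
    ranking = pd.concat(rank_rows, ignore_index=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_patches": len(dataset.patches),
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.csv", index=False, float_format=_FLOAT_FMT)
        ranking.to_csv(out / "ranking.csv", index=False, float_format=_FLOAT_FMT)
        table.to_csv(out / "features.csv", index=False, float_format=_FLOAT_FMT)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "report": report,
        "ranking": ranking,
        "features": table,
        "dataset": dataset,
        "manifest": manifest,
    }


def run_incremental_analysis(config: ExperimentConfig, dataset=None, condition="Col"):
    """Incremental color-augmentation curves (d' vs number of properties)."""
    config.validate()
    if dataset is None:
        dataset = generate_dataset(
            config.n_per_class_per_size, config.generator, seed=config.seed
        )
    table = feature_table(dataset.patches)
    sub = table[table["condition"] == condition]
    return incremental_curves(
        sub[list(FEATURE_NAMES)].to_numpy(),
        sub["category"].to_numpy(),
        FEATURE_NAMES,
        n_boot=config.n_boot,
        seed=config.seed,
        protocol=config.protocol,
    )


def run_human_analysis(trials, out_dir=None):
    """Per-observer and group SDT tables from trial-level responses.

    ``trials`` may be a path to a CSV in the trial schema or a DataFrame.
    Writes observers.csv, group.csv and paired_diff.csv when ``out_dir``
    is given.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = read_trials(trials)
    per_observer = summarize_observers(trials)
    n_obs = per_observer["observer_id"].nunique()
    if n_obs >= 2:
        group, paired = aggregate_group(per_observer)
    else:
        group = (
            per_observer.groupby(["condition", "size_class"], sort=True)["dprime"]
            .agg(mean_dprime="mean")
            .reset_index()
        )
        group["sem"] = np.nan
        group["n"] = 1
        paired = pd.DataFrame(
            columns=["size_class", "mean_diff", "ci_lo", "ci_hi", "n_observers"]
        )
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_observer.to_csv(out / "observers.csv", index=False, float_format=_FLOAT_FMT)
        group.to_csv(out / "group.csv", index=False, float_format=_FLOAT_FMT)
        paired.to_csv(out / "paired_diff.csv", index=False, float_format=_FLOAT_FMT)
    return {"observers": per_observer, "group": group, "paired": paired}
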