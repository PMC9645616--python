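"""End-to-end orchestration: simulate/ingest -> characterize -> classify ->
meta-regress -> importance -> reports.

One *simulation run* turns a dataset collection into a report bundle: the
characteristic table, the per-dataset error profiles, the meta-dataset, one
fitted meta-regressor per (regression model x classifier target) pair with
hold-out R-squared, the rf tuning tables and the importance rankings. A
*study* runs several simulations and adds cross-simulation products: the
Spearman correlation matrix of linear-model importance rankings and the
pooled comparison of regression models (medians plus a paired Wilcoxon
signed-rank test of rf vs linear).

Everything is deterministic given (configuration, seed); all reports are
plain TSV plus one JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .classify import CLASSIFIER_NAMES, default_specs, error_profile
from .importance import ImportanceRanking, lm_importance, ranking_correlation, rf_importance
from .metafeatures import DatasetCharacterizer
from .metaregress import (
    MODEL_NAMES,
    MetaDataset,
    assemble_meta_dataset,
    evaluate_r2,
    make_regressor,
    split_holdout,
)
from .simdata import (
    SimulationConfig,
    generate_collection,
    generate_study_collection,
    simulation_registry,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "SimulationBundle",
    "run_single_simulation",
    "run_simulation_study",
    "run_usecase",
    "compare_regression_models",
]

TTEST_PREFIXES = ("tt_", "pthr", "npth")


@dataclass
class ExperimentConfig:
    """Configuration of a full experiment.

    ``mode`` is 'simulation' (names from the S1-S9 registry) or 'microarray'
    (paths to ingested LabeledDataset TSVs). Scale knobs (dataset count,
    ensemble sizes) are explicit so studies can be run at reduced size.
    """

    mode: str = "simulation"
    simulations: tuple[str, ...] = tuple(f"S{i}" for i in range(1, 10))
    dataset_paths: tuple[str, ...] = ()
    num_datasets: int = 300
    holdout_fraction: float = 0.25
    seed: int = 0
    feature_subset: str = "all"          # 'all' or 'ttest_only'
    out_dir: str | None = None
    classifier_trees: int = 500
    meta_rf_trees: int = 500
    tau: float = 0.7
    collection: str = "per_part"

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("simulations", "dataset_paths"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulationBundle:
    """All Step I-III products of one simulation."""

    name: str
    meta: MetaDataset
    holdout_r2: pd.DataFrame                 # rows = classifiers, cols = models
    tuning_tables: dict[str, pd.DataFrame]   # rf tuning per classifier target
    importances: dict[tuple[str, str], ImportanceRanking]
    best_cv_r2: dict[str, float]             # rf training-CV R2 per target

    def mean_importance(self, model: str = "linear") -> pd.Series:
        """Importance averaged over the four classifier targets."""
        mats = [
            self.importances[(model, c)].scores
            for c in CLASSIFIER_NAMES
            if (model, c) in self.importances
        ]
        return pd.concat(mats, axis=1).mean(axis=1)


def _subset_columns(X: pd.DataFrame, subset: str) -> pd.DataFrame:
    if subset == "all":
        return X
    if subset == "ttest_only":
        keep = [c for c in X.columns if c.startswith(TTEST_PREFIXES)]
        return X[keep]
    raise ValueError(f"unknown feature subset {subset!r}")


def build_meta_dataset(
    datasets,
    seed: int = 0,
    classifier_trees: int = 500,
    tau: float = 0.7,
    out_dir: Path | None = None,
    label: str = "collection",
) -> MetaDataset:
    """Characterize a dataset collection and measure its error profiles."""
    characterizer = DatasetCharacterizer(tau=tau)
    vectors = characterizer.transform(datasets)
    specs = default_specs(rf_trees=classifier_trees)
    profiles = [
        error_profile(ds, seed=seed + i, specs=specs)
        for i, ds in enumerate(datasets)
    ]
    meta = assemble_meta_dataset(vectors, profiles)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        vectors.to_csv(out_dir / f"characteristics_{label}.tsv", sep="\t",
                       index_label="dataset")
        pd.concat([p.to_frame() for p in profiles]).to_csv(
            out_dir / f"error_profiles_{label}.tsv", sep="\t", index=False
        )
        meta.to_tsv(out_dir / f"meta_{label}.tsv")
    return meta


def run_single_simulation(
    config: SimulationConfig,
    seed: int = 0,
    num_datasets: int | None = None,
    holdout_fraction: float = 0.25,
    classifier_trees: int = 500,
    meta_rf_trees: int = 500,
    tau: float = 0.7,
    out_dir: Path | None = None,
    collection: str = "per_part",
) -> SimulationBundle:
    """Full pipeline for one simulation configuration.

    ``collection`` selects the study design: 'per_part' (default) generates
    one sub-collection per configuration part — the heterogeneous design
    whose error spread meta-regression is meant to predict; 'combined'
    concatenates all parts into each dataset. With 'per_part',
    ``num_datasets`` counts datasets per part.
    """
    if collection == "per_part":
        datasets = generate_study_collection(config, num_datasets_per_part=num_datasets)
    elif collection == "combined":
        datasets = generate_collection(config, num_datasets=num_datasets)
    else:
        raise ValueError(f"unknown collection mode {collection!r}")
    meta = build_meta_dataset(
        datasets,
        seed=seed,
        classifier_trees=classifier_trees,
        tau=tau,
        out_dir=out_dir,
        label=config.name,
    )
    train, test = split_holdout(meta, fraction=holdout_fraction, seed=seed)

    holdout = pd.DataFrame(index=list(CLASSIFIER_NAMES), columns=list(MODEL_NAMES),
                           dtype=float)
    tuning_tables: dict[str, pd.DataFrame] = {}
    importances: dict[tuple[str, str], ImportanceRanking] = {}
    best_cv: dict[str, float] = {}
    for target in CLASSIFIER_NAMES:
        y_tr = train.Y[f"error_{target}"].to_numpy()
        y_te = test.Y[f"error_{target}"].to_numpy()
        for model in MODEL_NAMES:
            reg = make_regressor(model, seed=seed, rf_trees=meta_rf_trees)
            reg.fit(train.X, y_tr)
            holdout.loc[target, model] = evaluate_r2(reg, test.X, y_te)
            if model == "rf":
                tuning_tables[target] = reg.tuning_table_
                best_cv[target] = reg.best_cv_r2_
                importances[("rf", target)] = rf_importance(
                    reg, train.X.columns, target=target
                )
            elif model == "linear":
                importances[("linear", target)] = lm_importance(
                    reg, train.X.columns, target=target
                )
    bundle = SimulationBundle(
        name=config.name,
        meta=meta,
        holdout_r2=holdout,
        tuning_tables=tuning_tables,
        importances=importances,
        best_cv_r2=best_cv,
    )
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: SimulationBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.holdout_r2.to_csv(out_dir / f"holdout_r2_{bundle.name}.tsv", sep="\t",
                             index_label="classifier")
    for target, table in bundle.tuning_tables.items():
        table.to_csv(out_dir / f"tuning_rf_{target}_{bundle.name}.tsv", sep="\t",
                     index=False)
    for (model, target), ranking in bundle.importances.items():
        ranking.to_frame().to_csv(
            out_dir / f"importance_{model}_{target}_{bundle.name}.tsv",
            sep="\t", index=False,
        )


def run_simulation_study(cfg: ExperimentConfig) -> dict:
    """Run all configured simulations and the cross-simulation comparisons."""
    registry = simulation_registry(num_datasets=cfg.num_datasets, seed=cfg.seed)
    unknown = set(cfg.simulations) - set(registry)
    if unknown:
        raise ValueError(f"unregistered simulations: {sorted(unknown)}")
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None

    bundles: dict[str, SimulationBundle] = {}
    for i, name in enumerate(cfg.simulations):
        logger.info("running simulation %s", name)
        bundles[name] = run_single_simulation(
            registry[name],
            seed=cfg.seed + i,
            holdout_fraction=cfg.holdout_fraction,
            classifier_trees=cfg.classifier_trees,
            meta_rf_trees=cfg.meta_rf_trees,
            tau=cfg.tau,
            out_dir=out_dir,
            collection=cfg.collection,
        )

    results: dict = {"bundles": bundles}
    if len(bundles) >= 2:
        # zero-variance drops can differ per simulation; compare rankings on
        # the meta-features common to all of them
        vectors = {name: b.mean_importance("linear") for name, b in bundles.items()}
        common = sorted(set.intersection(*(set(v.index) for v in vectors.values())))
        rank_corr = ranking_correlation(
            {name: v[common] for name, v in vectors.items()}
        )
        comparison = compare_regression_models(
            {name: b.holdout_r2 for name, b in bundles.items()}
        )
        results["ranking_correlation"] = rank_corr
        results["model_comparison"] = comparison
        if out_dir is not None:
            rank_corr.to_csv(out_dir / "ranking_correlation.tsv", sep="\t",
                             index_label="simulation")
            comparison.to_csv(out_dir / "model_comparison.tsv", sep="\t",
                              index_label="model")
    if out_dir is not None:
        manifest = {
            "perfcast_version": __version__,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(cfg).items()
            },
        }
        (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def compare_regression_models(holdout_tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pooled hold-out R-squared distribution per regression model.

    Rows = regression models, columns: median, mean, n, and for rf the
    paired Wilcoxon signed-rank p-value against the linear model over
    matched (simulation x classifier-target) pairs.
    """
    pooled = {m: [] for m in MODEL_NAMES}
    for table in holdout_tables.values():
        for m in MODEL_NAMES:
            pooled[m].extend(table[m].tolist())
    rows = {}
    for m in MODEL_NAMES:
        vals = np.asarray(pooled[m], dtype=float)
        rows[m] = {"median_R2": float(np.median(vals)),
                   "mean_R2": float(np.mean(vals)),
                   "n": len(vals)}
    diffs = np.asarray(pooled["rf"]) - np.asarray(pooled["linear"])
    if np.allclose(diffs, 0.0):
        p_value = 1.0
    else:
        p_value = float(stats.wilcoxon(diffs).pvalue)
    out = pd.DataFrame(rows).T
    out["wilcoxon_p_vs_linear"] = [np.nan, p_value, np.nan]
    out.index.name = "model"
    return out


def run_usecase(
    meta: MetaDataset,
    n_test: int = 8,
    seed: int = 0,
    targets: tuple[str, ...] = ("RF", "SVM"),
    meta_rf_trees: int = 500,
) -> dict:
    """Leave-datasets-out protocol: predict errors of held-out datasets.

    Fits the rf meta-regression twice — on all meta-features and on the
    t-test-based subset (names prefixed tt_/pthr/npth) — and reports
    observed vs predicted errors (clipped to [0, 1]) plus the RMSE over the
    held-out datasets for each setting.
    """
    if meta.n < 10:
        raise ValueError("use case needs at least 10 datasets")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(meta.n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    train = MetaDataset(meta.X.iloc[train_idx], meta.Y.iloc[train_idx])
    test = MetaDataset(meta.X.iloc[test_idx], meta.Y.iloc[test_idx])

    tables: dict[str, pd.DataFrame] = {}
    rmse: dict[tuple[str, str], float] = {}
    for target in targets:
        y_tr = train.Y[f"error_{target}"].to_numpy()
        y_te = test.Y[f"error_{target}"].to_numpy()
        preds = {}
        for subset in ("all", "ttest_only"):
            X_tr = _subset_columns(train.X, subset)
            X_te = _subset_columns(test.X, subset)
            reg = make_regressor("rf", seed=seed, rf_trees=meta_rf_trees)
            reg.fit(X_tr, y_tr)
            pred = np.clip(reg.predict(X_te), 0.0, 1.0)
            preds[subset] = pred
            rmse[(target, subset)] = float(np.sqrt(np.mean((pred - y_te) ** 2)))
        tables[target] = pd.DataFrame(
            {
                "dataset": test.X.index,
                "observed": y_te,
                "predicted_all": preds["all"],
                "predicted_ttest_only": preds["ttest_only"],
            }
        )
    return {"predictions": tables, "rmse": rmse,
            "train_ids": list(train.X.index), "test_ids": list(test.X.index)}
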