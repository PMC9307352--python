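"""Configuration-driven orchestration of the full classification pipeline.

A :class:`PipelineConfig` describes one experiment cell: data source
(synthetic config or a matrix file), gene-selection mode, feature-extraction
method and dimensionality, optional correlation-distance feature selection,
classifier and hyperparameters, and the CV layout.  :func:`run_pipeline`
executes simulate/load -> select genes -> extract -> (select features) ->
cross-validate and writes deterministic metric artifacts;
:func:`run_grid` sweeps the (method x classifier x selection) grid and
returns one table row per cell.

All model fitting happens inside each training fold: per-fold ANOVA gene
selection, per-fold FCM/SDA fitting, per-fold feature selection and
classifier training.  One master seed governs the run; every stochastic
stage derives its substream from (seed, stage label, fold).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import classification as clf
from . import feature_extraction as fx
from .datasets import (
    LabeledExpressionMatrix,
    SyntheticConfig,
    generate_dataset,
    read_matrix,
    subset_genes,
)
from .errors import ConfigurationError
from .evaluation import (
    ConfusionMatrix,
    CVResult,
    FoldOutcome,
    MetricsReport,
    metrics_from_confusion,
    mse_scores,
    stratified_folds,
    stratified_kfold_cv,
)
from .feature_selection import DEFAULT_K, select_by_correlation_distance
from .gene_selection import DEFAULT_FRACTION, anova_volcano, select_prominent

__all__ = ["PipelineConfig", "run_pipeline", "run_grid", "derive_seed", "GRID_COLUMNS"]

logger = logging.getLogger("ovaclass")

GRID_COLUMNS = [
    "method", "classifier", "selection", "tp", "tn", "fp", "fn", "mse",
    "accuracy", "precision", "f1", "mcc", "fm", "error_rate", "jaccard", "csi",
]


def derive_seed(master: int, *labels) -> int:
    """Stable substream seed below 2^31 from a master seed and stage labels."""
    text = ":".join([str(master), *map(str, labels)])
    return zlib.crc32(text.encode()) % (2**31)


@dataclass
class PipelineConfig:
    """One experiment cell plus the shared pipeline settings."""

    # data source: either a synthetic config or an input matrix path
    synthetic: SyntheticConfig | None = None
    input_path: str | None = None
    labels_path: str | None = None
    # gene selection
    gene_mode: str = "fraction_by_p"
    gene_fraction: float = DEFAULT_FRACTION
    gene_k: int | None = None
    gene_p_max: float = 0.05
    gene_fc_min: float = 1.0
    # feature extraction
    method: str = "FCM"
    n_features: int | None = None  # None -> study-scale ratio
    fcm_fuzzifier: float = 2.0
    fcm_tol: float = 1e-5
    fcm_max_iter: int = 300
    sda_lambda: float = 1.0
    # feature selection
    selection: bool = False
    selection_k: int = DEFAULT_K
    selection_method: str = "pearson_distance"
    # classifier
    classifier: str = "LR"
    classifier_params: dict = field(default_factory=dict)
    encoding: clf.TargetEncoding = field(default_factory=clf.TargetEncoding)
    # cross-validation
    cv_k: int = 10
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None and self.input_path is None:
            self.synthetic = SyntheticConfig(seed=derive_seed(self.seed, "data"))
        self.method = self.method.upper()
        if self.method not in fx.METHODS:
            raise ConfigurationError(
                f"method must be one of {fx.METHODS}, got {self.method!r}"
            )
        self.classifier = self.classifier.upper()
        if self.classifier not in clf.ALGORITHMS:
            raise ConfigurationError(
                f"classifier must be one of {clf.ALGORITHMS}, got {self.classifier!r}"
            )
        if self.input_path is not None and not Path(self.input_path).exists():
            raise ConfigurationError(f"input_path does not exist: {self.input_path}")

    # -- data -------------------------------------------------------------
    def load_data(self) -> LabeledExpressionMatrix:
        if self.input_path is not None:
            return read_matrix(self.input_path, self.labels_path)
        return generate_dataset(self.synthetic)

    # -- per-fold pipeline -------------------------------------------------
    def _select_genes(
        self, data: LabeledExpressionMatrix, train_idx: np.ndarray
    ) -> np.ndarray:
        train = LabeledExpressionMatrix(
            values=data.values[:, train_idx],
            gene_ids=list(data.gene_ids),
            sample_ids=[data.sample_ids[i] for i in train_idx],
            labels=data.labels[train_idx],
        )
        stats = anova_volcano(train)
        selected = select_prominent(
            stats,
            self.gene_mode,
            k=self.gene_k,
            fraction=self.gene_fraction,
            p_max=self.gene_p_max,
            fc_min=self.gene_fc_min,
        )
        return selected.selected_idx

    def _extract(
        self,
        values: np.ndarray,
        labels: np.ndarray,
        train_idx: np.ndarray,
        fold_seed: int,
    ) -> fx.FeatureMatrix:
        return fx.extract_features(
            self.method,
            values,
            labels,
            train_idx=train_idx,
            n_features=self.n_features,
            seed=derive_seed(fold_seed, "fcm"),
            fcm_params={
                "fuzzifier": self.fcm_fuzzifier,
                "tol": self.fcm_tol,
                "max_iter": self.fcm_max_iter,
            }
            if self.method == "FCM"
            else None,
            lambda_=self.sda_lambda,
        )

    def run_fold(
        self,
        data: LabeledExpressionMatrix,
        train_idx: np.ndarray,
        test_idx: np.ndarray,
        seed: int,
    ) -> FoldOutcome:
        gene_idx = self._select_genes(data, train_idx)
        sub = subset_genes(data, gene_idx)
        feats = self._extract(sub.values, sub.labels, train_idx, seed)
        X_train = feats.values[train_idx]
        X_test = feats.values[test_idx]
        if self.selection:
            k = min(self.selection_k, X_train.shape[1])
            kept = select_by_correlation_distance(
                X_train, data.labels[train_idx], k=k, method=self.selection_method
            ).kept_idx
            X_train = X_train[:, kept]
            X_test = X_test[:, kept]
        model = clf.fit(
            self.classifier,
            X_train,
            data.labels[train_idx],
            encoding=self.encoding,
            seed=derive_seed(seed, "clf"),
            **self.classifier_params,
        )
        scores, pred = model.predict(X_test)
        return FoldOutcome(
            scores=scores,
            pred_labels=pred,
            true_labels=data.labels[test_idx],
            targets=clf.encode_targets(data.labels[test_idx], self.encoding),
        )


def _result_row(
    method: str, classifier: str, selection: bool, result: CVResult
) -> dict:
    cm = result.pooled_confusion
    rounded = result.pooled_metrics.rounded()
    row = {
        "method": method,
        "classifier": classifier,
        "selection": bool(selection),
        "tp": cm.tp, "tn": cm.tn, "fp": cm.fp, "fn": cm.fn,
        "mse": result.mse,
    }
    for col in ("accuracy", "precision", "f1", "mcc", "fm", "error_rate", "jaccard", "csi"):
        row[col] = rounded[col]
    return row


def _write_artifacts(outdir: Path, config: PipelineConfig, rows: list[dict],
                     results: list[CVResult]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rows, columns=GRID_COLUMNS)
    df.to_csv(outdir / "metrics.csv", index=False, float_format="%.6g")
    payload = {
        "config": _config_dict(config),
        "rows": rows,
        "folds": [
            {
                "cell": {k: rows[i][k] for k in ("method", "classifier", "selection")},
                "fold_confusions": [
                    {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
                    for c in res.fold_confusions
                ],
            }
            for i, res in enumerate(results)
        ],
    }
    (outdir / "metrics.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (outdir / "run.log").write_text(
        "ovaclass run\nconfig:\n"
        + json.dumps(_config_dict(config), indent=2, sort_keys=True)
        + f"\nseed: {config.seed}\n"
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    # artifacts must be byte-identical for identical experiment configs;
    # where they are written is not part of the experiment
    d.pop("output_dir", None)
    d["encoding"] = {
        "t_cancer": config.encoding.t_cancer,
        "t_normal": config.encoding.t_normal,
        "threshold": config.encoding.threshold,
    }
    return d


def run_pipeline(config: PipelineConfig, data: LabeledExpressionMatrix | None = None) -> CVResult:
    """Run one (method x classifier x selection) cell end to end.

    Writes ``metrics.csv``, ``metrics.json`` and ``run.log`` to
    ``config.output_dir`` when set; identical configs produce byte-identical
    metric files.
    """
    if data is None:
        data = config.load_data()
    logger.info(
        "pipeline: %s + %s (selection=%s) on %d genes x %d samples",
        config.method, config.classifier, config.selection,
        data.n_genes, data.n_samples,
    )
    result = stratified_kfold_cv(config, data, k=config.cv_k, seed=config.seed)
    if config.output_dir:
        rows = [_result_row(config.method, config.classifier, config.selection, result)]
        _write_artifacts(Path(config.output_dir), config, rows, [result])
    return result


def run_grid(
    config: PipelineConfig,
    methods: Sequence[str] | None = None,
    classifiers: Sequence[str] | None = None,
    selection: Sequence[bool] = (False, True),
    data: LabeledExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Sweep the experiment grid, sharing per-fold work across classifiers.

    Gene selection runs once per fold, feature extraction once per
    (fold, method), and feature selection once per (fold, method); the six
    classifiers then reuse those features.  Returns one row per cell in the
    published-table layout (the full default grid is 5 x 6 x 2 = 60 rows).
    """
    methods = [m.upper() for m in (methods or fx.METHODS)]
    classifiers = [c.upper() for c in (classifiers or clf.ALGORITHMS)]
    if data is None:
        data = config.load_data()
    folds = stratified_folds(data.labels, config.cv_k, config.seed)

    cells: dict[tuple, dict] = {}
    for m in methods:
        for c in classifiers:
            for sel in selection:
                cells[(m, c, sel)] = {"confusions": [], "mses": []}

    for fold_no, (train_idx, test_idx) in enumerate(folds):
        fold_seed = config.seed + fold_no
        gene_idx = config._select_genes(data, train_idx)
        sub = subset_genes(data, gene_idx)
        y_train = data.labels[train_idx]
        y_test = data.labels[test_idx]
        targets_test = clf.encode_targets(y_test, config.encoding)
        for m in methods:
            mc = replace(config, method=m, classifier=classifiers[0])
            feats = mc._extract(sub.values, sub.labels, train_idx, fold_seed)
            for sel in selection:
                X_train = feats.values[train_idx]
                X_test = feats.values[test_idx]
                if sel:
                    k = min(config.selection_k, X_train.shape[1])
                    kept = select_by_correlation_distance(
                        X_train, y_train, k=k, method=config.selection_method
                    ).kept_idx
                    X_train = X_train[:, kept]
                    X_test = X_test[:, kept]
                for c in classifiers:
                    model = clf.fit(
                        c, X_train, y_train,
                        encoding=config.encoding,
                        seed=derive_seed(fold_seed, "clf", m, c, sel),
                        **(config.classifier_params if c == config.classifier else {}),
                    )
                    scores, pred = model.predict(X_test)
                    cells[(m, c, sel)]["confusions"].append(
                        ConfusionMatrix.from_labels(y_test, pred)
                    )
                    cells[(m, c, sel)]["mses"].append(mse_scores(scores, targets_test))

    rows: list[dict] = []
    for (m, c, sel), acc in cells.items():
        pooled = acc["confusions"][0]
        for cm in acc["confusions"][1:]:
            pooled = pooled + cm
        mse = float(np.mean(acc["mses"]))
        report: MetricsReport = metrics_from_confusion(pooled, mse=mse)
        rounded = report.rounded()
        row = {
            "method": m, "classifier": c, "selection": bool(sel),
            "tp": pooled.tp, "tn": pooled.tn, "fp": pooled.fp, "fn": pooled.fn,
            "mse": mse,
        }
        for col in ("accuracy", "precision", "f1", "mcc", "fm", "error_rate",
                    "jaccard", "csi"):
            row[col] = rounded[col]
        rows.append(row)
    df = pd.DataFrame(rows, columns=GRID_COLUMNS)
    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "grid.csv", index=False, float_format="%.6g")
    return df
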