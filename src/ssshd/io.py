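"""Dataset loading, the selection workflow, and run manifests.

Input tables are delimited text (CSV/TSV) with a header row; one column holds
the class label and every other column must be numeric.  Whatever the original
label values, the rarer one is mapped to +1 (positive/minority) and the
commoner to -1, and the mapping is recorded on the dataset.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, baselines, core, metrics, resampling, sparse_svm
from .exceptions import InvalidInputError, ParameterError

__all__ = [
    "Dataset",
    "read_dataset",
    "imbalance_ratio",
    "run_selection_workflow",
    "write_manifest",
]

log = logging.getLogger("ssshd")

FILTER_METHODS = {
    "fisher": baselines.fisher_score,
    "aucroc": baselines.aucroc_filter,
    "aucprc": baselines.aucprc_filter,
}
METHODS = ("ssshd", "fisher", "relief", "aucroc", "aucprc")


@dataclass
class Dataset:
    """Numeric feature matrix with +-1 labels (minority mapped to +1)."""

    matrix: np.ndarray
    feature_names: list
    labels: np.ndarray
    label_mapping: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.feature_names) != len(set(self.feature_names)):
            raise InvalidInputError("feature names must be unique")
        if self.matrix.shape != (len(self.labels), len(self.feature_names)):
            raise InvalidInputError("matrix shape does not match names/labels")

    @property
    def n_minority(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_majority(self) -> int:
        return int(np.sum(self.labels == -1))


def read_dataset(path, label_column: str = "label", delimiter: str | None = None) -> Dataset:
    """Parse a delimited table into a Dataset.

    The delimiter is sniffed from the extension (.tsv -> tab, otherwise
    comma) unless given.  The minority class is detected by count and mapped
    to +1; exact 50/50 splits map the label that sorts first to +1.  Files
    with missing values, non-numeric feature cells or a constant label column
    are rejected with the offending row/column named.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=delimiter)
    if label_column not in df.columns:
        raise InvalidInputError(
            f"label column {label_column!r} not found in {path.name}; "
            f"columns are {list(df.columns)}"
        )
    raw_labels = df[label_column]
    feat = df.drop(columns=[label_column])
    for col in feat.columns:
        numeric = pd.to_numeric(feat[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise InvalidInputError(
                f"non-numeric or missing value in column {col!r}, row {row} "
                f"of {path.name}: {feat[col].iloc[row]!r}"
            )
        feat[col] = numeric
    counts = raw_labels.value_counts()
    if len(counts) != 2:
        raise InvalidInputError(
            f"label column must contain exactly 2 classes, found {len(counts)}"
        )
    # minority -> +1; ties broken by sort order for determinism
    ordered = sorted(counts.index, key=lambda v: (counts[v], str(v)))
    minority, majority = ordered[0], ordered[1]
    mapping = {minority: 1, majority: -1}
    labels = raw_labels.map(mapping).to_numpy()
    return Dataset(
        matrix=feat.to_numpy(dtype=float),
        feature_names=list(feat.columns),
        labels=labels,
        label_mapping={str(k): int(v) for k, v in mapping.items()},
    )


def imbalance_ratio(d: Dataset) -> float:
    """Majority over minority count, rounded to 2 decimals."""
    if d.n_minority == 0 or d.n_majority == 0:
        raise InvalidInputError("both classes must be present")
    return round(d.n_majority / d.n_minority, 2)


def write_manifest(path, config: dict) -> None:
    """Persist a machine-readable record sufficient to reproduce a run."""
    manifest = dict(config)
    manifest["versions"] = {
        "ssshd": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def _rank_features(ds: Dataset, method: str, cfg: dict, seed):
    if method == "ssshd":
        grid = None
        grid_cfg = cfg.get("grid") or {}
        if grid_cfg:
            grid = core.TuningGrid.default(ds.matrix, ds.labels, **grid_cfg)
        stab = cfg.get("stability") or {}
        res = core.stability_select(
            ds.matrix,
            ds.labels,
            grid=grid,
            K=int(stab.get("runs", 100)),
            fraction=float(stab.get("fraction", 0.5)),
            seed=seed,
        )
        return core.rank_features(res), res.frequencies
    if method == "relief":
        scores = baselines.relief_weights(ds.matrix, ds.labels, seed=seed)
    elif method in FILTER_METHODS:
        scores = FILTER_METHODS[method](ds.matrix, ds.labels)
    else:
        raise ParameterError(f"unknown method {method!r}; choose from {METHODS}")
    return scores.ranking(), scores.values


def _cv_metrics(X, y, seed, protocol: str, n_folds: int = 5):
    """Pooled out-of-fold metrics of a ridge-SVM on the given features."""
    n = len(y)
    if protocol == "loocv":
        splits = resampling.loocv_indices(n)
    else:
        plan = resampling.stratified_kfold(y, n_folds, seed=seed)
        splits = list(plan.split())
    scores = np.empty(n)
    lam = 1.0
    for train, test in splits:
        if len(np.unique(y[train])) < 2:
            raise InvalidInputError("a training fold lost one class entirely")
        model = sparse_svm.fit(
            X[train], y[train],
            sparse_svm.PenaltyConfig(lam=lam, alpha=0.0),
            tol=1e-5,
        )
        scores[test] = sparse_svm.decision_scores(model, X[test])
    pred = np.where(scores > 0, 1, -1)
    r = metrics.rates(metrics.confusion(y, pred))
    return {
        "tpr": r["tpr"],
        "g_mean": r["g_mean"],
        "f_measure": r["f_measure"],
        "aucroc": metrics.auc_roc_lower_trapezoid(scores, y),
        "precision": r["precision"],
    }


def run_selection_workflow(config: dict, out_dir) -> dict:
    """Rank features on a dataset and optionally evaluate top-q subsets.

    ``config`` keys (flat YAML schema): ``data`` (path, label_column,
    delimiter), ``method`` (ssshd/fisher/relief/aucroc/aucprc), ``seed``,
    optional ``grid``/``stability`` blocks for ssshd, ``resampling``
    (smote: true, k, target_ratio), and ``evaluation`` (qs list, protocol
    loocv/kfold, n_folds).  Writes ranking.tsv, optional metrics.tsv and a
    manifest.yaml into ``out_dir``; returns the results in memory as well.
    """
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_cfg = config.get("data") or {}
    if isinstance(data_cfg, str):
        data_cfg = {"path": data_cfg}
    ds = read_dataset(
        data_cfg["path"],
        label_column=data_cfg.get("label_column", "label"),
        delimiter=data_cfg.get("delimiter"),
    )
    method = config.get("method", "ssshd")
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; choose from {METHODS}")
    seed = config.get("seed")
    log.info(
        "dataset: %d x %d, CIR %.2f; method=%s seed=%s",
        *ds.matrix.shape, imbalance_ratio(ds), method, seed,
    )

    X, y = ds.matrix, ds.labels
    res_cfg = config.get("resampling") or {}
    smoted = bool(res_cfg.get("smote", False))
    if smoted:
        X, y = resampling.smote(
            X, y,
            k=int(res_cfg.get("k", 5)),
            target_ratio=float(res_cfg.get("target_ratio", 1.0)),
            seed=seed,
        )
        log.info("SMOTE: %d -> %d samples", ds.matrix.shape[0], X.shape[0])

    work = Dataset(
        matrix=X, feature_names=ds.feature_names, labels=y,
        label_mapping=ds.label_mapping,
    )
    order, values = _rank_features(work, method, config, seed)

    ranking_path = out_dir / "ranking.tsv"
    with open(ranking_path, "w") as fh:
        fh.write("feature_id\tscore\trank\n")
        for rank, j in enumerate(order, start=1):
            fh.write(f"{ds.feature_names[j]}\t{values[j]:.6g}\t{rank}\n")

    results: dict = {"ranking": order, "scores": values}
    eval_cfg = config.get("evaluation") or {}
    qs = eval_cfg.get("qs")
    if qs:
        # LOOCV on raw imbalanced data (folds would skew the per-fold class
        # mix), stratified k-fold once SMOTE has balanced the classes
        protocol = eval_cfg.get("protocol", "kfold" if smoted else "loocv")
        n_folds = int(eval_cfg.get("n_folds", 5))
        rows = []
        for q in qs:
            if not 1 <= int(q) <= len(ds.feature_names):
                raise ParameterError(f"q={q} out of range [1, {len(ds.feature_names)}]")
            cols = order[: int(q)]
            m = _cv_metrics(X[:, cols], y, seed, protocol, n_folds)
            rows.append({"q": int(q), **m})
        metrics_path = out_dir / "metrics.tsv"
        pd.DataFrame(rows).to_csv(metrics_path, sep="\t", index=False)
        results["metrics"] = rows

    write_manifest(
        out_dir / "manifest.yaml",
        {
            "config": _yaml_safe(config),
            "seed": seed,
            "label_mapping": ds.label_mapping,
            "elapsed_s": round(time.time() - t0, 2),
        },
    )
    return results


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
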