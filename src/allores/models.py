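"""Per-residue-type weighted gradient-boosted classifiers.

One binary classifier is trained per canonical amino-acid type, with the
positive (AFR) class up-weighted by ``scale_pos_weight`` (defaulting to the
subset's FR/AFR ratio).  Rows of residue types without a model predict FR.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import roc_auc_score

from ._data import STANDARD_RESIDUES
from .errors import ContractError
from .nanoenv import DescriptorTable

logger = logging.getLogger(__name__)

_PROB_EPS = 1e-15


@dataclass
class TrainingRecord:
    y: int
    y_hat: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.y_hat <= 1.0):
            raise ContractError("predicted probability must lie in [0, 1]")


@dataclass
class ModelConfig:
    """Training knobs.  ``None`` means the library default; explicit values
    are validated against the documented search bounds."""

    scale_pos_weight: float | str = "auto"
    iterations: int | None = None
    depth: int | None = None
    learning_rate: float | None = None
    seed: int = 0
    feature_manifest: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.depth is not None and not (3 <= self.depth <= 10):
            raise ContractError("depth must be in [3, 10]")
        if self.learning_rate is not None and not (0.001 <= self.learning_rate <= 0.5):
            raise ContractError("learning_rate must be in [0.001, 0.5]")
        if self.iterations is not None and not (100 <= self.iterations <= 1000):
            raise ContractError("iterations must be in [100, 1000]")
        if self.scale_pos_weight != "auto" and float(self.scale_pos_weight) <= 0:
            raise ContractError("scale_pos_weight must be positive")


@dataclass
class ModelEnsemble:
    per_residue_models: dict[str, HistGradientBoostingClassifier]
    config: ModelConfig
    training_stats: dict[str, dict] = field(default_factory=dict)
    skipped_types: list[str] = field(default_factory=list)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        (directory / "models").mkdir(parents=True, exist_ok=True)
        for res_name, model in self.per_residue_models.items():
            with open(directory / "models" / f"{res_name}.bin", "wb") as fh:
                pickle.dump(model, fh)
        manifest = {
            "feature_manifest": self.config.feature_manifest,
            "config": {
                "scale_pos_weight": self.config.scale_pos_weight,
                "iterations": self.config.iterations,
                "depth": self.config.depth,
                "learning_rate": self.config.learning_rate,
                "seed": self.config.seed,
            },
            "training_stats": self.training_stats,
            "skipped_types": self.skipped_types,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ModelEnsemble":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        config = ModelConfig(feature_manifest=manifest["feature_manifest"], **manifest["config"])
        models = {}
        for path in sorted((directory / "models").glob("*.bin")):
            with open(path, "rb") as fh:
                models[path.stem] = pickle.load(fh)
        return cls(
            per_residue_models=models,
            config=config,
            training_stats=manifest["training_stats"],
            skipped_types=manifest["skipped_types"],
        )


# ---------------------------------------------------------------------------


def partition_by_residue_type(
    table: DescriptorTable | pd.DataFrame,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Split rows by residue type.  Returns (standard-type subsets,
    excluded non-standard rows)."""
    frame = table.frame if isinstance(table, DescriptorTable) else table
    if "res_name" not in frame.columns:
        raise ContractError("table lacks a res_name column")
    standard = frame["res_name"].isin(STANDARD_RESIDUES)
    excluded = frame[~standard]
    subsets = {
        name: group
        for name, group in frame[standard].groupby("res_name", sort=True)
    }
    if len(excluded):
        logger.info("excluded %d non-standard residue rows", len(excluded))
    return subsets, excluded


def class_weight(n_pos: int, n_neg: int) -> float:
    """FR/AFR count ratio used as the positive-class weight."""
    if n_pos <= 0:
        raise ContractError("cannot train: no AFR rows for this residue type")
    return n_neg / n_pos


def log_loss(records: Iterable[TrainingRecord]) -> float:
    """Mean negative log-likelihood of binary records."""
    records = list(records)
    if not records:
        raise ContractError("log_loss of an empty record set")
    y = np.asarray([r.y for r in records], dtype=float)
    p = np.clip([r.y_hat for r in records], _PROB_EPS, 1.0 - _PROB_EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _design_matrix(frame: pd.DataFrame, manifest: Sequence[str]) -> np.ndarray:
    missing = [c for c in manifest if c not in frame.columns]
    if missing:
        raise ContractError(f"missing feature column(s): {missing}")
    return frame[list(manifest)].to_numpy(dtype=float)


def _make_classifier(config: ModelConfig) -> HistGradientBoostingClassifier:
    kwargs: dict = {"random_state": config.seed}
    if config.iterations is not None:
        kwargs["max_iter"] = config.iterations
    if config.depth is not None:
        kwargs["max_depth"] = config.depth
    if config.learning_rate is not None:
        kwargs["learning_rate"] = config.learning_rate
    return HistGradientBoostingClassifier(**kwargs)


def train_ensemble(
    subsets: dict[str, pd.DataFrame], config: ModelConfig
) -> ModelEnsemble:
    """Fit one weighted gradient-boosted classifier per residue type.

    Subsets lacking AFR (or FR) rows are skipped and listed; training is
    reproducible for a fixed ``config.seed``.
    """
    if not config.feature_manifest:
        raise ContractError("config.feature_manifest is empty")
    models: dict[str, HistGradientBoostingClassifier] = {}
    stats: dict[str, dict] = {}
    skipped: list[str] = []
    for res_name in sorted(subsets):
        frame = subsets[res_name]
        y = (frame["label"] == "AFR").to_numpy(dtype=int)
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        if n_pos == 0 or n_neg == 0:
            skipped.append(res_name)
            continue
        weight = (
            class_weight(n_pos, n_neg)
            if config.scale_pos_weight == "auto"
            else float(config.scale_pos_weight)
        )
        x = _design_matrix(frame, config.feature_manifest)
        sample_weight = np.where(y == 1, weight, 1.0)
        model = _make_classifier(config)
        model.fit(x, y, sample_weight=sample_weight)
        models[res_name] = model
        stats[res_name] = {
            "n_rows": len(frame),
            "n_afr": n_pos,
            "n_fr": n_neg,
            "scale_pos_weight": weight,
        }
    if not models:
        raise ContractError("every residue-type subset was skipped; nothing trained")
    if skipped:
        logger.info("skipped residue types without both classes: %s", skipped)
    return ModelEnsemble(
        per_residue_models=models,
        config=config,
        training_stats=stats,
        skipped_types=skipped,
    )


def predict_residues(
    ensemble: ModelEnsemble,
    table: DescriptorTable | pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Route each row to its residue-type model.

    Rows of types without a model get probability NaN and label FR.
    Returns columns identity, res_name, probability, predicted_label.
    """
    frame = table.frame if isinstance(table, DescriptorTable) else table
    probability = np.full(len(frame), np.nan)
    if len(frame):
        res_names = frame["res_name"].to_numpy()
        for res_name, model in ensemble.per_residue_models.items():
            mask = res_names == res_name
            if mask.any():
                x = _design_matrix(frame[mask], ensemble.config.feature_manifest)
                probability[mask] = model.predict_proba(x)[:, 1]
    predicted = np.where(probability >= threshold, "AFR", "FR")
    out = pd.DataFrame(
        {
            "identity": frame["identity"].to_numpy() if "identity" in frame else np.arange(len(frame)),
            "res_name": frame["res_name"].to_numpy() if len(frame) else [],
            "probability": probability,
            "predicted_label": predicted,
        }
    )
    n_unrouted = int(np.isnan(probability).sum())
    if n_unrouted:
        logger.info("%d rows had no residue-type model; predicted FR", n_unrouted)
    return out


def feature_importance(
    ensemble: ModelEnsemble,
    table: DescriptorTable | pd.DataFrame,
    method: str = "attribution",
    seed: int = 0,
    n_shuffles: int = 10,
) -> tuple[dict[tuple[str, str], float], dict[str, float]]:
    """Per-(residue type, descriptor) importance plus the ensemble mean.

    ``attribution``: mean |change in predicted probability| when the
    descriptor column is permuted — a model-output attribution on the
    probability scale.  ``permutation``: mean ROC-AUC drop over
    ``n_shuffles`` shuffles (requires both classes per subset).
    """
    if method not in ("attribution", "permutation"):
        raise ContractError(f"unknown method {method!r}")
    frame = table.frame if isinstance(table, DescriptorTable) else table
    if not len(frame):
        raise ContractError("empty table")
    rng = np.random.default_rng(seed)
    manifest = ensemble.config.feature_manifest
    per_model: dict[tuple[str, str], float] = {}

    for res_name, model in ensemble.per_residue_models.items():
        sub = frame[frame["res_name"] == res_name]
        if not len(sub):
            continue
        x = _design_matrix(sub, manifest)
        base_prob = model.predict_proba(x)[:, 1]
        y = (sub["label"] == "AFR").to_numpy(dtype=int) if "label" in sub else None
        if method == "permutation":
            if y is None or len(np.unique(y)) < 2:
                continue
            base_score = roc_auc_score(y, base_prob)
        for col_idx, name in enumerate(manifest):
            deltas = []
            for _ in range(n_shuffles):
                x_perm = x.copy()
                x_perm[:, col_idx] = rng.permutation(x_perm[:, col_idx])
                prob = model.predict_proba(x_perm)[:, 1]
                if method == "attribution":
                    deltas.append(np.mean(np.abs(prob - base_prob)))
                else:
                    deltas.append(base_score - roc_auc_score(y, prob))
            per_model[(res_name, name)] = float(max(np.mean(deltas), 0.0))

    if not per_model:
        raise ContractError("no importances computable (no scorable subsets)")
    mean: dict[str, float] = {}
    for name in manifest:
        values = [v for (_, col), v in per_model.items() if col == name]
        mean[name] = float(np.mean(values)) if values else 0.0
    return per_model, mean
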