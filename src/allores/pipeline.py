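"""End-to-end orchestration: label → describe → split → select → train → evaluate.

Feature selection is fit on training-split rows only and frozen for
validation/test.  Every artifact directory carries a provenance JSON with
the configuration hash, so two runs with equal hashes are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .errors import ContractError
from .evaluation import (
    EvaluationReport,
    MetricSet,
    SplitAssignment,
    chain_centric_split,
    classification_metrics,
    dcc,
    success_rate,
)
from .labeling import build_dataset
from .models import (
    ModelConfig,
    ModelEnsemble,
    partition_by_residue_type,
    predict_residues,
    train_ensemble,
)
from .nanoenv import DescriptorTable, NanoenvConfig, compute_descriptor_table
from .selection import SelectionConfig, SelectionReport, select_features, write_manifest
from .structures import Structure, read_structure, select_modulator, strip_group

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    structures: list[dict] = field(default_factory=list)  # {holo, apo?, modulator?}
    pockets: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    nanoenv: NanoenvConfig = field(default_factory=NanoenvConfig)
    split_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    split_seed: int = 0
    afr_distance: float = 5.0
    dcc_cutoff: float = 4.0
    decision_threshold: float = 0.5
    na_policy: str = "exclude"
    output_dir: str = "allores_run"

    def __post_init__(self) -> None:
        if min(self.afr_distance, self.dcc_cutoff, self.decision_threshold) <= 0:
            raise ContractError("thresholds must be positive")
        if self.na_policy not in ("exclude", "count_as_failure"):
            raise ContractError(f"unknown na_policy {self.na_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "selection" in kwargs:
            kwargs["selection"] = SelectionConfig(**kwargs["selection"])
        if "model" in kwargs:
            kwargs["model"] = ModelConfig(**kwargs["model"])
        if "nanoenv" in kwargs:
            kwargs["nanoenv"] = NanoenvConfig(**kwargs["nanoenv"])
        if "split_fractions" in kwargs:
            kwargs["split_fractions"] = tuple(kwargs["split_fractions"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["split_fractions"] = list(self.split_fractions)
        return out

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class TrainResult:
    ensemble: ModelEnsemble
    selection_report: SelectionReport
    split: SplitAssignment
    table: DescriptorTable
    labels: pd.DataFrame
    holo_structures: dict[str, Structure]
    validation_metrics: MetricSet | None


def _load_entries(config: RunConfig) -> list[tuple]:
    entries = []
    for item in config.structures:
        entries.append((item["holo"], item.get("apo"), item.get("modulator", "auto")))
    return entries


def prepare_dataset(
    entries: Sequence[tuple], config: RunConfig
) -> tuple[pd.DataFrame, DescriptorTable, dict[str, Structure]]:
    """Label the holo structures and compute descriptors on the unbound forms."""
    if not entries:
        raise ContractError("empty structure list")
    resolved: list[tuple] = []
    holos: dict[str, Structure] = {}
    apos: list[Structure] = []
    for entry in entries:
        holo, apo, modulator = (tuple(entry) + ("auto",))[:3]
        if not isinstance(holo, Structure):
            holo = read_structure(Path(holo))
        if apo is not None and not isinstance(apo, Structure):
            apo = read_structure(Path(apo))
        if modulator == "auto":
            modulator = select_modulator(holo)
        resolved.append((holo, apo, modulator))
        holos[holo.id] = holo
        apos.append(apo if apo is not None else strip_group(holo, modulator))

    labels, errors = build_dataset(
        resolved,
        distance_cutoff=config.afr_distance,
        n_points=config.nanoenv.n_points,
    )
    for err in errors:
        logger.warning("labeling failure: %s", err)
    table = compute_descriptor_table(apos, labels, config=config.nanoenv)
    return labels, table, holos


def run_train(
    config: RunConfig,
    entries: Sequence[tuple] | None = None,
    output_dir: str | Path | None = None,
) -> TrainResult:
    """Execute the training workflow and write all artifacts.

    ``entries`` (triples of holo/apo/modulator, structures or paths)
    overrides the paths in ``config.structures``.
    """
    if entries is None:
        entries = _load_entries(config)
    out = Path(output_dir if output_dir is not None else config.output_dir)
    created_dir = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        labels, table, holos = prepare_dataset(entries, config)

        chain_keys = sorted(labels["chain"].unique())
        split = chain_centric_split(
            chain_keys, config.split_fractions, seed=config.split_seed
        )
        subset_of = split.assignment
        frame = table.frame
        in_train = frame["chain"].map(subset_of) == "train"
        train_table = DescriptorTable(
            frame=frame[in_train].reset_index(drop=True), provenance=table.provenance
        )

        features, selection_report = select_features(train_table, config.selection)
        if not features:
            # degenerate desk-scale corner: fall back to the pruned set
            logger.warning("KS filter rejected every descriptor; using pruned set")
            features = selection_report.kept = list(selection_report.ks_stats)

        model_config = dataclasses.replace(config.model, feature_manifest=features)
        subsets, _ = partition_by_residue_type(train_table)
        ensemble = train_ensemble(subsets, model_config)

        validation_metrics = None
        in_val = frame["chain"].map(subset_of) == "validation"
        if in_val.any():
            val_frame = frame[in_val]
            preds = predict_residues(ensemble, val_frame, config.decision_threshold)
            validation_metrics = classification_metrics(
                val_frame["label"].to_numpy(),
                preds["probability"].to_numpy(),
                threshold=config.decision_threshold,
            )
            logger.info("validation metrics: %s", validation_metrics.as_dict())

        # artifacts
        labels.to_csv(out / "labels.tsv", sep="\t", index=False)
        table.to_tsv(out / "descriptors.tsv")
        selection_report.to_json(out / "selection.json")
        write_manifest(features, out / "feature_manifest.txt")
        (out / "split.json").write_text(json.dumps(split.assignment, indent=2))
        ensemble.save(out / "ensemble")
        provenance = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "n_rows": len(frame),
            "n_features_selected": len(features),
            "validation_metrics": (
                validation_metrics.as_dict() if validation_metrics else None
            ),
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    except Exception:
        # do not leave partial artifact directories behind
        if created_dir:
            shutil.rmtree(out, ignore_errors=True)
        raise
    return TrainResult(
        ensemble=ensemble,
        selection_report=selection_report,
        split=split,
        table=table,
        labels=labels,
        holo_structures=holos,
        validation_metrics=validation_metrics,
    )


def run_evaluate(
    config: RunConfig,
    ensemble: ModelEnsemble,
    table: DescriptorTable,
    labels: pd.DataFrame,
    holo_structures: dict[str, Structure],
    chains: Sequence[str] | None = None,
    output_dir: str | Path | None = None,
) -> EvaluationReport:
    """Evaluate an ensemble on the given chains (default: all in ``table``).

    Produces per-chain DCC values, success rates under both N/A policies,
    and residue-level metrics overall and per residue type.
    """
    frame = table.frame
    if chains is not None:
        frame = frame[frame["chain"].isin(set(chains))]
    if not len(frame):
        raise ContractError("no rows selected for evaluation")
    missing = [c for c in ensemble.config.feature_manifest if c not in frame.columns]
    if missing:
        raise ContractError(f"table lacks manifest feature(s) {missing}")

    preds = predict_residues(ensemble, frame, threshold=config.decision_threshold)
    merged = frame[["identity", "chain", "res_name", "label"]].merge(
        preds[["identity", "probability", "predicted_label"]], on="identity"
    )

    per_chain_dcc: dict[str, float | None] = {}
    for chain_key, group in merged.groupby("chain"):
        true_set = set(group.loc[group["label"] == "AFR", "identity"])
        if not true_set:
            continue  # no annotated site on this chain
        pred_set = set(group.loc[group["predicted_label"] == "AFR", "identity"])
        structure_id = group["identity"].iloc[0].rsplit("_", 3)[0]
        structure = holo_structures.get(structure_id)
        if structure is None:
            raise ContractError(f"no structure loaded for {structure_id}")
        per_chain_dcc[str(chain_key)] = dcc(pred_set, true_set, structure)

    values = list(per_chain_dcc.values())
    try:
        rate_excl = success_rate(values, config.dcc_cutoff, "exclude")
    except ContractError:
        rate_excl = None  # every chain was N/A
    rate_fail = success_rate(values, config.dcc_cutoff, "count_as_failure") if values else 0.0

    overall = classification_metrics(
        merged["label"].to_numpy(), merged["probability"].to_numpy(),
        threshold=config.decision_threshold,
    )
    per_type: dict[str, MetricSet] = {}
    for res_name, group in merged.groupby("res_name"):
        per_type[str(res_name)] = classification_metrics(
            group["label"].to_numpy(), group["probability"].to_numpy(),
            threshold=config.decision_threshold,
        )

    report = EvaluationReport(
        per_chain_dcc=per_chain_dcc,
        dcc_cutoff=config.dcc_cutoff,
        success_rate_exclude=rate_excl,
        success_rate_count_as_failure=rate_fail,
        overall=overall,
        per_type=per_type,
    )
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "evaluation.json")
        report.dcc_tsv(out / "dcc.tsv")
        report.metrics_tsv(out / "metrics.tsv")
    return report
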