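"""Chain-centric splitting, DCC site evaluation, residue metrics, pockets.

The distance-center-center (DCC) score is the Euclidean distance between the
heavy-atom centroids of the predicted and the true site residue sets; a
chain counts as a success when DCC is at or below the cutoff (default 4 Å).
Chains with an empty predicted set have undefined DCC ("N/A") and are
handled by an explicit policy.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import ContractError
from .structures import Structure

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitAssignment:
    assignment: dict[str, str]  # chain key -> {train, validation, test}
    fractions_requested: tuple[float, float, float]
    fractions_achieved: tuple[float, float, float]
    seed: int

    def keys_in(self, subset: str) -> list[str]:
        return [k for k, s in self.assignment.items() if s == subset]


def chain_centric_split(
    keys: Sequence[str],
    fractions: tuple[float, float, float],
    seed: int = 0,
) -> SplitAssignment:
    """Disjoint train/validation/test partition of composite chain keys.

    Validation and test sizes are ``round(fraction × n)``; the remainder
    goes to train.  Shuffling is by ``seed``.
    """
    keys = list(keys)
    if len(set(keys)) != len(keys):
        raise ContractError("duplicate chain keys in split input")
    f_train, f_val, f_test = fractions
    if min(fractions) < 0 or f_train <= 0:
        raise ContractError("fractions must be non-negative with train > 0")
    if abs(sum(fractions) - 1.0) > 0.01:
        raise ContractError(f"fractions must sum to ~1, got {sum(fractions)}")

    n = len(keys)
    n_val = int(round(f_val * n))
    n_test = int(round(f_test * n))
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ContractError("rounded validation+test exceed the key count")

    rng = np.random.default_rng(seed)
    shuffled = [keys[i] for i in rng.permutation(n)]
    assignment: dict[str, str] = {}
    for key in shuffled[:n_train]:
        assignment[key] = "train"
    for key in shuffled[n_train : n_train + n_val]:
        assignment[key] = "validation"
    for key in shuffled[n_train + n_val :]:
        assignment[key] = "test"
    achieved = (n_train / n, n_val / n, n_test / n)
    return SplitAssignment(
        assignment=assignment,
        fractions_requested=tuple(fractions),
        fractions_achieved=achieved,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# DCC
# ---------------------------------------------------------------------------


def _set_centroid(identities: Iterable[str], structure: Structure) -> np.ndarray:
    by_identity = {
        r.identity(structure.id): r for r in structure.iter_residues()
    }
    coords = []
    for ident in identities:
        if ident not in by_identity:
            raise ContractError(f"residue {ident} not in structure {structure.id}")
        coords.append(by_identity[ident].heavy_coords())
    return np.vstack(coords).mean(axis=0)


def dcc(
    pred_residues: Iterable[str],
    true_residues: Iterable[str],
    structure: Structure,
) -> float | None:
    """Distance between heavy-atom centroids of two residue sets.

    ``None`` (undefined) when the predicted set is empty — the model made
    no prediction for this chain.
    """
    pred = list(pred_residues)
    true = list(true_residues)
    if not pred:
        return None
    if not true:
        raise ContractError("true residue set is empty")
    return float(
        np.linalg.norm(_set_centroid(pred, structure) - _set_centroid(true, structure))
    )


def success_rate(
    dcc_values: Iterable[float | None],
    cutoff: float = 4.0,
    undefined_policy: str = "exclude",
) -> float:
    """Percentage of chains with DCC ≤ cutoff.

    ``exclude`` drops undefined (N/A) values from the denominator;
    ``count_as_failure`` keeps them as misses.
    """
    if undefined_policy not in ("exclude", "count_as_failure"):
        raise ContractError(f"unknown undefined_policy {undefined_policy!r}")
    values = list(dcc_values)
    if not values:
        raise ContractError("success_rate of an empty collection")
    defined = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    successes = sum(1 for v in defined if v <= cutoff)
    denominator = len(defined) if undefined_policy == "exclude" else len(values)
    if denominator == 0:
        raise ContractError("no defined DCC values under the exclude policy")
    return 100.0 * successes / denominator


# ---------------------------------------------------------------------------
# Residue-level metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricSet:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float | None
    roc_auc: float | None

    @classmethod
    def from_counts(
        cls, tp: int, fp: int, fn: int, tn: int, roc_auc: float | None = None
    ) -> "MetricSet":
        n = tp + tn + fp + fn
        if n == 0:
            raise ContractError("empty confusion matrix")
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = f1_from_pr(precision, recall)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        both_classes = (tp + fn) > 0 and (tn + fp) > 0
        mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else (0.0 if both_classes else None)
        return cls(
            tp=tp, tn=tn, fp=fp, fn=fn,
            accuracy=(tp + tn) / n,
            precision=precision,
            recall=recall,
            f1=f1,
            mcc=mcc if both_classes else None,
            roc_auc=roc_auc,
        )

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "mcc": self.mcc,
            "roc_auc": self.roc_auc,
        }


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both vanish)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def classification_metrics(
    y: Sequence, scores: Sequence[float], threshold: float = 0.5
) -> MetricSet:
    """Standard confusion-matrix metrics plus rank-based ROC-AUC.

    ``y`` may be AFR/FR strings or 0/1; ``scores`` are positive-class
    probabilities (NaN counts as "no prediction" = score 0).  MCC and
    ROC-AUC are left undefined (None) when only one class is present.
    """
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if len(y) != len(scores):
        raise ContractError("y and scores length mismatch")
    y_true = (y == "AFR").astype(int) if y.dtype.kind in "UO" else y.astype(int)
    scores = np.nan_to_num(scores, nan=0.0)
    y_pred = (scores >= threshold).astype(int)

    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    auc = None
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    return MetricSet.from_counts(tp=tp, fp=fp, fn=fn, tn=tn, roc_auc=auc)


# ---------------------------------------------------------------------------
# Pocket coverage
# ---------------------------------------------------------------------------


def percent_outside(n_in: int, n_out: int) -> float:
    """Share of AFRs outside any pocket, in percent."""
    if n_in + n_out == 0:
        raise ContractError("no AFRs counted")
    return 100.0 * n_out / (n_in + n_out)


def pocket_coverage(
    afr_sets: Mapping[str, set[str]],
    pocket_sets: Mapping[str, Sequence[set[str]]],
) -> tuple[int, int, float]:
    """Count AFRs inside/outside pocket membership lists per chain.

    An AFR is "in" iff it belongs to any pocket set of its chain.  Chains
    absent from ``pocket_sets`` count with empty pockets (warned).
    """
    n_in = n_out = 0
    for chain, afrs in afr_sets.items():
        pockets = pocket_sets.get(chain)
        if pockets is None:
            logger.warning("chain %s has no pocket sets; counted as all-outside", chain)
            pockets = []
        members = set().union(*pockets) if pockets else set()
        inside = len(afrs & members)
        n_in += inside
        n_out += len(afrs) - inside
    return n_in, n_out, percent_outside(n_in, n_out)


def read_pocket_sets(path: str | Path) -> dict[str, list[set[str]]]:
    """Read pocket membership TSV (columns: chain, pocket_id, identity)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"chain", "pocket_id", "identity"}
    if not required <= set(frame.columns):
        raise ContractError(f"pocket TSV must have columns {sorted(required)}")
    out: dict[str, list[set[str]]] = {}
    for (chain, _), group in frame.groupby(["chain", "pocket_id"]):
        out.setdefault(str(chain), []).append(set(group["identity"]))
    return out


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    per_chain_dcc: dict[str, float | None]
    dcc_cutoff: float
    success_rate_exclude: float | None
    success_rate_count_as_failure: float
    overall: MetricSet
    per_type: dict[str, MetricSet] = field(default_factory=dict)
    pocket_counts: tuple[int, int, float] | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_chain_dcc": self.per_chain_dcc,
            "dcc_cutoff": self.dcc_cutoff,
            "success_rate_exclude": self.success_rate_exclude,
            "success_rate_count_as_failure": self.success_rate_count_as_failure,
            "overall": self.overall.as_dict(),
            "per_type": {k: m.as_dict() for k, m in self.per_type.items()},
            "pocket_counts": self.pocket_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def dcc_tsv(self, path: str | Path) -> None:
        lines = ["chain\tdcc"]
        for chain, value in self.per_chain_dcc.items():
            lines.append(f"{chain}\t{'N/A' if value is None else f'{value:.4f}'}")
        Path(path).write_text("\n".join(lines) + "\n")

    def metrics_tsv(self, path: str | Path) -> None:
        lines = ["residue\tf1\tmcc\trecall\tprecision"]
        for res_name, m in sorted(self.per_type.items()):
            mcc = "N/A" if m.mcc is None else f"{m.mcc:.4f}"
            lines.append(
                f"{res_name}\t{m.f1:.4f}\t{mcc}\t{m.recall:.4f}\t{m.precision:.4f}"
            )
        Path(path).write_text("\n".join(lines) + "\n")
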