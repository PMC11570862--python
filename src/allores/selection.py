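"""Descriptor reduction: correlation pruning then KS distribution filtering."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .nanoenv import DescriptorTable

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    rho_max: float = 0.7
    alpha: float = 0.05
    correction: str = "none"  # or "benjamini_hochberg"

    def __post_init__(self) -> None:
        if not (0 < self.rho_max <= 1):
            raise ContractError("rho_max must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ContractError("alpha must be in (0, 1)")
        if self.correction not in ("none", "benjamini_hochberg"):
            raise ContractError(f"unknown correction {self.correction!r}")


@dataclass
class SelectionReport:
    dropped_by_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    ks_stats: dict[str, tuple[float, float, bool]] = field(default_factory=dict)
    kept: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dropped_by_correlation": [
                {"descriptor": d, "partner": p, "rho": r}
                for d, p, r in self.dropped_by_correlation
            ],
            "ks_stats": {
                name: {"statistic": d, "p_value": p, "kept": kept}
                for name, (d, p, kept) in self.ks_stats.items()
            },
            "kept": self.kept,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _numeric_frame(table: DescriptorTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, DescriptorTable):
        return table.frame[table.descriptor_columns]
    return table.select_dtypes(include=[np.number])


def correlation_prune(
    table: DescriptorTable | pd.DataFrame, rho_max: float = 0.7
) -> tuple[list[str], SelectionReport]:
    """Greedy elimination until every surviving pair has |ρ| ≤ ``rho_max``.

    At each step the worst pair (largest |ρ|) is found and the member with
    the larger mean absolute correlation to the remaining columns is
    dropped; ties fall to the later column.  Zero-variance columns cannot
    correlate and are kept with a warning.
    """
    frame = _numeric_frame(table)
    if len(frame) < 2:
        raise ContractError("need at least 2 rows to estimate correlations")
    for col in frame.columns[frame.std(ddof=0) == 0]:
        warnings.warn(f"constant column {col!r}: kept, correlations undefined")

    report = SelectionReport()
    kept = list(frame.columns)
    with np.errstate(invalid="ignore"):
        corr = frame.corr().abs().fillna(0.0)
    np.fill_diagonal(corr.values, 0.0)

    while kept:
        sub = corr.loc[kept, kept]
        max_rho = float(sub.values.max())
        if max_rho <= rho_max:
            break
        flat = np.argmax(sub.values)
        i, j = np.unravel_index(flat, sub.shape)
        a, b = sub.index[i], sub.columns[j]
        # drop the member with larger mean |ρ| to all remaining columns
        mean_a, mean_b = float(sub[a].mean()), float(sub[b].mean())
        later = a if kept.index(a) > kept.index(b) else b
        victim = later if np.isclose(mean_a, mean_b) else (a if mean_a > mean_b else b)
        partner = b if victim == a else a
        report.dropped_by_correlation.append((victim, partner, max_rho))
        kept.remove(victim)

    report.kept = kept
    return kept, report


def ks_filter(
    table: DescriptorTable | pd.DataFrame,
    labels: pd.Series | np.ndarray | None = None,
    config: SelectionConfig | None = None,
    columns: list[str] | None = None,
) -> tuple[list[str], SelectionReport]:
    """Keep descriptors whose AFR and FR samples differ by a two-sample KS
    test at level ``alpha`` (optionally Benjamini–Hochberg corrected)."""
    if config is None:
        config = SelectionConfig()
    frame = _numeric_frame(table)
    if columns is not None:
        frame = frame[columns]
    if labels is None:
        if not isinstance(table, DescriptorTable):
            raise ContractError("labels required when table is a bare frame")
        labels = table.frame["label"]
    is_pos = np.asarray(labels) == "AFR" if np.asarray(labels).dtype.kind in "UO" else np.asarray(labels).astype(bool)
    n_pos, n_neg = int(is_pos.sum()), int((~is_pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("both classes must be present for the KS filter")
    if min(n_pos, n_neg) < 8:
        raise ContractError("need >= 8 rows in each class")

    method = "exact" if min(n_pos, n_neg) < 25 else "asymp"
    names = list(frame.columns)
    d_stats, p_values = [], []
    for name in names:
        values = frame[name].to_numpy()
        result = stats.ks_2samp(values[is_pos], values[~is_pos], method=method)
        d_stats.append(float(result.statistic))
        p_values.append(float(result.pvalue))

    p_adj = np.asarray(p_values)
    if config.correction == "benjamini_hochberg":
        order = np.argsort(p_adj)
        ranked = p_adj[order] * len(p_adj) / (np.arange(len(p_adj)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = np.empty_like(p_adj)
        adjusted[order] = np.minimum(ranked, 1.0)
        p_adj = adjusted

    report = SelectionReport()
    kept = []
    for name, d, p_raw, p in zip(names, d_stats, p_values, p_adj):
        keep = bool(p < config.alpha)
        report.ks_stats[name] = (d, p_raw, keep)
        if keep:
            kept.append(name)
    report.kept = kept
    return kept, report


def select_features(
    table: DescriptorTable, config: SelectionConfig | None = None
) -> tuple[list[str], SelectionReport]:
    """Full pipeline: correlation pruning first, KS filtering second."""
    if config is None:
        config = SelectionConfig()
    kept_corr, corr_report = correlation_prune(table, rho_max=config.rho_max)
    kept, ks_report = ks_filter(table, config=config, columns=kept_corr)
    report = SelectionReport(
        dropped_by_correlation=corr_report.dropped_by_correlation,
        ks_stats=ks_report.ks_stats,
        kept=kept,
    )
    return kept, report


def qq_points(values: np.ndarray) -> np.ndarray:
    """Ordered (standard-normal theoretical quantile, sample quantile) pairs
    at plotting positions (i − 0.5)/n.  Data only; no rendering."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ContractError("need n >= 3")
    ordered = np.sort(values)
    theoretical = stats.norm.ppf((np.arange(1, values.size + 1) - 0.5) / values.size)
    return np.column_stack([theoretical, ordered])


def write_manifest(features: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(features) + "\n")
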