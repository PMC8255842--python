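"""Mimic-vs-control fold changes and two-cell-line intersection calls.

The transfection design has one contrast per cell line: cells transfected with
a miRNA mimic versus a negative-control (NC) duplex.  Differential expression
is summarized by a mean-ratio log2 fold change with a pseudocount,

    log2FC(g) = log2((mean mimic TPM_g + eps) / (mean NC TPM_g + eps)),

which is well defined with a single sample per condition and needs no
dispersion model.  Genes are called down/up per cell line against a symmetric
fold-change threshold and then intersected across cell lines, so the shared
sets reflect reproducible regulation rather than per-line noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .seeds import SiteSummary

__all__ = [
    "AnalysisConfig",
    "ConfigurationError",
    "compute_log2fc",
    "log2fc_table",
    "call_directions",
    "call_shared_regulated",
    "top_downregulated",
    "MimicContrast",
    "FoldChangeResults",
]

DOWN = "down"
UP = "up"
UNCHANGED = "unchanged"


class ConfigurationError(ValueError):
    """A required cell line or condition is absent from the metadata."""


@dataclass
class AnalysisConfig:
    """Thresholds of the screen.

    fc_threshold
        Fold-change cut for down/up calls, applied symmetrically:
        down ⇔ log2FC ≤ −log2(fc_threshold), up ⇔ log2FC ≥ +log2(fc_threshold).
    strong_down_cut
        log2FC ceiling (strict <) for the "most downregulated" top table.
    pseudocount
        Added to both condition means before the ratio.
    alpha
        Two-sided significance level of the cohort screen.
    min_expressed_samples
        A miRNA must be detected (>0) in more than this many patients to enter
        the cohort screen.
    """

    fc_threshold: float = 1.5
    strong_down_cut: float = -0.9
    pseudocount: float = 1.0
    alpha: float = 0.05
    min_expressed_samples: int = 300

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def down_cut(self) -> float:
        """log2 threshold below which (≤) a gene is called down."""
        return -math.log2(self.fc_threshold)


def _condition_samples(metadata: pd.DataFrame, cell_line: str, condition: str) -> list[str]:
    sel = metadata[
        (metadata["cell_line"] == cell_line) & (metadata["condition"] == condition)
    ]["sample_id"].tolist()
    if not sel:
        raise ConfigurationError(
            f"no {condition!r} samples for cell line {cell_line!r}"
        )
    return sel


def compute_log2fc(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    cell_line: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene mean-ratio log2 fold change (mimic over NC) for one cell line."""
    mimic = _condition_samples(metadata, cell_line, "mimic")
    nc = _condition_samples(metadata, cell_line, "NC")
    num = expression[mimic].mean(axis=1) + pseudocount
    den = expression[nc].mean(axis=1) + pseudocount
    if (num <= 0).any() or (den <= 0).any():
        raise ConfigurationError(
            "zero condition mean with pseudocount 0; use a positive pseudocount"
        )
    out = np.log2(num / den)
    out.name = cell_line
    return out


def log2fc_table(
    expression: pd.DataFrame, metadata: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2FC per gene (rows) per cell line (columns), lines in metadata order."""
    lines = list(dict.fromkeys(metadata["cell_line"]))
    return pd.DataFrame(
        {line: compute_log2fc(expression, metadata, line, pseudocount) for line in lines}
    )


def call_directions(log2fc: pd.DataFrame, fc_threshold: float = 1.5) -> pd.DataFrame:
    """down / up / unchanged per gene and cell line at the symmetric cut."""
    cut = math.log2(fc_threshold)
    calls = pd.DataFrame(UNCHANGED, index=log2fc.index, columns=log2fc.columns)
    calls = calls.mask(log2fc <= -cut, DOWN).mask(log2fc >= cut, UP)
    return calls


def call_shared_regulated(
    log2fc: pd.DataFrame, fc_threshold: float = 1.5
) -> tuple[pd.Index, pd.Index]:
    """Genes called down (resp. up) in *every* cell line; the sets are disjoint."""
    calls = call_directions(log2fc, fc_threshold)
    shared_down = log2fc.index[(calls == DOWN).all(axis=1)]
    shared_up = log2fc.index[(calls == UP).all(axis=1)]
    return shared_down, shared_up


def top_downregulated(
    log2fc: pd.DataFrame,
    fc_threshold: float = 1.5,
    strong_down_cut: float = -0.9,
    summaries: Optional[Mapping[str, SiteSummary]] = None,
) -> pd.DataFrame:
    """Shared-down genes below the strong cut in every line, strongest first.

    Sorted by mean log2FC ascending (ties broken by gene id); when per-gene
    site summaries are given, site counts/types/regions are joined in.
    """
    shared_down, _ = call_shared_regulated(log2fc, fc_threshold)
    sub = log2fc.loc[shared_down]
    keep = (sub < strong_down_cut).all(axis=1)
    sub = sub[keep].copy()
    sub["mean_log2fc"] = sub.mean(axis=1)
    sub.index.name = "gene_id"
    out = sub.reset_index().sort_values(
        ["mean_log2fc", "gene_id"], kind="mergesort", ignore_index=True
    )
    if summaries is not None:
        out["n_sites"] = [
            summaries[g].total_sites if g in summaries else 0 for g in out["gene_id"]
        ]
        out["site_types"] = [
            "; ".join(
                f"{t} ({n})"
                for t, n in sorted(summaries[g].counts_by_type.items())
            )
            if g in summaries
            else ""
            for g in out["gene_id"]
        ]
        out["regions"] = [
            "; ".join(
                f"{r} ({n})"
                for r, n in sorted(summaries[g].counts_by_region.items())
            )
            if g in summaries
            else ""
            for g in out["gene_id"]
        ]
    return out


class MimicContrast:
    """Model object for a mimic-vs-NC transfection experiment.

    Parameters
    ----------
    expression
        Non-negative genes × samples table (TPM-like).
    metadata
        One row per sample: ``sample_id``, ``cell_line``,
        ``condition`` ∈ {mimic, NC}.  Every cell line needs at least one
        sample of each condition.
    config
        Thresholds; defaults to :class:`AnalysisConfig`.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        metadata: pd.DataFrame,
        config: Optional[AnalysisConfig] = None,
    ) -> None:
        if (expression.to_numpy() < 0).any():
            raise ValueError("expression must be non-negative")
        unknown = set(metadata["sample_id"]) - set(expression.columns)
        if unknown:
            raise ConfigurationError(f"metadata samples absent from table: {sorted(unknown)}")
        self.expression = expression
        self.metadata = metadata.reset_index(drop=True)
        self.config = config or AnalysisConfig()
        for line in dict.fromkeys(self.metadata["cell_line"]):
            _condition_samples(self.metadata, line, "mimic")
            _condition_samples(self.metadata, line, "NC")

    @classmethod
    def from_files(
        cls, expression_path: str, metadata_path: str, config: Optional[AnalysisConfig] = None
    ) -> "MimicContrast":
        from .io import read_expression, read_sample_metadata

        return cls(read_expression(expression_path), read_sample_metadata(metadata_path), config)

    def fit(self) -> "FoldChangeResults":
        log2fc = log2fc_table(self.expression, self.metadata, self.config.pseudocount)
        return FoldChangeResults(log2fc, self.config)


class FoldChangeResults:
    """Fitted fold changes with direction calls and shared regulated sets."""

    def __init__(self, log2fc: pd.DataFrame, config: AnalysisConfig) -> None:
        self.log2fc = log2fc
        self.config = config
        self.directions = call_directions(log2fc, config.fc_threshold)
        self.shared_down, self.shared_up = call_shared_regulated(
            log2fc, config.fc_threshold
        )

    @property
    def cell_lines(self) -> list[str]:
        return list(self.log2fc.columns)

    def top_table(
        self, summaries: Optional[Mapping[str, SiteSummary]] = None
    ) -> pd.DataFrame:
        return top_downregulated(
            self.log2fc,
            self.config.fc_threshold,
            self.config.strong_down_cut,
            summaries,
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-gene log2FC per line plus the consensus call."""
        out = self.log2fc.copy()
        call = pd.Series("none", index=out.index)
        call[out.index.isin(self.shared_down)] = "shared_down"
        call[out.index.isin(self.shared_up)] = "shared_up"
        out = out.add_prefix("log2fc_")
        out["call"] = call
        out.index.name = "gene_id"
        return out.reset_index()

    def summary(self) -> str:
        cut = self.config.down_cut
        lines = [
            "Mimic-vs-NC contrast",
            "====================",
            f"cell lines:        {', '.join(self.cell_lines)}",
            f"genes:             {len(self.log2fc)}",
            f"fold-change cut:   {self.config.fc_threshold} (|log2FC| >= {-cut:.3f})",
            f"shared down:       {len(self.shared_down)}",
            f"shared up:         {len(self.shared_up)}",
            f"strong-down (< {self.config.strong_down_cut}): {len(self.top_table())}",
        ]
        return "\n".join(lines)
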