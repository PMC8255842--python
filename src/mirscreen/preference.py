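"""Targeting-preference statistics and pathway over-representation.

Given the shared-down gene set and the per-gene seed-site summaries, this
module answers four questions about how the miRNA selects its targets: what
fraction of repressed genes carry at least one seed site; how the sites split
across the canonical classes (7mer-A1 / 7mer-m8 / 8mer); where they sit on the
transcript (CDS vs 3'UTR); and whether the repression depth scales with the
number of sites (Spearman rank correlation of log2FC vs site count).

Over-representation of the regulated sets in user-supplied pathway gene sets
uses the one-sided hypergeometric upper tail with Benjamini–Hochberg control
across pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy import stats

from .seeds import (
    REGION_3UTR,
    REGION_CDS,
    REGION_5UTR,
    SITE_TYPES,
    SeedSite,
    SiteSummary,
)

__all__ = [
    "EmptyInputError",
    "CorrelationResult",
    "PreferenceReport",
    "site_presence_fraction",
    "mode_and_region_distributions",
    "fc_sitecount_correlation",
    "build_preference_report",
    "pathway_overrepresentation",
]

logger = logging.getLogger(__name__)


class EmptyInputError(ValueError):
    """An operation that needs at least one gene or site received none."""


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation with its two-sided p; ``applicable`` is False when
    the correlation is undefined (constant input or too few pairs)."""

    rho: float
    p_value: float
    n: int
    applicable: bool = True


@dataclass
class PreferenceReport:
    """Headline targeting-preference quantities for one regulated gene set."""

    fraction_with_sites: float
    mode_distribution: dict[str, float]
    region_distribution: dict[str, float]
    correlations: dict[str, CorrelationResult] = field(default_factory=dict)


def site_presence_fraction(
    genes: Iterable[str], summaries: Mapping[str, SiteSummary]
) -> float:
    """Fraction of genes carrying at least one seed site (absent summary = 0)."""
    genes = list(genes)
    if not genes:
        raise EmptyInputError("site_presence_fraction needs a nonempty gene set")
    with_sites = sum(
        1 for g in genes if g in summaries and summaries[g].total_sites >= 1
    )
    return with_sites / len(genes)


def mode_and_region_distributions(
    sites: Iterable[SeedSite], include_5utr: bool = False
) -> tuple[dict[str, float], dict[str, float]]:
    """Proportions of site classes and of CDS/3'UTR localization.

    The mode distribution covers all sites (5'UTR sites excluded by default;
    they are atypical and reported separately).  The region distribution is
    restricted to sites inside CDS or 3'UTR — junction windows belong to
    neither denominator.
    """
    sites = list(sites)
    if not include_5utr:
        sites = [s for s in sites if s.region != REGION_5UTR]
    if not sites:
        raise EmptyInputError("mode_and_region_distributions needs at least one site")
    modes = {t: 0 for t in SITE_TYPES}
    for s in sites:
        modes[s.site_type] += 1
    mode_dist = {t: n / len(sites) for t, n in modes.items() if n > 0}
    localized = [s for s in sites if s.region in (REGION_CDS, REGION_3UTR)]
    if localized:
        region_counts = {REGION_CDS: 0, REGION_3UTR: 0}
        for s in localized:
            region_counts[s.region] += 1
        region_dist = {
            r: n / len(localized) for r, n in region_counts.items() if n > 0
        }
    else:
        region_dist = {}
    return mode_dist, region_dist


def fc_sitecount_correlation(
    log2fc: pd.Series, site_counts: pd.Series
) -> CorrelationResult:
    """Spearman rank correlation of log2FC against per-gene site count.

    Returns a flagged not-applicable result when either variable is constant
    or fewer than 3 genes have both values defined.
    """
    joined = pd.concat(
        {"fc": log2fc, "n_sites": site_counts}, axis=1, join="inner"
    ).dropna()
    n = len(joined)
    if n < 3 or joined["n_sites"].nunique() < 2 or joined["fc"].nunique() < 2:
        return CorrelationResult(float("nan"), float("nan"), n, applicable=False)
    rho, p = stats.spearmanr(joined["fc"], joined["n_sites"])
    return CorrelationResult(float(rho), float(p), n, applicable=True)


def build_preference_report(
    shared_down: Iterable[str],
    summaries: Mapping[str, SiteSummary],
    sites: Iterable[SeedSite],
    log2fc: Optional[pd.DataFrame] = None,
    include_5utr: bool = False,
) -> PreferenceReport:
    """Assemble the full preference report for the shared-down gene set.

    ``sites`` should be restricted to shared-down genes; the dose–response
    correlation is computed per cell line within that same population.
    """
    shared_down = list(shared_down)
    down_set = set(shared_down)
    sites = [s for s in sites if s.gene_id in down_set]
    fraction = site_presence_fraction(shared_down, summaries)
    mode_dist, region_dist = mode_and_region_distributions(sites, include_5utr)
    correlations: dict[str, CorrelationResult] = {}
    if log2fc is not None:
        counts = pd.Series(
            {g: summaries[g].total_sites if g in summaries else 0 for g in shared_down}
        )
        for line in log2fc.columns:
            correlations[line] = fc_sitecount_correlation(
                log2fc.loc[log2fc.index.isin(down_set), line], counts
            )
    return PreferenceReport(fraction, mode_dist, region_dist, correlations)


def pathway_overrepresentation(
    selected: Iterable[str],
    universe: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``selected`` per pathway.

    For a universe of N genes, a pathway hitting K of them, and n selected
    genes of which k fall in the pathway, p = P[X >= k] for
    X ~ Hypergeom(N, K, n).  Pathways with no universe overlap are skipped.
    q-values are Benjamini–Hochberg across the tested pathways; rows are
    sorted by p (ties by pathway id).
    """
    universe = set(universe)
    selected = set(selected)
    if not universe:
        raise EmptyInputError("empty universe")
    stray = selected - universe
    if stray:
        raise ValueError(
            f"{len(stray)} selected genes are not in the universe "
            f"(e.g. {sorted(stray)[:3]})"
        )
    if not gene_sets:
        raise EmptyInputError("empty gene-set collection")
    N, n = len(universe), len(selected)
    rows = []
    for pathway_id in sorted(gene_sets):
        members = set(gene_sets[pathway_id]) & universe
        K = len(members)
        if K == 0:
            logger.info("pathway %s has no overlap with the universe; skipped", pathway_id)
            continue
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"pathway_id": pathway_id, "K": K, "k": k, "N": N, "n": n, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows, columns=["pathway_id", "K", "k", "N", "n", "p"])
    if not df.empty:
        df["q"] = stats.false_discovery_control(df["p"].to_numpy(), method="bh")
        df = df.sort_values(["p", "pathway_id"], kind="mergesort", ignore_index=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df
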