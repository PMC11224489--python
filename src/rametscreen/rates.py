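"""Mutation-rate estimation, coverage summaries, and site/gene density.

The per-bp mutation rate is defined as

    rate = sum over samples of distinct mutated positions called in the
           sample  /  sum over samples of surveyed (callable) bp

with an exact (chi-square inversion) Poisson 95% CI on the numerator.  A
sample "carries" a variant when its alt read support exceeds the same
per-sample threshold the logic-tree uses (more than five reads by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .baits import Interval
from .screen import ClassifiedMutation
from .sites import CandidateSite

log = logging.getLogger(__name__)


@dataclass
class RateEstimate:
    genotype: str
    category: str  # off_target | somatic
    numerator: int  # mutated-position x sample events
    denominator: float  # summed surveyed bp over samples
    rate: float
    poisson_ci95: tuple[float, float]


@dataclass
class CoverageSummary:
    group: str
    n: int
    mean: float
    sd: float  # sample sd (n-1); nan for a single measurement
    cov: float  # sd / mean


def poisson_ci(n_events: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact Poisson CI on a count (one-sided lower bound 0 when n = 0)."""
    alpha = 1 - conf
    lo = stats.chi2.ppf(alpha / 2, 2 * n_events) / 2 if n_events > 0 else 0.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (n_events + 1)) / 2
    return float(lo), float(hi)


def surveyed_basepairs(
    pileups: pd.DataFrame, depth_floor: int = 20
) -> dict[str, int]:
    """Callable surveyed bp per sample: covered positions with depth >= floor."""
    depth = pileups.groupby(["sample", "chrom", "pos"], sort=False)["depth"].first()
    ok = depth[depth >= depth_floor]
    return ok.groupby(level="sample").size().to_dict()


def mutation_rate(
    classified: Iterable[ClassifiedMutation],
    surveyed_bp_per_sample: Mapping[str, float],
    category: str,
    carrier_min_alt: int = 6,
    count_mode: str = "sample_events",
    genotype: str = "all",
) -> RateEstimate:
    """Per-bp mutation rate for one category over the surveyed samples.

    ``count_mode="sample_events"`` counts (position, carrier sample) pairs,
    so a mutation fixed in many ramets weighs by its prevalence;
    ``"positions"`` counts distinct mutated positions once each.
    """
    denom = float(sum(surveyed_bp_per_sample.values()))
    if denom <= 0:
        raise ValueError("surveyed bp denominator is zero; rate undefined")
    samples = set(surveyed_bp_per_sample)
    carried: set[tuple] = set()
    for mut in classified:
        if mut.category != category:
            continue
        cand = mut.candidate
        for sample, (alt, _depth) in cand.per_sample.items():
            if sample in samples and alt >= carrier_min_alt:
                if count_mode == "sample_events":
                    carried.add((cand.chrom, cand.pos, sample))
                else:
                    carried.add((cand.chrom, cand.pos))
    n = len(carried)
    lo, hi = poisson_ci(n)
    return RateEstimate(
        genotype=genotype,
        category=category,
        numerator=n,
        denominator=denom,
        rate=n / denom,
        poisson_ci95=(lo / denom, hi / denom),
    )


def tile_windows(chrom_lengths: Mapping[str, int], window_bp: int) -> pd.DataFrame:
    """Tile each chromosome into fixed windows; the last partial one is kept
    and flagged."""
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, length, window_bp):
            end = min(start + window_bp, length)
            rows.append(
                {"chrom": chrom, "start": start, "end": end, "partial": end - start < window_bp}
            )
    return pd.DataFrame(rows)


def density_correlation(
    sites: Sequence[CandidateSite],
    genes: Sequence[Interval],
    chrom_lengths: Mapping[str, int],
    window_bp: int = 500_000,
) -> tuple[float, float, pd.DataFrame]:
    """Pearson correlation of gene count vs candidate-site count per window.

    Genes and sites are assigned to the window holding their midpoint.
    Raises on fewer than 3 windows or zero variance in either count (the
    correlation is undefined).
    """
    table = tile_windows(chrom_lengths, window_bp)
    if len(table) < 3:
        raise ValueError(f"only {len(table)} windows; need at least 3")
    gene_counts = np.zeros(len(table), dtype=int)
    site_counts = np.zeros(len(table), dtype=int)
    index: dict[str, list[int]] = {}
    for i, row in table.iterrows():
        index.setdefault(row["chrom"], []).append(i)

    def _window_of(chrom: str, pos: int) -> int | None:
        rows = index.get(chrom)
        if rows is None:
            return None
        j = pos // window_bp
        return rows[j] if j < len(rows) else None

    for g in genes:
        i = _window_of(g.chrom, (g.start + g.end) // 2)
        if i is not None:
            gene_counts[i] += 1
    for s in sites:
        i = _window_of(s.chrom, (s.start + s.end) // 2)
        if i is not None:
            site_counts[i] += 1
    table = table.assign(gene_count=gene_counts, site_count=site_counts)
    if gene_counts.std() == 0 or site_counts.std() == 0:
        raise ValueError("constant counts across windows; correlation undefined")
    r, p = stats.pearsonr(gene_counts, site_counts)
    return float(r), float(p), table


def coverage_summary(depths: pd.DataFrame, group_by: str = "construct") -> list[CoverageSummary]:
    """Depth summaries per group from per-site per-sample depth proxies.

    ``depths`` needs columns ``sample``, ``depth`` and the grouping column
    (e.g. ``construct`` or ``chrom``).  Depths are first averaged within
    sample, then each per-sample mean is one measurement: the summary is the
    mean, sample SD (n-1) and coefficient of variation of those means.  A
    group with a single measurement reports an undefined (NaN) SD.
    """
    if group_by not in depths.columns:
        raise KeyError(f"no column {group_by!r} in depth table")
    out = []
    for group, sub in depths.groupby(group_by, sort=True):
        per_sample = sub.groupby("sample")["depth"].mean()
        n = len(per_sample)
        mean = float(per_sample.mean())
        sd = float(per_sample.std(ddof=1)) if n > 1 else math.nan
        cov = sd / mean if (n > 1 and mean > 0) else math.nan
        out.append(CoverageSummary(group=str(group), n=n, mean=mean, sd=sd, cov=cov))
    return out
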