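"""PAM-relative allele-frequency and mutation-spectrum profiling.

Mirrors the manual read-counting protocol: a read is scored mutant when it
carries any non-reference base or indel breakpoint within the PAM-relative
window [+2 .. -5] (PAM bases +2 and +1, then protospacer bases -1 .. -5;
seven positions straddling the blunt cut between -3 and -4).  On pileup
tables the per-read bookkeeping is approximated by the maximum alt-allele
count over the window positions, which is exact when a mutant read carries
a single variant — the regime the screen operates in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .screen import ClassifiedMutation, SampleMeta, EDITED_ROLE, deletion_length
from .sites import CandidateSite

log = logging.getLogger(__name__)

DEFAULT_WINDOW = (2, -5)  # PAM-relative [window_start .. window_end], inclusive


@dataclass
class AFMeasurement:
    """Mutant allele frequency of one site in one sample.

    ``total_reads == 0`` flags a no-data (NR) measurement: the locus was not
    sequenced in the sample, which is distinct from an observed AF of 0.
    """

    sample_id: str
    site_id: str
    mutant_reads: int
    total_reads: int
    window: tuple[int, int] = DEFAULT_WINDOW

    @property
    def af(self) -> float:
        return self.mutant_reads / self.total_reads if self.total_reads else math.nan

    @property
    def no_data(self) -> bool:
        return self.total_reads == 0


@dataclass(frozen=True)
class SpectrumBin:
    pam_relative_position: int
    allele_count: int


def window_positions(site: CandidateSite, window_start: int = 2, window_end: int = -5) -> list[int]:
    """Forward-strand genomic positions of the PAM-relative counting window."""
    rels = [r for r in range(window_end, window_start + 1) if r != 0]
    return sorted(site.genomic_position(r) for r in rels)


def count_mutant_reads(
    pileup: pd.DataFrame,
    site: CandidateSite,
    window_start: int = 2,
    window_end: int = -5,
    sample_id: str | None = None,
) -> AFMeasurement:
    """Score one sample's reads over a site's PAM-relative counting window.

    ``pileup`` is a long-format pileup table; if it holds several samples,
    ``sample_id`` selects one.  Deletions whose left-aligned breakpoint
    interval intersects the window are counted even when anchored upstream
    of it.  Zero coverage anywhere in the window yields a no-data (NR)
    measurement rather than an AF of 0.
    """
    if sample_id is not None:
        pileup = pileup[pileup["sample"] == sample_id]
    else:
        samples = pileup["sample"].unique()
        if len(samples) > 1:
            raise ValueError("pileup holds several samples; pass sample_id")
        sample_id = samples[0] if len(samples) else ""

    gpos = window_positions(site, window_start, window_end)
    lo, hi = gpos[0], gpos[-1]
    near = pileup[
        (pileup["chrom"] == site.chrom)
        & (pileup["pos"] >= lo - 64)
        & (pileup["pos"] <= hi)
    ]
    depth_at: dict[int, int] = {}
    alt_at: dict[int, int] = {}
    denom_at: dict[int, int] = {}  # depth of the rows supplying each alt
    wset = set(gpos)
    for row in near.itertuples(index=False):
        pos, allele, count = row.pos, row.allele, row.count
        if pos in wset:
            depth_at[pos] = max(depth_at.get(pos, 0), int(row.depth))
        if allele == row.ref:
            continue
        if allele.startswith("del:"):
            span_end = pos + deletion_length(allele)  # half-open deleted span
            hit = [p for p in gpos if pos <= p < span_end]
        elif pos in wset:
            hit = [pos]
        else:
            hit = []
        for p in hit:
            alt_at[p] = alt_at.get(p, 0) + int(count)
            # the AF denominator must be the depth at the observation's
            # anchor, not an unrelated draw at a spanned position
            denom_at[p] = max(denom_at.get(p, 0), int(row.depth))
    if not depth_at or max(depth_at.values()) == 0:
        return AFMeasurement(sample_id, site.site_id, 0, 0, (window_start, window_end))
    if alt_at:
        # denominator per position: the depth of the rows that supplied the
        # observations (for a spanned deletion, its anchor), not an
        # unrelated draw; pick the position with the strongest mutant
        # fraction, which is the variant's anchor in practice
        def _frac(p):
            denom = max(denom_at.get(p, depth_at.get(p, 0)), alt_at[p])
            return alt_at[p] / denom if denom else 0.0

        best = max(alt_at, key=lambda p: (_frac(p), alt_at[p], -p))
        mutant = alt_at[best]
        total = max(denom_at.get(best, depth_at.get(best, 0)), mutant)
    else:
        # no mutant reads: report the median window depth as the total, a
        # representative locus coverage (the max would overstate it)
        mutant, total = 0, int(np.median(list(depth_at.values())))
    return AFMeasurement(sample_id, site.site_id, int(mutant), int(total), (window_start, window_end))


def af_matrix(
    pileups: pd.DataFrame,
    sites: Sequence[CandidateSite],
    metadata: Sequence[SampleMeta],
    window_start: int = 2,
    window_end: int = -5,
) -> list[AFMeasurement]:
    """AF measurements for every (site, sample) pair."""
    out = []
    for sample in metadata:
        sub = pileups[pileups["sample"] == sample.sample_id]
        for site in sites:
            out.append(
                count_mutant_reads(
                    sub, site, window_start, window_end, sample_id=sample.sample_id
                )
            )
    return out


def pam_spectrum(
    mutations: Iterable[ClassifiedMutation],
    group: str | None = None,
) -> list[SpectrumBin]:
    """Histogram of mutation counts by PAM-relative position.

    ``group="target"`` keeps mutations at on-target (0-mismatch) sites,
    ``group="off_target"`` those at degenerate sites; ``None`` keeps all.
    Positions without counts are filled in over the observed range (position
    0 does not exist in PAM-relative coordinates and is never emitted).
    """
    counts: dict[int, int] = {}
    for mut in mutations:
        if mut.pam_relative_position is None or mut.nearest_site is None:
            continue
        on = mut.nearest_site.is_on_target
        if group == "target" and not on:
            continue
        if group == "off_target" and on:
            continue
        pos = mut.pam_relative_position
        counts[pos] = counts.get(pos, 0) + 1
    if not counts:
        return []
    lo, hi = min(counts), max(counts)
    return [
        SpectrumBin(p, counts.get(p, 0))
        for p in range(lo, hi + 1)
        if p != 0
    ]


def expand_by_carriers(
    mutations: Iterable[ClassifiedMutation], min_alt: int = 6
) -> list[ClassifiedMutation]:
    """Repeat each mutation once per carrier sample (alt support >= min_alt),
    so spectra weigh alleles by their prevalence across mutated ramets."""
    out = []
    for m in mutations:
        carriers = sum(
            1 for _s, (alt, _d) in m.candidate.per_sample.items() if alt >= min_alt
        )
        out.extend([m] * max(carriers, 1))
    return out


def modal_position(spectrum: Sequence[SpectrumBin]) -> int:
    """Position of the fullest bin (ties break toward the PAM)."""
    if not spectrum:
        raise ValueError("empty spectrum")
    return max(spectrum, key=lambda b: (b.allele_count, b.pam_relative_position)).pam_relative_position


def merge_phased(
    hap_a: AFMeasurement,
    hap_b: AFMeasurement,
    correspondence: Mapping[str, str] | None = None,
) -> AFMeasurement:
    """Merge the two haplotype copies of one site into a single measurement.

    Counts are pooled (read-count-weighted mean AF).  When a correspondence
    table is supplied and does not pair the two site ids, the first
    measurement passes through unchanged with a warning.  A no-data
    haplotype contributes nothing.
    """
    if correspondence is not None and correspondence.get(hap_a.site_id) != hap_b.site_id:
        log.warning(
            "no haplotype correspondence between %s and %s; passing through",
            hap_a.site_id, hap_b.site_id,
        )
        return hap_a
    merged_id = f"{hap_a.site_id}|{hap_b.site_id}"
    return AFMeasurement(
        sample_id=hap_a.sample_id,
        site_id=merged_id,
        mutant_reads=hap_a.mutant_reads + hap_b.mutant_reads,
        total_reads=hap_a.total_reads + hap_b.total_reads,
        window=hap_a.window,
    )


def sharing_statistics(
    afs: Iterable[AFMeasurement],
    metadata: Sequence[SampleMeta],
    af_threshold: float = 0.10,
    within: float = 0.05,
) -> pd.DataFrame:
    """Per-site event/ramet sharing summary among clonal ramets.

    For each site, events with at least two ramets are scored as *shared*
    (every ramet strictly exceeds ``af_threshold``), *single-ramet* (exactly
    one does), or unedited.  Fractions are reported among edited events,
    plus the fraction of single-ramet events whose two ramet AFs lie within
    ``within`` of each other.  Single-ramet events (in the metadata sense:
    an event with one sample) are excluded with a log note.
    """
    by_event: dict[str, list[str]] = {}
    for m in metadata:
        if m.role == EDITED_ROLE:
            by_event.setdefault(m.event, []).append(m.sample_id)
    usable = {}
    for event, samples in by_event.items():
        if len(samples) < 2:
            log.info("event %s has a single ramet; excluded from sharing statistics", event)
        else:
            usable[event] = samples
    af_lookup: dict[tuple[str, str], AFMeasurement] = {
        (m.site_id, m.sample_id): m for m in afs
    }
    sample_event = {m.sample_id: m.event for m in metadata}

    rows = []
    site_ids = sorted({sid for sid, _ in af_lookup})
    for site_id in site_ids:
        n_edited = n_shared = n_single = n_single_close = 0
        for event, samples in usable.items():
            vals = [
                af_lookup[(site_id, s)].af
                for s in samples
                if (site_id, s) in af_lookup and not af_lookup[(site_id, s)].no_data
            ]
            if len(vals) < 2:
                continue
            above = [v > af_threshold for v in vals]
            if not any(above):
                continue
            n_edited += 1
            if all(above):
                n_shared += 1
            elif sum(above) == 1:
                n_single += 1
                if max(vals) - min(vals) <= within:
                    n_single_close += 1
        rows.append(
            {
                "site_id": site_id,
                "n_edited_events": n_edited,
                "shared_fraction": n_shared / n_edited if n_edited else math.nan,
                "single_ramet_fraction": n_single / n_edited if n_edited else math.nan,
                "single_ramet_within_margin_fraction": (
                    n_single_close / n_single if n_single else math.nan
                ),
            }
        )
    return pd.DataFrame(rows)
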