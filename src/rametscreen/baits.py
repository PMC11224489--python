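"""Capture-probe (bait) design over candidate sites.

80 bp probes are centered on each candidate site; the probe spans double as
the screening/coverage intervals downstream.  No hybridization
thermodynamics are modeled — ``flank_offset`` is a generic stand-in for
shifting a probe into flanking sequence when the centered one is unusable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .sites import CandidateSite, _as_sequences

log = logging.getLogger(__name__)

DEFAULT_BAIT_LENGTH = 80


@dataclass
class BaitProbe:
    site_id: str
    chrom: str
    start: int
    end: int
    sequence: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty probe span")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"degenerate interval {self.chrom}:{self.start}-{self.end}")


def design_baits(
    sites: Iterable[CandidateSite],
    genome,
    length: int = DEFAULT_BAIT_LENGTH,
    flank_offset: int = 0,
) -> list[BaitProbe]:
    """One fixed-length probe per site, centered on the site span.

    The probe midpoint is the site midpoint (odd spans round toward the
    lower coordinate), optionally shifted by ``flank_offset``.  Probes that
    would overhang a contig edge are shifted inward to keep full length;
    sites on contigs shorter than ``length`` are skipped with a warning.
    """
    seqs = _as_sequences(genome)
    probes = []
    for site in sites:
        contig = seqs.get(site.chrom)
        if contig is None:
            raise KeyError(f"site on unknown sequence {site.chrom!r}")
        clen = len(contig)
        if clen < length:
            log.warning("skipping %s: contig %s shorter than bait length", site.site_id, site.chrom)
            continue
        mid = (site.start + site.end) // 2
        start = mid - length // 2 + flank_offset
        start = min(max(start, 0), clen - length)
        probes.append(
            BaitProbe(
                site_id=site.site_id,
                chrom=site.chrom,
                start=start,
                end=start + length,
                sequence=contig[start : start + length],
            )
        )
    return probes


def intervals_from_baits(
    baits: Iterable[BaitProbe], merge_overlaps: bool = False
) -> list[Interval]:
    """Screening intervals from probes: one per probe, or a sorted union."""
    ivs = sorted(
        (Interval(b.chrom, b.start, b.end, label=b.site_id) for b in baits),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    if not merge_overlaps or not ivs:
        return ivs
    merged = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom == last.chrom and iv.start <= last.end:
            merged[-1] = Interval(last.chrom, last.start, max(last.end, iv.end), last.label)
        else:
            merged.append(iv)
    return merged


def interval_positions(intervals: Iterable[Interval]) -> dict[str, "set[int]"]:
    """All covered positions per chromosome (for membership checks)."""
    pos: dict[str, set[int]] = {}
    for iv in intervals:
        pos.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    return pos
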