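"""Pooled tumor/normal-style variant screen and the manual filtering logic-tree.

Samples are partitioned per genotype into a "normal" pool (wild-type and
Cas9-only controls) and a "tumor" pool (edited events and their clonal
ramets).  Candidates are (position, alt allele) pairs whose pooled edited
read support and allele frequency stand out against the pooled controls;
survivors of the logic-tree are classified as off-target (within 20 bp of a
degenerate guide-matching site) or somatic (beyond it).

Pileup tables are long-format DataFrames with columns
``sample, chrom, pos, ref, depth, allele, count`` (0-based positions).
Alleles are the four bases, ``del:<L>`` for an L-bp deletion whose first
deleted base is ``pos``, or ``ins:<SEQ>`` for SEQ inserted after ``pos``;
the row with ``allele == ref`` carries the reference-supporting reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .baits import Interval, interval_positions
from .sites import CandidateSite, _as_sequences

log = logging.getLogger(__name__)

CONTROL_ROLES = frozenset({"wild_type", "cas9_only"})
EDITED_ROLE = "edited"

PILEUP_COLUMNS = ["sample", "chrom", "pos", "ref", "depth", "allele", "count"]


class ConfigurationError(ValueError):
    """The sample metadata does not support the requested contrast."""


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    genotype: str
    construct: str
    event: str  # empty for controls
    ramet: int
    role: str  # wild_type | cas9_only | edited

    def __post_init__(self):
        if self.role not in CONTROL_ROLES | {EDITED_ROLE}:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role in CONTROL_ROLES and self.event:
            raise ValueError(f"control sample {self.sample_id} must not carry an event id")


def is_indel(allele: str) -> bool:
    return allele.startswith(("del:", "ins:"))


def deletion_length(allele: str) -> int:
    return int(allele.split(":", 1)[1]) if allele.startswith("del:") else 0


@dataclass
class VariantCandidate:
    """A screened variant with pooled and per-sample read support."""

    chrom: str
    pos: int  # 0-based; first deleted base / insertion anchor for indels
    ref: str
    alt: str
    genotype: str = ""
    per_sample: dict[str, tuple[int, int]] = field(default_factory=dict)  # sample -> (alt, depth)
    tumor_alt: int = 0
    tumor_depth: int = 0
    normal_alt: int = 0
    normal_depth: int = 0
    filter_status: set[str] = field(default_factory=set)

    @property
    def tumor_af(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0

    @property
    def normal_af(self) -> float:
        return self.normal_alt / self.normal_depth if self.normal_depth else 0.0

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def sample_af(self, sample_id: str) -> float:
        alt, depth = self.per_sample.get(sample_id, (0, 0))
        return alt / depth if depth else 0.0


@dataclass
class ClassifiedMutation:
    candidate: VariantCandidate
    category: str  # off_target | somatic
    nearest_site: CandidateSite | None = None
    distance_to_site_border: int | None = None
    pam_relative_position: int | None = None


def _meta_by_sample(metadata: Iterable[SampleMeta]) -> dict[str, SampleMeta]:
    return {m.sample_id: m for m in metadata}


def _pools(metadata: Iterable[SampleMeta]) -> dict[str, tuple[list[str], list[str]]]:
    """Per genotype: (normal sample ids, tumor sample ids)."""
    pools: dict[str, tuple[list[str], list[str]]] = {}
    for m in metadata:
        normals, tumors = pools.setdefault(m.genotype, ([], []))
        (normals if m.role in CONTROL_ROLES else tumors).append(m.sample_id)
    for genotype, (normals, tumors) in pools.items():
        if tumors and not normals:
            raise ConfigurationError(
                f"genotype {genotype!r} has edited samples but no controls; "
                "the tumor/normal contrast is undefined"
            )
    return pools


def detect_candidates(
    pileups: pd.DataFrame,
    metadata: Sequence[SampleMeta],
    intervals: Sequence[Interval] | None = None,
    min_alt_reads: int = 6,
    min_tumor_vs_normal_ratio: float = 3.0,
    error_rate: float = 1e-3,
) -> list[VariantCandidate]:
    """Pooled-contrast screen of edited samples against controls.

    A candidate is emitted for every (position, alt allele) whose pooled
    edited-sample support reaches ``min_alt_reads`` and whose pooled edited
    AF exceeds ``min_tumor_vs_normal_ratio`` times the pooled control AF
    (floored at ``error_rate`` so that control dropout cannot produce an
    infinite ratio).  Per-sample counts are attached for the logic-tree.
    """
    pools = _pools(metadata)
    if intervals is not None:
        keep = interval_positions(intervals)
        mask = [
            (chrom in keep and pos in keep[chrom])
            for chrom, pos in zip(pileups["chrom"], pileups["pos"])
        ]
        pileups = pileups.loc[mask]

    meta = _meta_by_sample(metadata)
    pileups = pileups[pileups["sample"].isin(meta)]
    # per-sample depth at every covered position
    depth = (
        pileups.groupby(["sample", "chrom", "pos"], sort=False)["depth"].first()
    )
    alt_rows = pileups[pileups["allele"] != pileups["ref"]]

    candidates: list[VariantCandidate] = []
    for genotype, (normals, tumors) in pools.items():
        if not tumors:
            continue
        nset, tset = set(normals), set(tumors)
        rows = alt_rows[alt_rows["sample"].isin(nset | tset)]
        grouped = rows.groupby(["chrom", "pos", "ref", "allele"], sort=True)
        for (chrom, pos, ref, allele), grp in grouped:
            counts = dict(zip(grp["sample"], grp["count"]))
            t_alt = sum(c for s, c in counts.items() if s in tset)
            if t_alt < min_alt_reads:
                continue
            t_depth = sum(
                int(depth.get((s, chrom, pos), 0)) for s in tumors
            )
            n_alt = sum(c for s, c in counts.items() if s in nset)
            n_depth = sum(int(depth.get((s, chrom, pos), 0)) for s in normals)
            t_af = t_alt / t_depth if t_depth else 0.0
            n_af = n_alt / n_depth if n_depth else 0.0
            if t_af <= min_tumor_vs_normal_ratio * max(n_af, error_rate):
                continue
            per_sample = {
                s: (int(counts.get(s, 0)), int(depth.get((s, chrom, pos), 0)))
                for s in normals + tumors
            }
            candidates.append(
                VariantCandidate(
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=allele,
                    genotype=genotype,
                    per_sample=per_sample,
                    tumor_alt=int(t_alt),
                    tumor_depth=int(t_depth),
                    normal_alt=int(n_alt),
                    normal_depth=int(n_depth),
                )
            )
    candidates.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt, c.genotype))
    log.info("detected %d candidate variants", len(candidates))
    return candidates


def _in_homopolymer(genome_seqs: Mapping[str, str], chrom: str, pos: int, min_run: int) -> bool:
    seq = genome_seqs.get(chrom)
    if seq is None or not 0 <= pos < len(seq):
        return False
    base = seq[pos]
    left = pos
    while left > 0 and seq[left - 1] == base:
        left -= 1
    right = pos
    while right + 1 < len(seq) and seq[right + 1] == base:
        right += 1
    return right - left + 1 >= min_run


def apply_filter_tree(
    candidates: Iterable[VariantCandidate],
    metadata: Sequence[SampleMeta],
    genome=None,
    similarity_margin: float = 0.5,
    max_per_sample_support: int = 5,
    recurrence_fraction: float = 0.9,
    recurrence_min_af: float = 0.05,
    homopolymer_run: int = 8,
) -> list[VariantCandidate]:
    """Apply the manual scoring logic-tree; every exclusion reason is recorded.

    low_support
        no single sample supports the alt with more than
        ``max_per_sample_support`` reads.
    in_normal
        the pooled control AF is at least ``similarity_margin`` times the
        pooled edited AF (the controls show "similar" frequencies).
    alignment_artifact
        the alt recurs at appreciable AF (>= ``recurrence_min_af``) in at
        least ``recurrence_fraction`` of all samples including controls, or
        an indel alt falls in a reference homopolymer run of
        ``homopolymer_run`` bp or more (requires ``genome``).
    """
    seqs = _as_sequences(genome) if genome is not None else None
    out = []
    n_samples = len(metadata)
    for cand in candidates:
        status: set[str] = set()
        if max(
            (alt for alt, _ in cand.per_sample.values()), default=0
        ) <= max_per_sample_support:
            status.add("low_support")
        if cand.tumor_af > 0 and cand.normal_af >= similarity_margin * cand.tumor_af:
            status.add("in_normal")
        recur = sum(
            1
            for s, (alt, depth) in cand.per_sample.items()
            if depth and alt / depth >= recurrence_min_af
        )
        if n_samples and recur / n_samples >= recurrence_fraction:
            status.add("alignment_artifact")
        if (
            seqs is not None
            and is_indel(cand.alt)
            and _in_homopolymer(seqs, cand.chrom, cand.pos, homopolymer_run)
        ):
            status.add("alignment_artifact")
        if not status:
            status.add("pass")
        else:
            log.debug("excluded %s:%d %s>%s: %s", cand.chrom, cand.pos, cand.ref, cand.alt,
                      ",".join(sorted(status)))
        cand.filter_status = status
        out.append(cand)
    by_reason: dict[str, int] = {}
    for cand in out:
        for reason in cand.filter_status:
            by_reason[reason] = by_reason.get(reason, 0) + 1
    log.info("filter tree: %s", by_reason)
    return out


def passing(candidates: Iterable[VariantCandidate]) -> list[VariantCandidate]:
    return [c for c in candidates if c.filter_status == {"pass"}]


def _altered_span(cand: VariantCandidate) -> tuple[int, int]:
    """Forward-strand span [first, last] of bases touched by the variant."""
    if cand.alt.startswith("del:"):
        L = deletion_length(cand.alt)
        return cand.pos, cand.pos + L - 1
    if cand.alt.startswith("ins:"):
        return cand.pos, cand.pos + 1  # the flanking junction bases
    return cand.pos, cand.pos


def classify_mutation(
    candidate: VariantCandidate,
    sites: Sequence[CandidateSite],
    window: int = 20,
) -> ClassifiedMutation:
    """Bin a passing variant as off-target or somatic.

    Distance is from the variant position to the nearest border of the
    nearest site span (0 inside the span); within ``window`` bp (inclusive)
    the variant is off_target, beyond it somatic.  Ties between sites break
    by distance, then by fewer mismatches.  The PAM-relative position is the
    signed coordinate of the altered base closest to the PAM (so a deletion
    spanning several protospacer bases reports its cut-proximal end).
    """
    best: tuple[int, int, CandidateSite] | None = None
    for site in sites:
        if site.chrom != candidate.chrom:
            continue
        if candidate.pos < site.start:
            dist = site.start - candidate.pos
        elif candidate.pos >= site.end:
            dist = candidate.pos - (site.end - 1)
        else:
            dist = 0
        rank = (dist, site.mismatches)
        if best is None or rank < (best[0], best[1]):
            best = (dist, site.mismatches, site)
    if best is None or best[0] > window:
        return ClassifiedMutation(
            candidate=candidate,
            category="somatic",
            nearest_site=best[2] if best else None,
            distance_to_site_border=best[0] if best else None,
        )
    site = best[2]
    lo, hi = _altered_span(candidate)
    pam_rel = max(site.pam_relative(lo), site.pam_relative(hi))
    return ClassifiedMutation(
        candidate=candidate,
        category="off_target",
        nearest_site=site,
        distance_to_site_border=best[0],
        pam_relative_position=pam_rel,
    )


def classify_all(
    candidates: Iterable[VariantCandidate],
    sites: Sequence[CandidateSite],
    window: int = 20,
) -> list[ClassifiedMutation]:
    return [classify_mutation(c, sites, window=window) for c in candidates]


def confirm_offtarget_events(
    afs,
    metadata: Sequence[SampleMeta],
    af_threshold: float = 0.10,
    min_ramets: int = 2,
) -> list[str]:
    """Sites where at least ``min_ramets`` edited samples strictly exceed
    ``af_threshold`` mutant allele frequency.

    ``afs`` is an iterable of :class:`~rametscreen.profiles.AFMeasurement`
    (site x sample); no-data measurements never count toward confirmation.
    """
    edited = {m.sample_id for m in metadata if m.role == EDITED_ROLE}
    exceed: dict[str, int] = {}
    for m in afs:
        if m.sample_id not in edited or m.no_data:
            continue
        if m.af > af_threshold:
            exceed[m.site_id] = exceed.get(m.site_id, 0) + 1
    return sorted(site for site, n in exceed.items() if n >= min_ramets)
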