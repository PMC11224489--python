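"""Truth-known synthetic cohorts for the off-target/somatic mutation survey.

Emulates the study design the pipeline is built for: a clonally propagated
cohort with wild-type and Cas9-only controls, several independent transgene
insertion events with two clonal ramets each, ~80 bp capture windows around
degenerate guide-matching sites, CRISPR indels concentrated at the canonical
blunt-cut position (protospacer -3 relative to the PAM), and rare background
somatic mutations.  Reads are abstracted as per-position allele-observation
counts (pileup tables) rather than simulated FASTQ: the analysis consumes
allele counts, and a thin adapter can populate the same tables from real
pileups.

Everything is deterministic under a fixed seed; the returned truth ledger is
exhaustive (all non-error variation is planted and recorded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .baits import Interval
from .screen import SampleMeta, EDITED_ROLE, PILEUP_COLUMNS, deletion_length
from .sites import CandidateSite, GuideSpec, enumerate_sites, revcomp

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

#: spacers used throughout the synthetic cohorts (the study's own guide
#: sequences are not published; these are arbitrary fixed 20-mers)
DEFAULT_GUIDES = (
    GuideSpec("g1", "GTCACCTCGAGGATTACGCC", "NGG", target_locus_name="locusA"),
    GuideSpec("g2", "TACGGATCCTGAAGGCTCAT", "NGG", target_locus_name="locusB"),
)


class GenerationError(RuntimeError):
    """Planting could not satisfy its constraints after bounded retries."""


@dataclass(frozen=True)
class PlantedSiteSpec:
    """Request for one planted locus: guide, degeneracy, and editing behaviour.

    ``propensity`` is the fraction of cells (per susceptible haplotype) that
    carry the edit in an event; with ``allelicity="bi"`` the event-level true
    allele fraction equals the propensity, with ``"mono"`` only one of the two
    alleles is editable and the pooled fraction is capped at propensity / 2.
    """

    guide_name: str
    mismatches: int
    bulge: str = "none"
    propensity: float = 1.0
    allelicity: str = "bi"

    def __post_init__(self):
        if not 0.0 <= self.propensity <= 1.0:
            raise ValueError("propensity must be in [0, 1]")
        if self.allelicity not in ("mono", "bi"):
            raise ValueError("allelicity must be 'mono' or 'bi'")


@dataclass
class PlantedSite:
    site: CandidateSite
    allelicity: str
    propensity: float

    @property
    def true_event_af(self) -> float:
        return self.propensity if self.allelicity == "bi" else self.propensity / 2.0

    @property
    def af_cap(self) -> float:
        return 1.0 if self.allelicity == "bi" else 0.5


def _default_planted() -> tuple[PlantedSiteSpec, ...]:
    return (
        # on-target loci, scored through the same machinery as off-targets
        PlantedSiteSpec("g1", 0, "none", propensity=1.0),
        PlantedSiteSpec("g2", 0, "none", propensity=1.0),
        # degenerate off-targets spanning the editing range surveyed
        PlantedSiteSpec("g1", 2, "none", propensity=0.05),
        PlantedSiteSpec("g2", 3, "none", propensity=0.10),
        PlantedSiteSpec("g1", 4, "none", propensity=0.15),
        PlantedSiteSpec("g2", 5, "none", propensity=0.50),
        PlantedSiteSpec("g1", 4, "dna", propensity=1.00),
    )


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the surveyed design: 8 insertion events with 2 clonal
    ramets each, 6 pooled controls, ~200x capture depth with substantial
    dispersion, a 1e-3 per-base observation error rate, planted off-target
    allele fractions spanning 0.05-1.0, and rare background somatic
    mutations.
    """

    n_chromosomes: int = 2
    chromosome_length: int = 50_000
    n_genes: int = 40
    gene_length: int = 1_000
    gene_density_profile: Sequence[float] | None = None  # per-window weights, recycled
    density_window_bp: int = 5_000
    guides: Sequence[GuideSpec] = DEFAULT_GUIDES
    planted_offtargets: Sequence[PlantedSiteSpec] = field(default_factory=_default_planted)
    n_events: int = 8
    ramets_per_event: int = 2
    n_control_samples: int = 6
    depth_mean: float = 200.0
    depth_sd: float = 60.0
    error_rate: float = 1e-3
    somatic_rate: float = 5e-8  # mutations per surveyed bp per sample
    somatic_af_range: tuple[float, float] = (0.10, 0.50)
    somatic_indel_fraction: float = 0.1
    ramet_jitter_sd: float = 0.02
    deletion_geom_p: float = 0.5
    max_deletion: int = 10
    insertion_fraction: float = 0.2
    genotype: str = "G1"
    construct: str = "C1"

    def __post_init__(self):
        if min(self.n_chromosomes, self.n_events, self.ramets_per_event) < 1:
            raise ValueError("counts must be positive")
        if self.n_control_samples < 0 or self.n_genes < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.somatic_rate <= 1e-3:
            raise ValueError("somatic_rate out of [0, 1e-3]")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate out of range")


@dataclass
class SyntheticTruth:
    """Ledger of everything planted: the recovery surface for all tests."""

    planted_sites: list[PlantedSite]
    site_afs: pd.DataFrame  # site_id, sample, true_af, alt
    somatic: pd.DataFrame  # sample, chrom, pos, ref, alt, true_af


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_genome(
    config: CohortConfig, seed
) -> tuple[dict[str, str], list[Interval]]:
    """Random genome plus gene intervals drawn from the density profile.

    Genes land in fixed tiling windows with probability proportional to
    ``gene_density_profile`` (recycled across all windows genome-wide;
    uniform when absent), then uniformly within the window.
    """
    rng = _rng(seed)
    genome = {
        f"chr{i + 1}": "".join(BASES[rng.integers(0, 4, config.chromosome_length)])
        for i in range(config.n_chromosomes)
    }
    windows = []
    for chrom, seq in genome.items():
        for start in range(0, len(seq), config.density_window_bp):
            windows.append((chrom, start, min(start + config.density_window_bp, len(seq))))
    if config.gene_density_profile is None:
        weights = np.ones(len(windows))
    else:
        prof = np.asarray(config.gene_density_profile, dtype=float)
        reps = int(np.ceil(len(windows) / len(prof)))
        weights = np.tile(prof, reps)[: len(windows)]
    weights = weights / weights.sum()
    genes = []
    for i in range(config.n_genes):
        w = rng.choice(len(windows), p=weights)
        chrom, wstart, wend = windows[w]
        hi = max(wstart + 1, min(wend, len(genome[chrom]) - config.gene_length))
        start = int(rng.integers(wstart, hi))
        genes.append(
            Interval(chrom, start, min(start + config.gene_length, len(genome[chrom])),
                     label=f"gene{i + 1:04d}")
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genome, genes


def _degenerate_window(rng: np.random.Generator, spacer: str, spec: PlantedSiteSpec) -> str:
    """A genomic window scoring `spec.mismatches` against the spacer under
    `spec.bulge` (before verification)."""
    window = list(spacer)
    if spec.bulge == "rna":
        del window[int(rng.integers(1, len(window) - 1))]
    elif spec.bulge == "dna":
        window.insert(int(rng.integers(1, len(window))), str(rng.choice(BASES)))
    positions = rng.choice(len(window), size=spec.mismatches, replace=False)
    for p in positions:
        window[p] = str(rng.choice([b for b in "ACGT" if b != window[p]]))
    return "".join(window)


def plant_sites(
    genome: Mapping[str, str],
    guides: Sequence[GuideSpec],
    planted_offtargets: Sequence[PlantedSiteSpec],
    seed,
    max_mm: int = 5,
    max_mm_bulged: int = 4,
    pam_rules: Sequence[str] = ("NGG", "NRG"),
    min_separation: int = 200,
    max_retries: int = 60,
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Write degenerate guide-matching loci into a genome, with verification.

    Every planted locus is re-scanned through :func:`enumerate_sites` on a
    local fragment; a placement is accepted only when the enumerator reports
    it with exactly the requested mismatch count and bulge mode (so a DNA
    bulge that happens to align better bulge-free, say, is rejection-sampled
    away).  Placements keep ``min_separation`` bp from one another.
    """
    rng = _rng(seed)
    seqs = {name: bytearray(seq.upper(), "ascii") for name, seq in genome.items()}
    by_name = {g.name: g for g in guides}
    occupied: list[tuple[str, int, int]] = []
    planted: list[PlantedSite] = []

    for spec in planted_offtargets:
        guide = by_name.get(spec.guide_name)
        if guide is None:
            raise GenerationError(f"planted spec references unknown guide {spec.guide_name!r}")
        limit = max_mm if spec.bulge == "none" else max_mm_bulged
        if spec.mismatches > limit:
            raise GenerationError(
                f"{spec.mismatches} mismatches with bulge={spec.bulge} exceeds the "
                "enumeration thresholds; the site would never be recovered"
            )
        placed = None
        for _ in range(max_retries):
            window = _degenerate_window(rng, guide.spacer, spec)
            pam = str(rng.choice(BASES)) + "GG"
            oriented = window + pam
            strand = "+" if rng.random() < 0.5 else "-"
            insert = oriented if strand == "+" else revcomp(oriented)
            chrom = f"chr{int(rng.integers(1, len(seqs) + 1))}"
            contig = seqs[chrom]
            span = len(insert)
            start = int(rng.integers(100, len(contig) - span - 100))
            end = start + span
            if any(
                c == chrom and start - min_separation < e and end + min_separation > s
                for c, s, e in occupied
            ):
                continue
            original = contig[start:end]
            contig[start:end] = insert.encode("ascii")
            pad = 30
            frag = contig[max(0, start - pad) : end + pad].decode("ascii")
            offset = max(0, start - pad)
            # the planted locus must be the only enumerable site in its
            # neighbourhood (for any guide): overlapping shadow
            # interpretations at adjacent PAM anchors would otherwise
            # capture the edit during classification
            found = enumerate_sites(
                {chrom: frag}, guides, max_mm, max_mm_bulged, pam_rules
            )
            if (
                len(found) == 1
                and found[0].guide_name == guide.name
                and found[0].strand == strand
                and found[0].start + offset == start
                and found[0].end + offset == end
                and found[0].mismatches == spec.mismatches
                and found[0].bulge == spec.bulge
            ):
                site = replace(
                    found[0],
                    start=start,
                    end=end,
                    pam_relative_origin=found[0].pam_relative_origin + offset,
                )
                placed = PlantedSite(site=site, allelicity=spec.allelicity,
                                     propensity=spec.propensity)
                occupied.append((chrom, start, end))
                break
            contig[start:end] = original  # revert and retry
        if placed is None:
            raise GenerationError(
                f"could not place {spec} without collision after {max_retries} tries"
            )
        planted.append(placed)
    return {name: seq.decode("ascii") for name, seq in seqs.items()}, planted


def build_samples(config: CohortConfig) -> list[SampleMeta]:
    """Sample sheet: controls (wild-type / Cas9-only alternating) + events."""
    samples = []
    for i in range(config.n_control_samples):
        role = "wild_type" if i % 2 == 0 else "cas9_only"
        prefix = "WT" if role == "wild_type" else "CAS"
        samples.append(
            SampleMeta(f"{prefix}{i + 1:02d}", config.genotype, config.construct, "", 1, role)
        )
    for e in range(config.n_events):
        event = f"E{e + 1:02d}"
        for r in range(config.ramets_per_event):
            samples.append(
                SampleMeta(f"{event}_R{r + 1}", config.genotype, config.construct,
                           event, r + 1, EDITED_ROLE)
            )
    return samples


def _draw_edit_allele(rng: np.random.Generator, config: CohortConfig,
                      site: CandidateSite, genome: Mapping[str, str]) -> tuple[int, str, str]:
    """(pos, ref, alt) for a CRISPR edit anchored at the blunt-cut position.

    Deletions start at protospacer -3 and extend PAM-distally; insertions sit
    in the cut between -3 and -4.  The returned ``pos`` is the first deleted
    base, or the insertion anchor (base after which the sequence goes in).
    """
    seq = genome[site.chrom]
    cut_pos = site.genomic_position(-3)
    if rng.random() < config.insertion_fraction:
        ins = str(rng.choice(BASES))
        # anchor on the PAM-distal side of the cut so the inserted sequence
        # lands in the scissile junction for either strand
        pos = cut_pos - 1 if site.strand == "+" else cut_pos
        return pos, seq[pos], f"ins:{ins}"
    length = int(min(rng.geometric(config.deletion_geom_p), config.max_deletion))
    if site.strand == "+":
        pos = cut_pos - length + 1
    else:
        pos = cut_pos
    return pos, seq[pos], f"del:{length}"


def _negative_binomial_depth(
    rng: np.random.Generator, mean: float, sd: float, size
) -> np.ndarray:
    var = sd * sd
    if var <= mean:
        return rng.poisson(mean, size=size)
    n = mean * mean / (var - mean)
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def simulate_pileups(
    config: CohortConfig,
    genome: Mapping[str, str],
    planted: Sequence[PlantedSite],
    intervals: Sequence[Interval],
    seed,
) -> tuple[pd.DataFrame, list[SampleMeta], SyntheticTruth]:
    """Per-sample allele-observation tables over the capture intervals.

    Depth per (sample, position) is negative-binomial with the configured
    mean/SD; mutant reads at planted sites are binomial at each ramet's true
    allele fraction (event AF plus truncated-normal ramet jitter, capped at
    0.5 for mono-allelic sites); sequencing errors land uniformly across the
    three non-reference bases at the per-base error rate; somatic mutations
    arise in edited samples, uniformly over interval positions more than
    20 bp from any planted-site border.
    """
    rng = _rng(seed)
    samples = build_samples(config)
    edited_samples = [s for s in samples if s.role == EDITED_ROLE]

    positions: list[tuple[str, int]] = []
    seen = set()
    for iv in sorted(intervals, key=lambda v: (v.chrom, v.start)):
        for p in range(iv.start, iv.end):
            if (iv.chrom, p) not in seen:
                seen.add((iv.chrom, p))
                positions.append((iv.chrom, p))
    refs = np.array([genome[c][p] for c, p in positions])
    pos_index = {cp: i for i, cp in enumerate(positions)}

    # --- event-level edits at planted sites -------------------------------
    # variants[(sample, j)] -> list of (allele, af); j indexes `positions`
    variants: dict[tuple[str, int], list[tuple[str, float]]] = {}
    truth_site_rows = []
    events = sorted({s.event for s in edited_samples})
    for ps in planted:
        per_event_allele = {}
        per_event_pos = {}
        for event in events:
            pos, ref, alt = _draw_edit_allele(rng, config, ps.site, genome)
            per_event_allele[event] = alt
            per_event_pos[event] = (pos, ref)
        for s in samples:
            if s.role != EDITED_ROLE:
                truth_site_rows.append(
                    {"site_id": ps.site.site_id, "sample": s.sample_id,
                     "true_af": 0.0, "alt": ""}
                )
                continue
            base = ps.true_event_af
            af = float(np.clip(base + rng.normal(0.0, config.ramet_jitter_sd), 0.0, ps.af_cap))
            if base == 0.0:
                af = 0.0
            pos, ref = per_event_pos[s.event]
            alt = per_event_allele[s.event]
            j = pos_index.get((ps.site.chrom, pos))
            if j is None:
                raise GenerationError(
                    f"planted edit at {ps.site.chrom}:{pos} falls outside the intervals"
                )
            if af > 0:
                variants.setdefault((s.sample_id, j), []).append((alt, af))
            truth_site_rows.append(
                {"site_id": ps.site.site_id, "sample": s.sample_id,
                 "true_af": af, "alt": alt}
            )

    # --- background somatic mutations -------------------------------------
    guard = set()
    for ps in planted:
        for p in range(ps.site.start - 20, ps.site.end + 20):
            guard.add((ps.site.chrom, p))
    eligible = [j for j, cp in enumerate(positions) if cp not in guard]
    somatic_rows = []
    lo_af, hi_af = config.somatic_af_range
    for s in edited_samples:
        n = rng.poisson(config.somatic_rate * len(eligible))
        if n == 0:
            continue
        for j in rng.choice(len(eligible), size=min(n, len(eligible)), replace=False):
            j = eligible[int(j)]
            chrom, pos = positions[j]
            ref = refs[j]
            if rng.random() < config.somatic_indel_fraction:
                alt = "del:1"
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            af = float(rng.uniform(lo_af, hi_af))
            variants.setdefault((s.sample_id, j), []).append((alt, af))
            somatic_rows.append(
                {"sample": s.sample_id, "chrom": chrom, "pos": pos,
                 "ref": ref, "alt": alt, "true_af": af}
            )

    # --- compose observation counts ---------------------------------------
    n_pos = len(positions)
    chrom_arr = np.array([c for c, _ in positions])
    pos_arr = np.array([p for _, p in positions])
    frames = []
    for s in samples:
        depth = _negative_binomial_depth(rng, config.depth_mean, config.depth_sd, n_pos)
        ref_count = depth.copy()
        alt_records: list[tuple[int, str, int]] = []  # (j, allele, count)
        for (sample_id, j), allele_list in variants.items():
            if sample_id != s.sample_id:
                continue
            for allele, af in allele_list:
                n_alt = int(rng.binomial(min(ref_count[j], depth[j]), af))
                n_alt = min(n_alt, int(ref_count[j]))
                if n_alt > 0:
                    alt_records.append((j, allele, n_alt))
                    ref_count[j] -= n_alt
                    # reads deleted across downstream positions do not
                    # support the reference there either
                    for k in range(1, deletion_length(allele)):
                        j2 = pos_index.get((chrom_arr[j], pos_arr[j] + k))
                        if j2 is not None:
                            ref_count[j2] -= min(int(ref_count[j2]), n_alt)
        if config.error_rate > 0:
            errs = rng.binomial(ref_count, config.error_rate)
            for j in np.flatnonzero(errs):
                split = rng.multinomial(errs[j], [1 / 3] * 3)
                alts = [b for b in "ACGT" if b != refs[j]]
                for b, c in zip(alts, split):
                    if c > 0:
                        alt_records.append((int(j), b, int(c)))
                ref_count[j] -= errs[j]
        js = [j for j, _, _ in alt_records]
        frames.append(
            pd.DataFrame(
                {
                    "sample": s.sample_id,
                    "chrom": np.concatenate([chrom_arr, chrom_arr[js]]) if js else chrom_arr,
                    "pos": np.concatenate([pos_arr, pos_arr[js]]) if js else pos_arr,
                    "ref": np.concatenate([refs, refs[js]]) if js else refs,
                    "depth": np.concatenate([depth, depth[js]]) if js else depth,
                    "allele": np.concatenate([refs, [a for _, a, _ in alt_records]])
                    if js
                    else refs,
                    "count": np.concatenate([ref_count, [c for _, _, c in alt_records]])
                    if js
                    else ref_count,
                }
            )
        )
    pileups = pd.concat(frames, ignore_index=True)
    pileups = pileups[PILEUP_COLUMNS].sort_values(
        ["sample", "chrom", "pos", "allele"], ignore_index=True
    )
    pileups["pos"] = pileups["pos"].astype(int)
    pileups["depth"] = pileups["depth"].astype(int)
    pileups["count"] = pileups["count"].astype(int)
    truth = SyntheticTruth(
        planted_sites=list(planted),
        site_afs=pd.DataFrame(truth_site_rows),
        somatic=pd.DataFrame(somatic_rows,
                             columns=["sample", "chrom", "pos", "ref", "alt", "true_af"]),
    )
    return pileups, samples, truth


def phased_monoallelic_cohort(
    n_sites: int,
    depth_mean: float = 200.0,
    propensity: float = 1.0,
    error_rate: float = 1e-3,
    seed=0,
) -> tuple[pd.DataFrame, list[tuple[CandidateSite, CandidateSite]], dict[str, str]]:
    """Replicate mono-allelic sites on a haplotype-resolved assembly.

    Each replicate is one off-target locus present on both haplotype contigs
    of a diploid; only haplotype A is editable and carries the edit at the
    given propensity, haplotype B shows errors only.  Returns single-sample
    (``S1``) pileups over the counting windows, the per-replicate site pair,
    and the haplotype correspondence table for :func:`merge_phased`.
    """
    rng = _rng(seed)
    rows = {col: [] for col in PILEUP_COLUMNS}
    pairs = []
    correspondence = {}
    start, end, origin = 40, 63, 60
    window = list(range(origin - 5, origin + 2))  # PAM-relative -5..+2
    cut = origin - 3
    for i in range(n_sites):
        pair = []
        for hap, af in (("A", propensity), ("B", 0.0)):
            chrom = f"site{i:04d}_hap{hap}"
            site = CandidateSite(
                guide_name="g1", chrom=chrom, start=start, end=end, strand="+",
                mismatches=2, bulge="none", protospacer_seq="A" * 20, pam_seq="AGG",
                pam_relative_origin=origin,
            )
            pair.append(site)
            for p in window:
                depth = int(rng.poisson(depth_mean))
                ref_n = depth
                alts = []
                if p == cut and af > 0 and depth > 0:
                    n_alt = int(rng.binomial(depth, af))
                    if n_alt:
                        alts.append(("del:1", n_alt))
                        ref_n -= n_alt
                if error_rate > 0 and ref_n > 0:
                    n_err = int(rng.binomial(ref_n, error_rate))
                    if n_err:
                        alts.append(("T" if hap == "A" else "G", n_err))
                        ref_n -= n_err
                for allele, count in [("A", ref_n)] + alts:
                    rows["sample"].append("S1")
                    rows["chrom"].append(chrom)
                    rows["pos"].append(p)
                    rows["ref"].append("A")
                    rows["depth"].append(depth)
                    rows["allele"].append(allele)
                    rows["count"].append(count)
        pairs.append((pair[0], pair[1]))
        correspondence[pair[0].site_id] = pair[1].site_id
    return pd.DataFrame(rows), pairs, correspondence


def simulate_somatic_cohort(
    n_edited: int = 20,
    n_controls: int = 6,
    surveyed_bp_per_sample: int = 5_000_000,
    somatic_rate: float = 5e-8,
    depth_mean: float = 200.0,
    depth_sd: float = 60.0,
    error_rate: float = 1e-3,
    af_range: tuple[float, float] = (0.10, 0.50),
    seed=0,
) -> tuple[pd.DataFrame, list[SampleMeta], dict[str, int], pd.DataFrame]:
    """Sparse cohort for mutation-rate studies at large surveyed footprints.

    Simulating 10^8 dense pileup positions is pointless when all but a
    handful carry only reference observations, so this generator plants
    Poisson(rate x surveyed bp) somatic mutations per edited sample on a
    virtual contig and emits pileup rows (for every sample) only at mutated
    positions.  The callable footprint is reported analytically as
    ``surveyed_bp_per_sample`` for each edited sample.
    """
    rng = _rng(seed)
    samples = [
        SampleMeta(f"WT{i + 1:02d}", "G1", "C1", "", 1,
                   "wild_type" if i % 2 == 0 else "cas9_only")
        for i in range(n_controls)
    ] + [
        SampleMeta(f"E{i + 1:02d}_R1", "G1", "C1", f"E{i + 1:02d}", 1, EDITED_ROLE)
        for i in range(n_edited)
    ]
    truth_rows = []
    per_pos: dict[int, list[tuple[str, str, str, float]]] = {}
    for s in samples[n_controls:]:
        n = rng.poisson(somatic_rate * surveyed_bp_per_sample)
        for pos in rng.choice(surveyed_bp_per_sample, size=n, replace=False):
            pos = int(pos)
            ref = str(rng.choice(BASES))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            af = float(rng.uniform(*af_range))
            per_pos.setdefault(pos, []).append((s.sample_id, ref, alt, af))
            truth_rows.append({"sample": s.sample_id, "chrom": "chr1", "pos": pos,
                               "ref": ref, "alt": alt, "true_af": af})
    rows = {col: [] for col in PILEUP_COLUMNS}
    for pos in sorted(per_pos):
        carriers = per_pos[pos]
        ref = carriers[0][1]
        carrier_af = {sid: af for sid, _, _, af in carriers}
        carrier_alt = {sid: alt for sid, _, alt, _ in carriers}
        for s in samples:
            depth = int(_negative_binomial_depth(rng, depth_mean, depth_sd, None))
            ref_n = depth
            alts = []
            if s.sample_id in carrier_af and depth > 0:
                n_alt = int(rng.binomial(depth, carrier_af[s.sample_id]))
                if n_alt:
                    alts.append((carrier_alt[s.sample_id], n_alt))
                    ref_n -= n_alt
            if error_rate > 0 and ref_n > 0:
                n_err = int(rng.binomial(ref_n, error_rate))
                if n_err:
                    err_base = str(rng.choice([b for b in "ACGT" if b != ref]))
                    alts.append((err_base, n_err))
                    ref_n -= n_err
            for allele, count in [(ref, ref_n)] + alts:
                rows["sample"].append(s.sample_id)
                rows["chrom"].append("chr1")
                rows["pos"].append(pos)
                rows["ref"].append(ref)
                rows["depth"].append(depth)
                rows["allele"].append(allele)
                rows["count"].append(count)
    surveyed = {s.sample_id: surveyed_bp_per_sample for s in samples[n_controls:]}
    truth = pd.DataFrame(truth_rows,
                         columns=["sample", "chrom", "pos", "ref", "alt", "true_af"])
    return pd.DataFrame(rows), samples, surveyed, truth
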