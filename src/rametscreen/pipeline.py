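"""End-to-end orchestration: simulate -> enumerate -> design -> screen ->
classify -> profile -> rates, with a run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .baits import design_baits, intervals_from_baits
from .profiles import (
    af_matrix,
    expand_by_carriers,
    modal_position,
    pam_spectrum,
    sharing_statistics,
)
from .rates import coverage_summary, density_correlation, mutation_rate, surveyed_basepairs
from .screen import (
    EDITED_ROLE,
    apply_filter_tree,
    classify_all,
    confirm_offtarget_events,
    detect_candidates,
    passing,
)
from .simulate import CohortConfig, generate_genome, plant_sites, simulate_pileups
from .sites import enumerate_sites

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters for a full synthetic run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    max_mm: int = 5
    max_mm_bulged: int = 4
    pam_rules: tuple[str, ...] = ("NGG", "NRG")
    bait_length: int = 80
    min_alt_reads: int = 6
    min_tumor_vs_normal_ratio: float = 3.0
    similarity_margin: float = 0.5
    classification_window: int = 20
    af_threshold: float = 0.10
    min_ramets: int = 2
    count_window: tuple[int, int] = (2, -5)
    callable_depth_floor: int = 20
    density_window_bp: int = 5_000
    seed: int = 7

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        cohort_raw = raw.pop("cohort", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if cohort_raw:
            cohort_raw = dict(cohort_raw)
            if "guides" in cohort_raw:
                from .sites import GuideSpec

                cohort_raw["guides"] = [
                    g if isinstance(g, GuideSpec) else GuideSpec(**g)
                    for g in cohort_raw["guides"]
                ]
            if "planted_offtargets" in cohort_raw:
                from .simulate import PlantedSiteSpec

                cohort_raw["planted_offtargets"] = [
                    p if isinstance(p, PlantedSiteSpec) else PlantedSiteSpec(**p)
                    for p in cohort_raw["planted_offtargets"]
                ]
            if "somatic_af_range" in cohort_raw:
                cohort_raw["somatic_af_range"] = tuple(cohort_raw["somatic_af_range"])
            cfg.cohort = CohortConfig(**cohort_raw)
        if isinstance(cfg.count_window, list):
            cfg.count_window = tuple(cfg.count_window)
        cfg.pam_rules = tuple(cfg.pam_rules)
        return cfg

    def to_params(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage on a fresh synthetic cohort; write all outputs.

    Returns the result bundle: stage objects plus the manifest dict.  Reruns
    with an identical config are bit-identical (no timestamps are written).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.to_params()
    seed = config.seed
    counters: dict[str, int] = {}

    log.info("stage simulate: genome + planted sites + pileups")
    genome, genes = generate_genome(config.cohort, seed)
    genome, planted = plant_sites(
        genome, config.cohort.guides, config.cohort.planted_offtargets, seed + 1,
        max_mm=config.max_mm, max_mm_bulged=config.max_mm_bulged,
        pam_rules=config.pam_rules,
    )
    io.write_fasta(genome, outdir / "genome.fasta")
    io.write_intervals(genes, outdir / "genes.bed")
    io.write_guides(config.cohort.guides, outdir / "guides.tsv")

    log.info("stage find-sites")
    sites = enumerate_sites(
        genome, config.cohort.guides, max_mm=config.max_mm,
        max_mm_bulged=config.max_mm_bulged, pam_rules=config.pam_rules,
    )
    counters["sites_found"] = len(sites)
    io.write_sites(sites, outdir / "sites.tsv", outdir / "sites.bed", params=params)

    log.info("stage design-baits")
    baits = design_baits(sites, genome, length=config.bait_length)
    intervals = intervals_from_baits(baits, merge_overlaps=True)
    counters["baits"] = len(baits)
    io.write_baits(baits, outdir / "baits.fasta", outdir / "baits.bed")
    io.write_intervals(intervals, outdir / "intervals.bed")

    pileups, samples, truth = simulate_pileups(
        config.cohort, genome, planted, intervals, seed + 2
    )
    io.write_metadata(samples, outdir / "metadata.tsv")
    io.write_pileups(pileups, outdir / "pileups.tsv", params=params)
    io.write_table(truth.site_afs, outdir / "truth_site_afs.tsv", "simulate", params)
    io.write_table(truth.somatic, outdir / "truth_somatic.tsv", "simulate", params)

    log.info("stage screen")
    candidates = detect_candidates(
        pileups, samples, intervals,
        min_alt_reads=config.min_alt_reads,
        min_tumor_vs_normal_ratio=config.min_tumor_vs_normal_ratio,
        error_rate=config.cohort.error_rate,
    )
    candidates = apply_filter_tree(
        candidates, samples, genome=genome, similarity_margin=config.similarity_margin
    )
    counters["candidates"] = len(candidates)
    survivors = passing(candidates)
    counters["passing"] = len(survivors)
    for c in candidates:
        for reason in c.filter_status - {"pass"}:
            counters[f"excluded_{reason}"] = counters.get(f"excluded_{reason}", 0) + 1
    io.write_table(io.candidates_to_frame(candidates), outdir / "candidates.tsv",
                   "screen", params)
    io.write_vcf(candidates, genome, outdir / "calls.vcf")

    log.info("stage classify")
    classified = classify_all(survivors, sites, window=config.classification_window)
    cls_df = pd.DataFrame(
        [
            {
                "chrom": m.candidate.chrom, "pos": m.candidate.pos,
                "ref": m.candidate.ref, "alt": m.candidate.alt,
                "category": m.category,
                "nearest_site": m.nearest_site.site_id if m.nearest_site else "",
                "distance_to_site_border": (
                    -1 if m.distance_to_site_border is None else m.distance_to_site_border
                ),
                "pam_relative_position": (
                    "" if m.pam_relative_position is None else m.pam_relative_position
                ),
            }
            for m in classified
        ]
    )
    io.write_table(cls_df, outdir / "classified.tsv", "classify", params)
    counters["off_target"] = sum(m.category == "off_target" for m in classified)
    counters["somatic"] = sum(m.category == "somatic" for m in classified)

    log.info("stage profile")
    ws, we = config.count_window
    profiled_sites = sorted(
        {id(m.nearest_site): m.nearest_site for m in classified if m.nearest_site}.values(),
        key=lambda s: s.site_id,
    )
    afs = af_matrix(pileups, profiled_sites, samples, window_start=ws, window_end=we)
    af_df = pd.DataFrame(
        [
            {"site_id": a.site_id, "sample": a.sample_id,
             "mutant_reads": a.mutant_reads, "total_reads": a.total_reads,
             "af": "NR" if a.no_data else round(a.af, 6)}
            for a in afs
        ]
    )
    io.write_table(af_df, outdir / "af_matrix.tsv", "profile", params)
    confirmed = confirm_offtarget_events(
        afs, samples, af_threshold=config.af_threshold, min_ramets=config.min_ramets
    )
    counters["confirmed_offtarget_sites"] = len(confirmed)
    (outdir / "confirmed_sites.txt").write_text("".join(s + "\n" for s in confirmed))

    # expand per carrier ramet so the spectrum weighs alleles by prevalence
    expanded = expand_by_carriers(classified)
    spec_rows = []
    for group in ("target", "off_target"):
        for b in pam_spectrum(expanded, group=group):
            spec_rows.append({"group": group, "pam_relative_position": b.pam_relative_position,
                              "allele_count": b.allele_count})
    io.write_table(pd.DataFrame(spec_rows), outdir / "spectrum.tsv", "profile", params)
    sharing = sharing_statistics(afs, samples, af_threshold=config.af_threshold)
    io.write_table(sharing, outdir / "sharing.tsv", "profile", params)

    log.info("stage rates")
    edited_ids = {s.sample_id for s in samples if s.role == EDITED_ROLE}
    surveyed = {
        k: v for k, v in surveyed_basepairs(pileups, config.callable_depth_floor).items()
        if k in edited_ids
    }
    rate_rows = []
    for category in ("off_target", "somatic"):
        est = mutation_rate(classified, surveyed, category, genotype=config.cohort.genotype)
        rate_rows.append(
            {"genotype": est.genotype, "category": est.category,
             "numerator": est.numerator, "denominator": est.denominator,
             "rate": est.rate, "ci95_lo": est.poisson_ci95[0], "ci95_hi": est.poisson_ci95[1]}
        )
    io.write_table(pd.DataFrame(rate_rows), outdir / "rates.tsv", "rates", params)

    chrom_lengths = {c: len(s) for c, s in genome.items()}
    try:
        r, p, win_table = density_correlation(
            sites, genes, chrom_lengths, window_bp=config.density_window_bp
        )
        io.write_table(win_table, outdir / "density_windows.tsv", "rates", params)
        density = {"r": r, "p": p}
    except ValueError as exc:
        log.warning("density correlation unavailable: %s", exc)
        density = {"r": None, "p": None}

    depth_rows = (
        pileups.groupby(["sample", "chrom", "pos"], sort=False)["depth"].first().reset_index()
    )
    construct_of = {s.sample_id: s.construct for s in samples}
    depth_rows["construct"] = depth_rows["sample"].map(construct_of)
    cov_rows = []
    for group_by in ("construct", "chrom"):
        for c in coverage_summary(depth_rows, group_by=group_by):
            cov_rows.append({"group_by": group_by, "group": c.group, "n": c.n,
                             "mean": c.mean, "sd": c.sd, "cov": c.cov})
    io.write_table(pd.DataFrame(cov_rows), outdir / "coverage_summary.tsv", "rates", params)

    manifest = {
        "package": "rametscreen",
        "seed": seed,
        "params_hash": io.params_hash(params),
        "counters": counters,
        "density": density,
        "confirmed_sites": confirmed,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "genome": genome,
        "genes": genes,
        "planted": planted,
        "sites": sites,
        "baits": baits,
        "intervals": intervals,
        "pileups": pileups,
        "samples": samples,
        "truth": truth,
        "candidates": candidates,
        "classified": classified,
        "afs": afs,
        "confirmed": confirmed,
        "manifest": manifest,
    }
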