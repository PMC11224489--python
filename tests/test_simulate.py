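"""Synthetic cohort generator: determinism, planting round-trips, and the
statistical behaviour of planted edits and somatic mutations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rametscreen.baits import design_baits, intervals_from_baits
from rametscreen.profiles import count_mutant_reads
from rametscreen.simulate import (
    CohortConfig,
    GenerationError,
    PlantedSiteSpec,
    build_samples,
    generate_genome,
    phased_monoallelic_cohort,
    plant_sites,
    simulate_pileups,
    simulate_somatic_cohort,
)
from rametscreen.sites import enumerate_sites


def small_config(**kw):
    defaults = dict(n_chromosomes=1, chromosome_length=20_000, n_genes=10)
    defaults.update(kw)
    return CohortConfig(**defaults)


def test_genome_generation_is_deterministic():
    cfg = small_config()
    g1, genes1 = generate_genome(cfg, 1)
    g2, genes2 = generate_genome(cfg, 1)
    assert g1 == g2 and genes1 == genes2
    g3, _ = generate_genome(cfg, 2)
    assert g3 != g1


def test_uniform_profile_gene_counts_pass_chi_square():
    cfg = CohortConfig(n_chromosomes=2, chromosome_length=50_000, n_genes=400,
                       gene_length=100, density_window_bp=10_000)
    _, genes = generate_genome(cfg, 3)
    counts = {}
    for g in genes:
        w = (g.chrom, g.start // 10_000)
        counts[w] = counts.get(w, 0) + 1
    observed = [counts.get((c, i), 0) for c in ("chr1", "chr2") for i in range(5)]
    assert sum(observed) == 400
    _, p = stats.chisquare(observed)
    assert p > 0.01


def test_zero_genes_gives_empty_annotation():
    _, genes = generate_genome(small_config(n_genes=0), 1)
    assert genes == []


@pytest.mark.parametrize(
    "mismatches,bulge", [(0, "none"), (3, "none"), (5, "none"), (4, "dna"), (4, "rna")]
)
def test_planted_sites_round_trip_through_enumeration(mismatches, bulge):
    cfg = small_config()
    genome, _ = generate_genome(cfg, 5)
    spec = PlantedSiteSpec("g1", mismatches, bulge)
    genome, planted = plant_sites(genome, cfg.guides, [spec], 6)
    (ps,) = planted
    found = [
        s for s in enumerate_sites(genome, cfg.guides)
        if (s.chrom, s.start, s.end, s.strand) ==
           (ps.site.chrom, ps.site.start, ps.site.end, ps.site.strand)
    ]
    assert len(found) == 1
    assert found[0].mismatches == mismatches
    assert found[0].bulge == bulge


def test_planting_rejects_impossible_requests():
    cfg = small_config()
    genome, _ = generate_genome(cfg, 5)
    with pytest.raises(GenerationError):
        plant_sites(genome, cfg.guides, [PlantedSiteSpec("g1", 5, "dna")], 6)


def _cohort(seed, **cfg_kw):
    cfg = small_config(**cfg_kw)
    genome, _ = generate_genome(cfg, seed)
    genome, planted = plant_sites(genome, cfg.guides, cfg.planted_offtargets, seed + 1)
    sites = enumerate_sites(genome, cfg.guides)
    intervals = intervals_from_baits(design_baits(sites, genome), merge_overlaps=True)
    pileups, samples, truth = simulate_pileups(cfg, genome, planted, intervals, seed + 2)
    return cfg, genome, planted, pileups, samples, truth


def test_pileups_are_deterministic_and_truth_is_exhaustive():
    _, _, _, p1, _, t1 = _cohort(11)
    _, _, _, p2, _, t2 = _cohort(11)
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(t1.site_afs, t2.site_afs)
    # every truth record maps to a generated pileup position
    covered = set(zip(p1["chrom"], p1["pos"]))
    for ps in t1.planted_sites:
        assert any((ps.site.chrom, p) in covered
                   for p in range(ps.site.start, ps.site.end))
    for r in t1.somatic.itertuples():
        assert (r.chrom, r.pos) in covered


def test_biallelic_full_editing_reaches_af_one():
    spec = [PlantedSiteSpec("g1", 2, "none", propensity=1.0, allelicity="bi")]
    cfg, genome, planted, pileups, samples, truth = _cohort(
        13, planted_offtargets=spec, ramet_jitter_sd=0.0, somatic_rate=0.0
    )
    ps = planted[0]
    ramet = [s for s in samples if s.role == "edited"][0]
    m = count_mutant_reads(pileups, ps.site, sample_id=ramet.sample_id)
    se = np.sqrt(1.0 * 0.0 / m.total_reads) if m.total_reads else 0
    assert m.af > 1.0 - 3 * np.sqrt(0.25 / m.total_reads)


def test_monoallelic_editing_caps_af_near_half():
    spec = [PlantedSiteSpec("g1", 2, "none", propensity=1.0, allelicity="mono")]
    cfg, genome, planted, pileups, samples, truth = _cohort(
        17, planted_offtargets=spec, ramet_jitter_sd=0.0, somatic_rate=0.0
    )
    ps = planted[0]
    afs = [
        count_mutant_reads(pileups, ps.site, sample_id=s.sample_id).af
        for s in samples if s.role == "edited"
    ]
    mean = np.mean(afs)
    se = np.sqrt(0.25 / (200 * len(afs)))
    assert abs(mean - 0.5) < 5 * se + 0.01
    assert max(afs) < 0.5 + 3 * np.sqrt(0.25 / 150)


def test_sparse_somatic_counts_within_poisson_bounds():
    rate, bp, n_samples = 5e-7, 1_000_000, 20
    _, _, _, truth = simulate_somatic_cohort(
        n_edited=n_samples, surveyed_bp_per_sample=bp, somatic_rate=rate, seed=23
    )
    lam = rate * bp * n_samples
    lo, hi = stats.poisson.ppf([0.005, 0.995], lam)
    assert lo <= len(truth) <= hi


def test_phased_monoallelic_cohort_structure():
    pileups, pairs, corr = phased_monoallelic_cohort(5, seed=29)
    assert len(pairs) == 5
    for a, b in pairs:
        assert corr[a.site_id] == b.site_id
        assert a.chrom.endswith("hapA") and b.chrom.endswith("hapB")
    # edited haplotype carries the deletion, silent one does not
    dels = pileups[pileups["allele"] == "del:1"]
    assert set(dels["chrom"].str[-4:]) == {"hapA"}


def test_sample_sheet_structure():
    samples = build_samples(CohortConfig())
    roles = [s.role for s in samples]
    assert roles.count("wild_type") + roles.count("cas9_only") == 6
    edited = [s for s in samples if s.role == "edited"]
    assert len(edited) == 16
    events = {}
    for s in edited:
        events.setdefault(s.event, []).append(s.ramet)
    assert all(sorted(r) == [1, 2] for r in events.values())
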