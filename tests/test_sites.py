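"""Degenerate site search against naive brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rametscreen.sites import (
    CandidateSite,
    ConfigError,
    GuideSpec,
    InvalidSequenceError,
    enumerate_sites,
    match_pam,
    revcomp,
    score_alignment,
)

from _oracles import bulge_oracle, naive_enumerate
from conftest import random_genome

DNA = st.text(alphabet="ACGT", min_size=20, max_size=20)


@pytest.mark.parametrize(
    "triplet,rule,expected",
    [
        ("AGG", "NGG", True),
        ("AAG", "NRG", True),
        ("ACG", "NRG", False),
        ("TGA", "NGG", False),
        ("CGG", "NRG", True),  # NRG accepts the canonical NGG too
        ("TAG", "NRG", True),
    ],
)
def test_match_pam(triplet, rule, expected):
    assert match_pam(triplet, rule) is expected


def test_match_pam_rejects_non_dna():
    with pytest.raises(InvalidSequenceError):
        match_pam("ANG", "NGG")


def test_score_alignment_identity_and_substitutions():
    spacer = "ACGTACGTACGTACGTACGT"
    assert score_alignment(spacer, spacer, "none") == (0, None)
    # positions 11 and 20 differ by construction
    assert score_alignment(spacer, "ACGTACGTACTTACGTACGA", "none") == (2, None)


@pytest.mark.parametrize("mode,length", [("none", 19), ("dna", 20), ("rna", 20)])
def test_score_alignment_window_length_contract(mode, length):
    with pytest.raises(ValueError):
        score_alignment("A" * 20, "A" * length, mode)


@settings(max_examples=100, derandomize=True)
@given(spacer=DNA, window=st.text(alphabet="ACGT", min_size=21, max_size=21))
def test_dna_bulge_matches_exhaustive_deletion_oracle(spacer, window):
    assert score_alignment(spacer, window, "dna") == bulge_oracle(spacer, window, "dna")


@settings(max_examples=100, derandomize=True)
@given(spacer=DNA, window=st.text(alphabet="ACGT", min_size=19, max_size=19))
def test_rna_bulge_matches_exhaustive_deletion_oracle(spacer, window):
    assert score_alignment(spacer, window, "rna") == bulge_oracle(spacer, window, "rna")


def _plant(genome, chrom, pos, seq):
    s = genome[chrom]
    genome[chrom] = s[:pos] + seq + s[pos + len(seq):]


def test_planted_exact_site_found_once(rng, guide):
    genome = random_genome(rng, {"chr1": 5000})
    _plant(genome, "chr1", 2000, guide.spacer + "AGG")
    sites = [
        s for s in enumerate_sites(genome, [guide], max_mm=0, bulges=False)
    ]
    assert len(sites) == 1
    s = sites[0]
    assert (s.start, s.end, s.strand, s.mismatches, s.bulge) == (2000, 2023, "+", 0, "none")
    assert s.is_on_target


def test_reverse_complement_planting_and_strand_symmetry(rng, guide):
    genome = random_genome(rng, {"chr1": 5000})
    _plant(genome, "chr1", 2000, revcomp(guide.spacer + "AGG"))
    sites = enumerate_sites(genome, [guide], max_mm=0, bulges=False)
    assert [(s.start, s.end, s.strand) for s in sites] == [(2000, 2023, "-")]

    # enumerating the reverse-complemented genome mirrors every coordinate
    fwd = enumerate_sites(genome, [guide], max_mm=2, bulges=False)
    rc = enumerate_sites({"chr1": revcomp(genome["chr1"])}, [guide], max_mm=2, bulges=False)
    L = len(genome["chr1"])
    mirrored = {(L - s.end, L - s.start, "-" if s.strand == "+" else "+", s.mismatches)
                for s in rc}
    assert {(s.start, s.end, s.strand, s.mismatches) for s in fwd} == mirrored


def test_enumeration_equals_naive_scan(rng, guide):
    genome = random_genome(rng, {"chr1": 4000, "scaffold_1": 2000})
    guides = [guide, GuideSpec("g2", "TACGGATCCTGAAGGCTCAT")]
    got = {
        (s.guide_name, s.chrom, s.start, s.end, s.strand, s.mismatches)
        for s in enumerate_sites(genome, guides, max_mm=3, bulges=False)
    }
    assert got == naive_enumerate(genome, guides, max_mm=3)


def test_mismatch_budget_monotonicity(rng, guide):
    genome = random_genome(rng, {"chr1": 20000})
    key = lambda s: (s.chrom, s.start, s.end, s.strand)
    prev: set = set()
    for k in (2, 3, 4):
        cur = {key(s) for s in enumerate_sites(genome, [guide], max_mm=k, bulges=False)}
        assert prev <= cur
        prev = cur


def test_emitted_sites_satisfy_their_own_invariants(rng, guide):
    genome = random_genome(rng, {"chr1": 30000})
    for s in enumerate_sites(genome, [guide], max_mm=5, max_mm_bulged=4):
        # the dataclass re-validates span length vs bulge mode and the
        # mismatch budget on construction
        CandidateSite(**{k: getattr(s, k) for k in (
            "guide_name", "chrom", "start", "end", "strand", "mismatches",
            "bulge", "bulge_position", "protospacer_seq", "pam_seq",
            "pam_relative_origin", "is_on_target")})
        assert match_pam(s.pam_seq, "NRG") or match_pam(s.pam_seq, "NGG")
        seq = genome[s.chrom][s.start:s.end]
        oriented = seq if s.strand == "+" else revcomp(seq)
        assert oriented == s.protospacer_seq + s.pam_seq


def test_scaffold_filtering_and_error_paths(rng, guide):
    genome = random_genome(rng, {"chr1": 3000, "scaffold_7": 3000})
    _plant(genome, "scaffold_7", 1000, guide.spacer + "TGG")
    with_scaf = enumerate_sites(genome, [guide], max_mm=0, bulges=False)
    without = enumerate_sites(genome, [guide], max_mm=0, bulges=False,
                              include_scaffolds=False)
    assert {s.chrom for s in with_scaf} == {"scaffold_7"}
    assert without == []

    assert enumerate_sites({}, [guide]) == []
    with pytest.raises(ConfigError):
        enumerate_sites(genome, [guide, guide])


def test_pam_relative_coordinate_round_trip(rng, guide):
    genome = random_genome(rng, {"chr1": 5000})
    _plant(genome, "chr1", 2000, guide.spacer + "AGG")
    _plant(genome, "chr1", 2500, revcomp(guide.spacer + "AGG"))
    for s in enumerate_sites(genome, [guide], max_mm=0, bulges=False):
        # -1 is the protospacer base adjacent to the PAM; +1 the first PAM base
        assert s.pam_relative(s.pam_relative_origin) == 1
        for rel in (-20, -5, -3, -1, 1, 2, 3):
            assert s.pam_relative(s.genomic_position(rel)) == rel
        inside = {s.genomic_position(r) for r in list(range(-20, 0)) + [1, 2, 3]}
        assert inside == set(range(s.start, s.end))
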