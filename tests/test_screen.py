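"""Pooled-contrast detection, the filtering logic-tree, classification, and
off-target confirmation rules."""

import pandas as pd
import pytest

from rametscreen.profiles import AFMeasurement
from rametscreen.screen import (
    ConfigurationError,
    SampleMeta,
    VariantCandidate,
    apply_filter_tree,
    classify_mutation,
    confirm_offtarget_events,
    detect_candidates,
    passing,
)

from conftest import make_pileup


META = [
    SampleMeta("WT1", "G1", "C1", "", 1, "wild_type"),
    SampleMeta("CAS1", "G1", "C1", "", 1, "cas9_only"),
    SampleMeta("E01_R1", "G1", "C1", "E01", 1, "edited"),
    SampleMeta("E01_R2", "G1", "C1", "E01", 2, "edited"),
]


def pileup_at(pos, per_sample_alt, depth=200, alt="T", ref="A"):
    """One position across the four metadata samples with given alt counts."""
    rows = []
    for m in META:
        n_alt = per_sample_alt.get(m.sample_id, 0)
        rows.append({"sample": m.sample_id, "pos": pos, "ref": ref,
                     "depth": depth, "allele": ref, "count": depth - n_alt})
        if n_alt:
            rows.append({"sample": m.sample_id, "pos": pos, "ref": ref,
                         "depth": depth, "allele": alt, "count": n_alt})
    return make_pileup(rows)


def test_clear_signal_is_detected():
    pu = pileup_at(50, {"E01_R1": 30, "E01_R2": 20})
    (cand,) = detect_candidates(pu, META)
    assert cand.tumor_alt == 50 and cand.tumor_depth == 400
    assert cand.normal_alt == 0
    assert cand.per_sample["E01_R1"] == (30, 200)


def test_support_must_exceed_five_reads():
    pu = pileup_at(50, {"E01_R1": 5})
    assert detect_candidates(pu, META) == []
    pu = pileup_at(50, {"E01_R1": 6})
    assert len(detect_candidates(pu, META)) == 1


def test_similar_normal_af_suppresses_candidate():
    # edited AF 0.30 vs control AF 0.29: not a 3-fold contrast
    pu = pileup_at(50, {"E01_R1": 60, "E01_R2": 60, "WT1": 58, "CAS1": 58})
    assert detect_candidates(pu, META) == []


def test_detection_is_monotone_in_min_alt_reads():
    pu = pd.concat(
        [pileup_at(50, {"E01_R1": 30}), pileup_at(90, {"E01_R2": 8})],
        ignore_index=True,
    )
    prev = None
    for threshold in (6, 9, 31):
        keys = {c.key for c in detect_candidates(pu, META, min_alt_reads=threshold)}
        if prev is not None:
            assert keys <= prev
        prev = keys


def test_missing_controls_is_a_configuration_error():
    edited_only = [m for m in META if m.role == "edited"]
    with pytest.raises(ConfigurationError):
        detect_candidates(pileup_at(50, {"E01_R1": 30}), edited_only)


def _candidate(per_sample, alt="T", normal=(0, 400), tumor=None, pos=50, ref="A"):
    t_alt = sum(a for s, (a, d) in per_sample.items() if s.startswith("E"))
    t_depth = sum(d for s, (a, d) in per_sample.items() if s.startswith("E"))
    if tumor is not None:
        t_alt, t_depth = tumor
    return VariantCandidate(
        chrom="chr1", pos=pos, ref=ref, alt=alt, genotype="G1",
        per_sample=per_sample, tumor_alt=t_alt, tumor_depth=t_depth,
        normal_alt=normal[0], normal_depth=normal[1],
    )


def test_filter_tree_passes_single_ramet_six_reads():
    cand = _candidate({"WT1": (0, 200), "CAS1": (0, 200),
                       "E01_R1": (6, 200), "E01_R2": (0, 200)})
    (out,) = apply_filter_tree([cand], META)
    assert out.filter_status == {"pass"}


def test_filter_tree_low_support_at_five_reads_per_sample():
    cand = _candidate({"WT1": (0, 200), "CAS1": (0, 200),
                       "E01_R1": (5, 200), "E01_R2": (5, 200)})
    (out,) = apply_filter_tree([cand], META)
    assert "low_support" in out.filter_status


def test_filter_tree_flags_wild_type_sharing():
    # edited pooled AF 0.25, control pooled AF 0.15 >= 0.5 x 0.25
    cand = _candidate({"WT1": (60, 200), "CAS1": (0, 200),
                       "E01_R1": (50, 200), "E01_R2": (50, 200)},
                      normal=(60, 400))
    (out,) = apply_filter_tree([cand], META)
    assert "in_normal" in out.filter_status


def test_filter_tree_homopolymer_indel_is_artifact():
    genome = {"chr1": "ACGT" * 10 + "AAAAAAAAAA" + "ACGT" * 10}
    cand = _candidate({"WT1": (0, 200), "CAS1": (0, 200),
                       "E01_R1": (30, 200), "E01_R2": (0, 200)},
                      alt="del:1", pos=45)
    (out,) = apply_filter_tree([cand], META, genome=genome)
    assert "alignment_artifact" in out.filter_status
    # the same indel away from the run passes
    cand2 = _candidate({"WT1": (0, 200), "CAS1": (0, 200),
                        "E01_R1": (30, 200), "E01_R2": (0, 200)},
                       alt="del:1", pos=10)
    (out2,) = apply_filter_tree([cand2], META, genome=genome)
    assert "alignment_artifact" not in out2.filter_status


def test_filter_tree_recurrent_allele_everywhere_is_artifact():
    cand = _candidate({"WT1": (100, 200), "CAS1": (100, 200),
                       "E01_R1": (100, 200), "E01_R2": (100, 200)},
                      normal=(200, 400))
    (out,) = apply_filter_tree([cand], META)
    assert {"alignment_artifact", "in_normal"} <= out.filter_status
    assert passing([out]) == []


@pytest.mark.parametrize(
    "pos,expected",
    [
        (113, "off_target"),   # 10 bp outside the 3' border (site ends at 123)
        (142, "off_target"),   # exactly 20 bp outside: inclusive boundary
        (143, "somatic"),      # 21 bp outside
        (110, "off_target"),   # inside the span
        (80, "off_target"),    # exactly 20 bp before the start
        (79, "somatic"),
    ],
)
def test_classification_partitions_at_inclusive_20bp(plus_site, pos, expected):
    site = plus_site  # span [100, 123)
    cand = _candidate({"E01_R1": (30, 200)}, pos=pos)
    m = classify_mutation(cand, [site], window=20)
    assert m.category == expected
    assert (m.category == "off_target") == (
        m.distance_to_site_border is not None
        and m.distance_to_site_border <= 20
        and m.nearest_site is not None
    )


def test_classification_tie_breaks_by_distance_then_mismatches(plus_site):
    import dataclasses

    near_low_mm = dataclasses.replace(plus_site, start=130, end=153,
                                      pam_relative_origin=150, mismatches=1)
    cand = _candidate({"E01_R1": (30, 200)}, pos=126)  # 4 bp from one, 4 from other
    m = classify_mutation(cand, [plus_site, near_low_mm], window=20)
    assert m.nearest_site is near_low_mm


def test_pam_relative_position_of_deletions_reports_cut_proximal_end(plus_site, minus_site):
    # + strand: protospacer -3 is genomic 117; a 4 bp deletion ending there
    cand = _candidate({"E01_R1": (30, 200)}, alt="del:4", pos=114)
    m = classify_mutation(cand, [plus_site])
    assert m.pam_relative_position == -3
    # - strand: protospacer -3 is genomic 105; deletion extends to higher coords
    cand = _candidate({"E01_R1": (30, 200)}, alt="del:4", pos=105)
    m = classify_mutation(cand, [minus_site])
    assert m.pam_relative_position == -3


def _af(site, sample, af, total=200):
    return AFMeasurement(sample, site, int(round(af * total)), total)


def test_confirmation_requires_two_ramets_strictly_above_threshold():
    meta = META
    afs = [_af("s1", "E01_R1", 0.12), _af("s1", "E01_R2", 0.15)]
    assert confirm_offtarget_events(afs, meta) == ["s1"]
    afs = [_af("s2", "E01_R1", 0.12), _af("s2", "E01_R2", 0.08)]
    assert confirm_offtarget_events(afs, meta) == []
    afs = [_af("s3", "E01_R1", 0.10), _af("s3", "E01_R2", 0.10)]
    assert confirm_offtarget_events(afs, meta) == []  # strict exceedance
    # control samples and no-data cells never count
    afs = [_af("s4", "WT1", 0.5), _af("s4", "CAS1", 0.5),
           AFMeasurement("E01_R1", "s4", 0, 0)]
    assert confirm_offtarget_events(afs, meta) == []
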