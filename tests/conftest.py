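import numpy as np
import pandas as pd
import pytest

from rametscreen.sites import CandidateSite, GuideSpec


def random_genome(rng: np.random.Generator, lengths: dict[str, int]) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {name: "".join(bases[rng.integers(0, 4, n)]) for name, n in lengths.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(20240621)


@pytest.fixture
def guide():
    return GuideSpec("g1", "GTCACCTCGAGGATTACGCC", "NGG")


@pytest.fixture
def plus_site():
    """A bulge-free + strand site: protospacer [100,120), PAM [120,123)."""
    return CandidateSite(
        guide_name="g1", chrom="chr1", start=100, end=123, strand="+",
        mismatches=2, protospacer_seq="A" * 20, pam_seq="AGG",
        pam_relative_origin=120,
    )


@pytest.fixture
def minus_site():
    """Mirror-image - strand site: PAM [100,103), protospacer [103,123)."""
    return CandidateSite(
        guide_name="g1", chrom="chr1", start=100, end=123, strand="-",
        mismatches=2, protospacer_seq="A" * 20, pam_seq="AGG",
        pam_relative_origin=102,
    )


def make_pileup(rows: list[dict]) -> pd.DataFrame:
    """Pileup table from terse row dicts; fills depth from counts if absent."""
    defaults = {"sample": "S1", "chrom": "chr1", "ref": "A"}
    full = []
    for r in rows:
        d = {**defaults, **r}
        full.append(d)
    df = pd.DataFrame(full)
    if "depth" not in df.columns:
        depth = df.groupby(["sample", "chrom", "pos"])["count"].transform("sum")
        df["depth"] = depth
    return df[["sample", "chrom", "pos", "ref", "depth", "allele", "count"]]
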