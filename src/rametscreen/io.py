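"""Readers and writers for the pipeline's file surface.

FASTA via pyfaidx, tables as TSV with a provenance comment line
(``# rametscreen stage=<stage> params=<hash>``), BED with the usual 0-based
half-open columns, and a minimal VCF (via pysam) for passing calls.
Internal coordinates are 0-based half-open everywhere; VCF output converts
to 1-based.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pyfaidx
import pysam

from .baits import BaitProbe, Interval
from .screen import SampleMeta, VariantCandidate, deletion_length
from .sites import CandidateSite, GuideSpec


def params_hash(params: Mapping) -> str:
    """Short stable hash of a parameter mapping (for output provenance)."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, stage: str = "", params: Mapping | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if stage:
            fh.write(f"# rametscreen stage={stage} params={params_hash(params or {})}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# --- FASTA -----------------------------------------------------------------

def read_genome(path) -> dict[str, str]:
    fasta = pyfaidx.Fasta(str(path))
    return {name: str(fasta[name][:]).upper() for name in fasta.keys()}


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --- guides ----------------------------------------------------------------

def write_guides(guides: Iterable[GuideSpec], path) -> None:
    df = pd.DataFrame(
        [
            {"name": g.name, "spacer": g.spacer, "pam_rule": g.pam_rule,
             "target_locus_name": g.target_locus_name}
            for g in guides
        ]
    )
    write_table(df, path)


def read_guides(path) -> list[GuideSpec]:
    df = read_table(path)

    def _str(value, default=""):
        return default if value is None or pd.isna(value) else str(value)

    return [
        GuideSpec(
            name=str(r["name"]),
            spacer=str(r["spacer"]),
            pam_rule=_str(r.get("pam_rule"), "NGG"),
            target_locus_name=_str(r.get("target_locus_name")),
        )
        for r in df.to_dict("records")
    ]


# --- candidate sites -------------------------------------------------------

def sites_to_frame(sites: Sequence[CandidateSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "guide_name": s.guide_name,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "strand": s.strand,
                "mismatches": s.mismatches,
                "bulge": s.bulge,
                "bulge_position": -1 if s.bulge_position is None else s.bulge_position,
                "protospacer_seq": s.protospacer_seq,
                "pam_seq": s.pam_seq,
                "pam_relative_origin": s.pam_relative_origin,
                "is_on_target": s.is_on_target,
            }
            for s in sites
        ]
    )


def write_sites(sites: Sequence[CandidateSite], tsv_path, bed_path=None,
                params: Mapping | None = None) -> None:
    write_table(sites_to_frame(sites), tsv_path, stage="find-sites", params=params)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for s in sites:
                name = f"{s.guide_name}|{s.mismatches}mm|{s.bulge}"
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{name}\t{s.mismatches}\t{s.strand}\n")


def read_sites(tsv_path) -> list[CandidateSite]:
    df = read_table(tsv_path)
    out = []
    for r in df.to_dict("records"):
        bpos = int(r["bulge_position"])
        out.append(
            CandidateSite(
                guide_name=str(r["guide_name"]),
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                strand=str(r["strand"]),
                mismatches=int(r["mismatches"]),
                bulge=str(r["bulge"]),
                bulge_position=None if bpos < 0 else bpos,
                protospacer_seq=str(r["protospacer_seq"]),
                pam_seq=str(r["pam_seq"]),
                pam_relative_origin=int(r["pam_relative_origin"]),
                is_on_target=bool(r["is_on_target"]),
            )
        )
    return out


# --- baits / intervals -----------------------------------------------------

def write_baits(baits: Sequence[BaitProbe], fasta_path, bed_path) -> None:
    write_fasta({f"bait_{i + 1:05d}|{b.site_id}": b.sequence for i, b in enumerate(baits)},
                fasta_path)
    with open(bed_path, "w") as fh:
        for b in baits:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.site_id}\n")


def write_intervals(intervals: Sequence[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_intervals(path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            label = parts[3] if len(parts) > 3 else ""
            out.append(Interval(parts[0], int(parts[1]), int(parts[2]), label))
    return out


# --- sample metadata -------------------------------------------------------

def write_metadata(samples: Sequence[SampleMeta], path) -> None:
    df = pd.DataFrame(
        [
            {"sample": m.sample_id, "genotype": m.genotype, "construct": m.construct,
             "event": m.event, "ramet": m.ramet, "role": m.role}
            for m in samples
        ]
    )
    write_table(df, path)


def read_metadata(path) -> list[SampleMeta]:
    df = read_table(path)
    return [
        SampleMeta(
            sample_id=str(r["sample"]),
            genotype=str(r["genotype"]),
            construct=str(r["construct"]),
            event="" if pd.isna(r["event"]) else str(r["event"]),
            ramet=int(r["ramet"]),
            role=str(r["role"]),
        )
        for r in df.to_dict("records")
    ]


# --- pileups ---------------------------------------------------------------

def write_pileups(pileups: pd.DataFrame, path, params: Mapping | None = None) -> None:
    write_table(pileups, path, stage="simulate", params=params)


def read_pileups(path) -> pd.DataFrame:
    df = read_table(path)
    df["pos"] = df["pos"].astype(int)
    return df


# --- candidates / VCF ------------------------------------------------------

def candidates_to_frame(candidates: Sequence[VariantCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "genotype": c.genotype,
                "tumor_alt": c.tumor_alt,
                "tumor_depth": c.tumor_depth,
                "tumor_af": c.tumor_af,
                "normal_alt": c.normal_alt,
                "normal_depth": c.normal_depth,
                "normal_af": c.normal_af,
                "filter_status": ",".join(sorted(c.filter_status)) or "unfiltered",
                "per_sample": json.dumps(c.per_sample, sort_keys=True),
            }
            for c in candidates
        ]
    )


def read_candidates(path) -> list[VariantCandidate]:
    df = read_table(path)
    out = []
    for r in df.to_dict("records"):
        status = set() if r["filter_status"] == "unfiltered" else set(str(r["filter_status"]).split(","))
        per_sample = {k: tuple(v) for k, v in json.loads(r["per_sample"]).items()}
        out.append(
            VariantCandidate(
                chrom=str(r["chrom"]), pos=int(r["pos"]), ref=str(r["ref"]),
                alt=str(r["alt"]), genotype=str(r["genotype"]),
                per_sample=per_sample,
                tumor_alt=int(r["tumor_alt"]), tumor_depth=int(r["tumor_depth"]),
                normal_alt=int(r["normal_alt"]), normal_depth=int(r["normal_depth"]),
                filter_status=status,
            )
        )
    return out


def _vcf_alleles(cand: VariantCandidate, genome: Mapping[str, str]) -> tuple[int, str, str]:
    """(1-based POS, REF, ALT) in VCF left-anchored representation."""
    seq = genome[cand.chrom]
    if cand.alt.startswith("del:"):
        L = deletion_length(cand.alt)
        anchor = cand.pos - 1
        return anchor + 1, seq[anchor : anchor + L + 1], seq[anchor]
    if cand.alt.startswith("ins:"):
        inserted = cand.alt.split(":", 1)[1]
        return cand.pos + 1, seq[cand.pos], seq[cand.pos] + inserted
    return cand.pos + 1, cand.ref, cand.alt


def write_vcf(candidates: Sequence[VariantCandidate], genome: Mapping[str, str], path) -> None:
    """Minimal VCF of screened calls; FILTER mirrors the logic-tree status."""
    header = pysam.VariantHeader()
    for chrom, seq in genome.items():
        header.contigs.add(chrom, length=len(seq))
    for fid, desc in [
        ("low_support", "No sample supports the alt with more than five reads"),
        ("in_normal", "Controls show similar allele frequency"),
        ("alignment_artifact", "Recurrent-allele or homopolymer alignment artifact"),
    ]:
        header.filters.add(fid, None, None, desc)
    header.info.add("TAF", 1, "Float", "Pooled edited (tumor) allele frequency")
    header.info.add("NAF", 1, "Float", "Pooled control (normal) allele frequency")
    header.info.add("TALT", 1, "Integer", "Pooled edited alt read count")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for cand in sorted(candidates, key=lambda c: (c.chrom, c.pos, c.alt)):
            pos1, ref, alt = _vcf_alleles(cand, genome)
            rec = vcf.new_record(
                contig=cand.chrom, start=pos1 - 1, alleles=(ref, alt)
            )
            status = cand.filter_status or {"pass"}
            if status == {"pass"}:
                rec.filter.add("PASS")
            else:
                for f in sorted(status - {"pass"}):
                    rec.filter.add(f)
            rec.info["TAF"] = cand.tumor_af
            rec.info["NAF"] = cand.normal_af
            rec.info["TALT"] = cand.tumor_alt
            vcf.write(rec)


def read_vcf_candidates(path, genotype: str = "all") -> list[VariantCandidate]:
    """Import externally called variants (e.g. a Mutect2 tumor-pool VCF).

    Alleles are converted to the internal encoding (SNP, ``del:<L>``,
    ``ins:<SEQ>``); records with symbolic or multi-allelic ALTs are skipped.
    Pooled counts are recovered from TALT/TAF/NAF INFO fields when present
    so the logic-tree can run on imported calls.
    """
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if not set(ref + alt) <= set("ACGT"):
                continue
            if len(ref) == len(alt) == 1:
                pos0, r, a = rec.start, ref, alt
            elif len(ref) > len(alt) == 1 and ref[0] == alt:
                pos0, r, a = rec.start + 1, ref[1], f"del:{len(ref) - 1}"
            elif len(alt) > len(ref) == 1 and alt[0] == ref:
                pos0, r, a = rec.start, ref, f"ins:{alt[1:]}"
            else:
                continue
            cand = VariantCandidate(chrom=rec.chrom, pos=pos0, ref=r, alt=a,
                                    genotype=genotype)
            info = dict(rec.info)
            cand.tumor_alt = int(info.get("TALT", 0))
            if "TAF" in info and cand.tumor_alt:
                taf = float(info["TAF"])
                cand.tumor_depth = int(round(cand.tumor_alt / taf)) if taf > 0 else 0
            out.append(cand)
    return out
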