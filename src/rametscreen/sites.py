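"""Degenerate CRISPR/Cas9 target-site search.

Enumerates every genomic locus a guide RNA could plausibly cut: up to a
configurable number of spacer mismatches, optionally with a single-base DNA
or RNA bulge, immediately 5' of an NGG or NRG protospacer-adjacent motif
(PAM).  The scan is an exhaustive sweep of both strands, so on desk-scale
genomes it is equivalent by construction to a naive position-by-position
oracle.

Coordinate conventions
----------------------
All spans are 0-based half-open on the forward reference strand.  For a
``+`` strand site ``[start, end)`` the protospacer occupies
``[start, end - 3)`` and the PAM ``[end - 3, end)``; for a ``-`` strand site
the PAM occupies ``[start, start + 3)`` and is read on the reverse strand.
``pam_relative_origin`` is the forward-strand coordinate of PAM position +1
(the PAM base adjacent to the protospacer).  PAM-relative positions are
+1..+3 inside the PAM and -1..-20 along the protospacer, -1 adjacent to the
PAM; the SpCas9 blunt cut falls between -3 and -4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

log = logging.getLogger(__name__)

SPACER_LEN = 20
PAM_LEN = 3

#: window length on the genomic (protospacer) strand per bulge mode
WINDOW_LEN = {"none": 20, "dna": 21, "rna": 19}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
# PAM pattern alphabet: genome 'N' (code 4) matches nothing, by design.
_IUPAC_PAM = {
    "A": (0,),
    "C": (1,),
    "G": (2,),
    "T": (3,),
    "R": (0, 2),
    "N": (0, 1, 2, 3),
}


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside the expected alphabet."""


class ConfigError(ValueError):
    """Invalid search configuration (e.g. duplicate guide names)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA as uint8 (A=0 C=1 G=2 T=3, anything else 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA: 20-nt spacer (5'->3', as in the gRNA) plus a PAM rule."""

    name: str
    spacer: str
    pam_rule: str = "NGG"
    target_locus_name: str = ""

    def __post_init__(self):
        spacer = self.spacer.upper()
        object.__setattr__(self, "spacer", spacer)
        if len(spacer) != SPACER_LEN or set(spacer) - set("ACGT"):
            raise InvalidSequenceError(
                f"guide {self.name!r}: spacer must be 20 nt of A/C/G/T, got {self.spacer!r}"
            )
        rule = self.pam_rule.upper()
        object.__setattr__(self, "pam_rule", rule)
        if len(rule) != PAM_LEN or set(rule) - set(_IUPAC_PAM):
            raise InvalidSequenceError(
                f"guide {self.name!r}: PAM rule must be 3 symbols over "
                f"{sorted(_IUPAC_PAM)}, got {self.pam_rule!r}"
            )


@dataclass
class CandidateSite:
    """A genomic locus degenerately matching a guide.

    ``bulge_position`` is 0-based from the PAM-distal (5') end of the
    oriented window: for a DNA bulge it indexes the unpaired genomic base
    within the 21-nt window, for an RNA bulge the skipped spacer base.
    """

    guide_name: str
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    bulge: str = "none"
    bulge_position: int | None = None
    protospacer_seq: str = ""
    pam_seq: str = ""
    pam_relative_origin: int = -1
    is_on_target: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.bulge not in WINDOW_LEN:
            raise ValueError(f"unknown bulge mode {self.bulge!r}")
        expected = WINDOW_LEN[self.bulge] + PAM_LEN
        if self.end - self.start != expected:
            raise ValueError(
                f"span length {self.end - self.start} inconsistent with "
                f"bulge={self.bulge} (expected {expected})"
            )
        limit = 5 if self.bulge == "none" else 4
        if not 0 <= self.mismatches <= limit:
            raise ValueError(
                f"{self.mismatches} mismatches out of range for bulge={self.bulge}"
            )

    @property
    def site_id(self) -> str:
        return f"{self.guide_name}|{self.chrom}:{self.start}-{self.end}({self.strand})"

    def pam_relative(self, pos: int) -> int:
        """Signed PAM-relative coordinate of forward-strand position ``pos``.

        +1..+3 are PAM bases (+1 adjacent to the protospacer), -1..-k the
        protospacer bases (-1 adjacent to the PAM).  The mapping extends
        linearly outside the site span; there is no position 0.
        """
        if self.strand == "+":
            d = pos - self.pam_relative_origin
        else:
            d = self.pam_relative_origin - pos
        return d + 1 if d >= 0 else d

    def genomic_position(self, pam_relative: int) -> int:
        """Inverse of :meth:`pam_relative`."""
        if pam_relative == 0:
            raise ValueError("PAM-relative coordinates have no position 0")
        d = pam_relative - 1 if pam_relative > 0 else pam_relative
        if self.strand == "+":
            return self.pam_relative_origin + d
        return self.pam_relative_origin - d


def match_pam(triplet: str, pam_rule: str) -> bool:
    """True iff a 3-nt DNA triplet satisfies a PAM pattern (N any, R = A/G)."""
    triplet = triplet.upper()
    if len(triplet) != PAM_LEN or set(triplet) - set("ACGT"):
        raise InvalidSequenceError(f"PAM triplet must be 3 nt of A/C/G/T, got {triplet!r}")
    pam_rule = pam_rule.upper()
    if len(pam_rule) != PAM_LEN or set(pam_rule) - set(_IUPAC_PAM):
        raise InvalidSequenceError(f"bad PAM rule {pam_rule!r}")
    return all(_CODE[b] in _IUPAC_PAM[s] for b, s in zip(triplet, pam_rule))


def score_alignment(
    spacer: str, genomic_window: str, allow_bulge: str = "none"
) -> tuple[int, int | None]:
    """Mismatch count between a spacer and an oriented genomic window.

    The window is given on the protospacer strand, PAM to the 3' (right)
    side, and must be 20 nt for ``none``, 21 for ``dna`` (one unpaired
    genomic base) or 19 for ``rna`` (one unpaired spacer base).  For bulge
    modes the minimum over all single-base bulge placements is returned with
    the placement achieving it; ties break toward the PAM-proximal end.
    Genomic ``N`` matches no spacer base.
    """
    if allow_bulge not in WINDOW_LEN:
        raise ValueError(f"unknown bulge mode {allow_bulge!r}")
    expected = WINDOW_LEN[allow_bulge]
    if len(genomic_window) != expected:
        raise ValueError(
            f"window length {len(genomic_window)} inconsistent with bulge="
            f"{allow_bulge} (expected {expected})"
        )
    s = encode(spacer)
    if len(s) != SPACER_LEN:
        raise InvalidSequenceError("spacer must be 20 nt")
    w = encode(genomic_window)
    if allow_bulge == "none":
        return int((s != w).sum()), None
    best_mm, best_pos = None, None
    if allow_bulge == "dna":
        placements = ((d, np.delete(w, d)) for d in range(len(w)))
        for d, aligned in placements:
            mm = int((s != aligned).sum())
            if best_mm is None or mm <= best_mm:
                best_mm, best_pos = mm, d
    else:  # rna: skip one spacer base
        for d in range(SPACER_LEN):
            mm = int((np.delete(s, d) != w).sum())
            if best_mm is None or mm <= best_mm:
                best_mm, best_pos = mm, d
    return best_mm, best_pos


def _pam_anchor_mask(codes: np.ndarray, pam_rules: Iterable[str]) -> np.ndarray:
    """Boolean mask over triplet anchors 0..L-3 matching any PAM rule."""
    w3 = sliding_window_view(codes, PAM_LEN)
    ok = np.zeros(len(w3), dtype=bool)
    for rule in pam_rules:
        m = np.ones(len(w3), dtype=bool)
        for i, sym in enumerate(rule.upper()):
            m &= np.isin(w3[:, i], _IUPAC_PAM[sym])
        ok |= m
    return ok


def _scan_oriented(
    codes: np.ndarray,
    spacer: np.ndarray,
    pam_ok: np.ndarray,
    max_mm: int,
    max_mm_bulged: int,
    bulges: bool,
) -> dict[int, tuple[str, int, int | None]]:
    """Scan one oriented sequence; return {pam_anchor: (mode, mm, bulge_pos)}.

    A PAM anchor matching under several modes is reported once: the
    bulge-free interpretation wins whenever it is within ``max_mm``,
    otherwise the bulged mode with fewest mismatches (DNA before RNA on
    ties).
    """
    best: dict[int, tuple[str, int, int | None]] = {}
    anchors = np.flatnonzero(pam_ok)
    if len(anchors) == 0:
        return best

    a = anchors[anchors >= SPACER_LEN]
    if len(a):
        w20 = sliding_window_view(codes, SPACER_LEN)[a - SPACER_LEN]
        mm = (w20 != spacer).sum(axis=1)
        for p, m in zip(a[mm <= max_mm], mm[mm <= max_mm]):
            best[int(p)] = ("none", int(m), None)
    if not bulges:
        return best

    a = anchors[anchors >= SPACER_LEN + 1]
    if len(a):
        w21 = sliding_window_view(codes, SPACER_LEN + 1)[a - (SPACER_LEN + 1)]
        stack = np.empty((SPACER_LEN + 1, len(a)), dtype=np.int32)
        for d in range(SPACER_LEN + 1):
            idx = np.r_[0:d, d + 1 : SPACER_LEN + 1]
            stack[d] = (w21[:, idx] != spacer).sum(axis=1)
        mm = stack.min(axis=0)
        # argmin on the reversed stack -> largest (PAM-proximal) placement
        dbest = SPACER_LEN - np.argmin(stack[::-1], axis=0)
        hit = mm <= max_mm_bulged
        for p, m, d in zip(a[hit], mm[hit], dbest[hit]):
            p = int(p)
            if p not in best:
                best[p] = ("dna", int(m), int(d))
    a = anchors[anchors >= SPACER_LEN - 1]
    if len(a):
        w19 = sliding_window_view(codes, SPACER_LEN - 1)[a - (SPACER_LEN - 1)]
        sdel = np.stack([np.delete(spacer, d) for d in range(SPACER_LEN)])
        stack = (w19[None, :, :] != sdel[:, None, :]).sum(axis=2)
        mm = stack.min(axis=0)
        dbest = SPACER_LEN - 1 - np.argmin(stack[::-1], axis=0)
        hit = mm <= max_mm_bulged
        for p, m, d in zip(a[hit], mm[hit], dbest[hit]):
            p = int(p)
            prev = best.get(p)
            if prev is None or (prev[0] == "dna" and int(m) < prev[1]):
                best[p] = ("rna", int(m), int(d))
    return best


def _as_sequences(genome) -> dict[str, str]:
    """Normalize a genome argument into {name: uppercase sequence}."""
    if isinstance(genome, Mapping):
        return {name: str(seq).upper() for name, seq in genome.items()}
    # pyfaidx.Fasta and similar record containers
    return {rec.name: str(rec[:]).upper() for rec in genome}


def enumerate_sites(
    genome,
    guides: Iterable[GuideSpec],
    max_mm: int = 5,
    max_mm_bulged: int = 4,
    pam_rules: Iterable[str] = ("NGG", "NRG"),
    include_scaffolds: bool = True,
    bulges: bool = True,
) -> list[CandidateSite]:
    """Exhaustively enumerate degenerate guide-matching loci on both strands.

    Parameters
    ----------
    genome : mapping of name -> sequence, or a pyfaidx.Fasta
    guides : guide specs; names must be unique
    max_mm : mismatch budget without a bulge
    max_mm_bulged : mismatch budget when a 1-bp DNA or RNA bulge is allowed
    pam_rules : PAM patterns accepted at any site (applied to all guides)
    include_scaffolds : when False, sequences whose name does not start with
        ``chr`` (unassembled scaffolds, by the naming convention of the
        synthetic genomes) are skipped
    bulges : disable to search substitution-only matches

    Returns sites sorted by (chrom, start, end, guide, strand); ambiguous
    genome bases (N) match no spacer base and invalidate any PAM.
    """
    guides = list(guides)
    names = [g.name for g in guides]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate guide names in {names}")
    pam_rules = tuple(pam_rules)
    sites: list[CandidateSite] = []
    for chrom, seq in _as_sequences(genome).items():
        if not include_scaffolds and not chrom.startswith("chr"):
            continue
        L = len(seq)
        if L < SPACER_LEN + PAM_LEN:
            continue
        for strand in "+-":
            oriented = seq if strand == "+" else revcomp(seq)
            codes = encode(oriented)
            pam_ok = _pam_anchor_mask(codes, pam_rules)
            for guide in guides:
                spacer = encode(guide.spacer)
                hits = _scan_oriented(codes, spacer, pam_ok, max_mm, max_mm_bulged, bulges)
                for p, (mode, mm, bpos) in hits.items():
                    wl = WINDOW_LEN[mode]
                    proto = oriented[p - wl : p]
                    pam = oriented[p : p + PAM_LEN]
                    if strand == "+":
                        start, end = p - wl, p + PAM_LEN
                        origin = p
                    else:
                        start, end = L - p - PAM_LEN, L - p + wl
                        origin = L - 1 - p
                    sites.append(
                        CandidateSite(
                            guide_name=guide.name,
                            chrom=chrom,
                            start=start,
                            end=end,
                            strand=strand,
                            mismatches=mm,
                            bulge=mode,
                            bulge_position=bpos,
                            protospacer_seq=proto,
                            pam_seq=pam,
                            pam_relative_origin=origin,
                            is_on_target=(mm == 0 and mode == "none"),
                        )
                    )
    sites.sort(key=lambda s: (s.chrom, s.start, s.end, s.guide_name, s.strand))
    log.info("enumerated %d candidate sites for %d guides", len(sites), len(guides))
    return sites
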