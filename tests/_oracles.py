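"""Independent brute-force oracles, deliberately naive.

These reimplement the degenerate site search position by position with plain
string operations so the vectorized scanner can be checked against them
exactly.  They share no code with the package beyond the alphabet.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_PAM_SETS = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "N": "ACGT"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_pam_match(triplet: str, rule: str) -> bool:
    return all(b in _PAM_SETS[s] for b, s in zip(triplet, rule))


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def bulge_oracle(spacer: str, window: str, mode: str) -> tuple[int, int]:
    """Exhaustive single-base-bulge alignment.

    For ``dna`` delete each genomic base of the 21-nt window in turn, for
    ``rna`` each spacer base, and take the minimum Hamming distance; ties go
    to the largest (PAM-proximal) placement index.
    """
    best = None
    if mode == "dna":
        for d in range(len(window)):
            mm = hamming(spacer, window[:d] + window[d + 1 :])
            if best is None or mm <= best[0]:
                best = (mm, d)
    elif mode == "rna":
        for d in range(len(spacer)):
            mm = hamming(spacer[:d] + spacer[d + 1 :], window)
            if best is None or mm <= best[0]:
                best = (mm, d)
    else:
        raise ValueError(mode)
    return best


def naive_enumerate(
    genome: dict[str, str],
    guides,
    max_mm: int,
    pam_rules=("NGG", "NRG"),
) -> set[tuple]:
    """Position-by-position substitution-only scan of both strands.

    Returns {(guide, chrom, start, end, strand, mismatches)} for comparison
    with the package scanner run with bulges disabled.
    """
    out = set()
    for chrom, seq in genome.items():
        seq = seq.upper()
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else naive_revcomp(seq)
            for p in range(20, L - 2):
                pam = s[p : p + 3]
                if "N" in pam or not any(naive_pam_match(pam, r) for r in pam_rules):
                    continue
                window = s[p - 20 : p]
                for g in guides:
                    mm = hamming(g.spacer, window)
                    if mm <= max_mm:
                        if strand == "+":
                            start, end = p - 20, p + 3
                        else:
                            start, end = L - p - 3, L - p + 20
                        out.add((g.name, chrom, start, end, strand, mm))
    return out
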