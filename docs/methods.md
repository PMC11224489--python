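# Methods

`rametscreen` re-implements, as a tested library and CLI, a targeted-capture
survey of CRISPR/Cas9 off-target and somatic mutations in clonally
propagated cohorts (e.g. field-grown transgenic trees, where the editing
transgene stays in the genome for years).  This note documents the models,
conventions, and numerical choices behind each stage, what the synthetic
cohorts do and do not emulate, and the design decisions taken where the
procedure was genuinely open.

## Degenerate site search

A *candidate site* is any genomic window that a guide's 20-nt spacer could
bind adjacent to an accepted PAM.  The search accepts:

- up to `max_mm = 5` substitutions with no bulge;
- up to `max_mm_bulged = 4` substitutions together with a single-base DNA
  bulge (one unpaired genomic base; 21-nt window) or RNA bulge (one unpaired
  spacer base; 19-nt window);
- NGG and NRG PAMs (R = A/G; NRG is a superset of NGG).

The scan anchors on every PAM-matching triplet of both strands and scores
the adjacent window with vectorized mismatch counting; for bulge modes the
score is the minimum over all single-base bulge placements, ties resolved
toward the PAM-proximal end.  This exhaustive sweep needs no index and is
equal by construction to a naive position-by-position scan — the test suite
asserts exact agreement with an independently written brute-force oracle,
and a property test checks each bulge score against an exhaustive deletion
oracle.

Conventions worth stating because everything downstream depends on them:

- Coordinates are 0-based half-open internally; BED output is unchanged,
  VCF output converts to 1-based.
- PAM-relative positions: PAM bases are +1, +2, +3 (+1 adjacent to the
  protospacer); protospacer bases are −1 … −20 with −1 PAM-adjacent.  There
  is no position 0.  The SpCas9 blunt cut falls between −3 and −4, making
  −3 the canonical cleavage-adjacent base.
- A locus matching under several bulge modes at the same PAM anchor is
  reported once: the bulge-free interpretation wins whenever it is within
  the substitution budget, otherwise the bulged mode with fewer mismatches
  (DNA before RNA on ties).  This keeps output deterministic.
- Ambiguous genome bases (N) match no spacer base, and an N anywhere in the
  PAM triplet fails every rule — conservative on assembly gaps.
- The on-target (0-mismatch, bulge-free) site is enumerated and flagged, so
  on-target edits are scored through exactly the same machinery.

Not modeled: FM-index/bitap acceleration, 5′-PAM or PAM-less nucleases,
chromatin-aware activity scores.

## Capture design

Each candidate site gets one 80 bp probe centered on the site span (odd
spans round the midpoint toward the lower coordinate, for determinism);
probes overhanging a contig edge are shifted inward to keep full length.
`flank_offset` shifts a probe into flanking sequence, the generic stand-in
for re-designing a probe whose centered sequence is unusable — vendor
synthesis scoring and hybridization thermodynamics are out of scope.  The
probe spans double as the screening/coverage intervals (optionally merged).

## Variant screen and logic-tree

Samples are pooled per genotype in the tumor/normal style: wild-type and
Cas9-only controls form the "normal" pool, all edited events and ramets the
"tumor" pool.  The screen consumes per-position allele-observation tables
(pileups), not reads.  A candidate is any (position, alt allele) with

- pooled edited support ≥ `min_alt_reads` (default 6 — "more than five
  reads"), and
- pooled edited AF > `min_tumor_vs_normal_ratio` (default 3) × the pooled
  control AF, the control AF floored at the per-base error rate so control
  dropout cannot manufacture an infinite contrast.

Survivors then pass a manual-scoring logic-tree, each exclusion recorded
(never silently dropped):

- `low_support`: no single sample supports the alt with more than five
  reads;
- `in_normal`: control AF ≥ `similarity_margin` (default 0.5) × edited AF —
  the operationalization of "the wild type shows similar frequencies";
- `alignment_artifact`: the alt recurs at ≥ 5% AF in ≥ 90% of *all*
  samples including controls (germline or mapping artifact), or an indel
  alt lies in a reference homopolymer run of ≥ 8 bp.  These two heuristics
  are declared stand-ins for case-by-case visual review of alignments; both
  are config-exposed.

Passing variants are classified by distance to the nearest candidate-site
border: within 20 bp (inclusive) they are *off-target*, beyond that
*somatic*.  Ties between sites break by distance, then fewer mismatches.
Indels are keyed by left-aligned position and a canonical `del:<len>` /
`ins:<seq>` encoding so the same event has a stable identity across
samples.  An off-target site is *confirmed* when at least `min_ramets`
(default 2) edited samples strictly exceed `af_threshold` (default 10%)
mutant allele frequency.  Note the strictness: a site whose true AF sits
exactly at the threshold is a coin flip per ramet, so recovery guarantees
are only made from 0.15 upward (and verified there).

External candidates can be imported from VCF and pushed through the same
logic-tree and classification.

## PAM-relative read counting

A sample's mutant allele fraction at a site counts a read as mutant when it
carries any non-reference base or indel breakpoint in the PAM-relative
window [+2 … −5] — PAM bases +2 and +1, then protospacer −1 … −5, seven
positions straddling the cut.  On pileups this is approximated by the
maximum alt-observation count across the window, exact when a mutant read
carries one variant (the regime the screen operates in).  Details that
matter numerically:

- A deletion is in-window when its left-aligned breakpoint interval
  intersects the window's genomic span, even if anchored upstream.
- The AF denominator is the depth of the rows that supplied the counted
  observations (a spanned deletion's anchor), never an unrelated position's
  depth; among window positions the one with the strongest mutant fraction
  is taken, which is the variant's anchor in practice.
- With no mutant observations the total is the median window depth (the
  maximum would overstate coverage).
- Zero coverage yields an NR (no-reads) measurement, distinct from AF 0.
- All reads are counted; the 150–200-read cap of manual scoring was a labor
  limit, not a statistical choice, and is not reproduced.
- The PAM-relative position attributed to an indel is its cut-proximal
  altered base, so a multi-base deletion reaching −3 reports −3.

Haplotype-resolved assemblies are handled by `merge_phased`: the two copies
of a site are pooled by read counts (a read-count-weighted mean AF) through
an explicit correspondence table — phasing itself is an input, never
inferred.  A fully edited site present on only one allele therefore caps
near 50% merged AF.

The mutation spectrum is a histogram of allele counts per PAM-relative
position, separable into on-target and off-target site groups and weighted
by carrier ramets.  Sharing statistics score each (site, event) with ≥ 2
ramets as shared (all ramets above threshold), single-ramet (exactly one),
or unedited, plus the fraction of single-ramet events whose ramet AFs lie
within 0.05 of each other.

## Rates, coverage, density

The per-bp mutation rate for a category is

    rate = Σ_samples (distinct mutated positions carried by the sample)
           / Σ_samples (callable surveyed bp)

where a sample carries a variant when its alt support exceeds five reads
(the logic-tree's own per-sample threshold), and callable bp are interval
positions with depth ≥ 20 (config).  The source study never states its
denominator, so this estimator is this package's own definition and is
deliberately prominent here; a config switch counts distinct positions
instead of (position × sample) events.  An exact (chi-square inversion)
Poisson 95% CI accompanies every estimate; zero counts give a one-sided
interval.

Coverage summaries first average depth within sample (over the whole
capture space or per chromosome), then treat each per-sample mean as one
measurement: mean, sample SD (n−1), and CoV = SD/mean per construct or
chromosome.  Site/gene density uses fixed tiling windows (default 500 kb on
real genomes; 5 kb on desk-scale synthetic ones), assigns genes and sites
by midpoint, and reports Pearson r (matching a linear fit) with a two-sided
p; constant counts or fewer than 3 windows raise rather than returning a
meaningless value.

## Synthetic cohorts

The generator emulates the surveyed study design, and its defaults are the
conditions under which the acceptance properties are stated:

| parameter | default | what it emulates |
|---|---|---|
| events × ramets | 8 × 2 | independent insertion events, two clonal copies each |
| controls | 6 (wild-type/Cas9-only alternating) | the pooled "normal" samples |
| depth | NB, mean 200, SD 60 | capture depth with realistic overdispersion (CoV ≈ 0.3 per site; population-level CoV in the study ran 0.8–1.3) |
| per-base error | 1e-3 | post-filter sequencing/mapping noise |
| planted off-target AFs | 0.05, 0.10, 0.15, 0.5, 1.0 | the editing range from marginal to fixed |
| CRISPR indels | 80% deletions (geometric p=0.5, ≤10 bp), 20% 1 bp insertions, anchored at −3 | cleavage-site-concentrated repair outcomes |
| ramet jitter | N(0, 0.02), truncated | mostly-shared, occasionally divergent ramets |
| somatic rate | 5e-8 /bp/sample, AF ~ U(0.1, 0.5) | rare background somatic variation |

Planting is verified by rejection sampling: a locus is accepted only when
re-scanning its neighbourhood finds exactly one site, with exactly the
requested mismatch count and bulge mode — so a DNA-bulge plant that
happens to align better bulge-free, or that spawns an overlapping shadow
interpretation at an adjacent PAM, is re-drawn.  `editing_propensity` is
the per-haplotype edited-cell fraction of an event; the event-level true AF
equals it for bi-allelic sites and half of it for mono-allelic ones (the
50% cap).  The study gives no distribution for it, so it is config, not an
assertion.

Reads are abstracted as per-position allele counts.  Consequences worth
knowing: depth is drawn independently per position (no fragment-level
autocorrelation), deletions deplete reference support at spanned positions
but read-level haplotype structure is not represented, and there is no
mapping error, capture-efficiency, strand-bias or base-quality modeling.
Passing tests therefore demonstrate the *logic* of the screen under
calibrated noise, not robustness to alignment pathology — the
alignment-artifact heuristics are exercised by construction, not by
simulated mapping failures.

Two special-purpose generators keep the heavier statistical checks honest
at desk scale:

- `phased_monoallelic_cohort` builds replicate mono-allelic sites on
  haplotype-resolved contig pairs (depth 200 per haplotype) to test
  counting + merging end to end;
- `simulate_somatic_cohort` plants Poisson(rate × footprint) somatic
  mutations per edited sample on a virtual contig and emits pileup rows
  only at mutated positions, reporting the callable footprint analytically
  — 10^8 surveyed bp would otherwise be all reference rows.  Problem sizes
  used by the tests: 20 edited samples × 5×10^6 bp per sample (10^8 summed),
  100 replicate seeds.

Everything is deterministic under a fixed seed, and the truth ledger is
exhaustive: all non-error variation is planted and recorded.

## Known limitations

- Published headline numbers of the motivating study (genome-wide site
  counts, its off-target/somatic rates, the gene-density r) depend on
  unreleased guide sequences, two reference genomes, and an unstated rate
  denominator; they are not reproducible from this artifact and are not
  claimed.  The pipeline reproduces the *procedures* and verifies them on
  truth-known data.
- Large structural variants and epigenetic changes are undetectable by
  design (targeted small-variant screen).
- The pooled screen needs at least one control per genotype; a cohort
  without controls is a configuration error, not a degraded analysis.
- Confirmation at the exact 10% threshold is a coin flip per ramet (strict
  exceedance); guarantees start at 0.15 true AF.
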