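# Methods

## Scaffold model

The target event is a tandem-duplication insertion phased against a nearby
SNV. A `ScaffoldSet` holds the wild-type region (WT) and a mutant scaffold
(MU) built as `WT[1..ip-1] + copy + WT[ip..]`, where `copy` is the duplicated
segment with the insertion allele's divergent bases applied and an engineered
marker base written at one conserved offset. Placing the modified copy
*upstream* of the retained original segment is a deliberate choice: it is the
unique tandem arrangement in which (a) the marker lies inside the inserted
copy and (b) the genuine cis SNV falls at the *downstream image* of the SNV
site (WT position + insertion length; 3252 = 3184 + 68 on the CBS-analog
fixture), so the two signals are physically separated on the MU scaffold.
Coordinates are 1-based, closed, plus-strand throughout; transcript-style
(minus-strand) nomenclature appears only in documentation.

The builder validates the specification (tandem insertion point, marker
inside the copy and different from the copied base, divergent bases actually
divergent, SNV ref base matching the reference) but does not — and cannot —
verify biological conservation of the marker position; choosing a conserved,
polymorphism-free marker site is the designer's responsibility.

## Synthetic fixture

`fixtures.cbs_synthetic_scaffolds()` generates a deterministic 5000 bp
stand-in for the CBS locus: random flanking sequence from a fixed internal
seed, with the real locus's coordinate structure imposed (segment 3173–3240
duplicated, SNV 3184A>G whose cis image is 3252, marker offset 38 → MU 3210
natural G / scaffold C, anchor chr21:44,480,001). The exact offsets of the
real alleles' divergent bases are not machine-readable from public
descriptions, so the fixture places the common allele's three divergent bases
at insertion offsets {5, 30, 60} and the rare allele's extra base at {45};
all offsets are configuration, so real allele sequences can be substituted.

What the synthetic sequence does *not* emulate: genome-scale context (reads
cannot be attracted away by off-target homology), real base-composition and
repeat structure, and instrument-specific error spectra. Passing tests
therefore demonstrate the competition logic, the decision table, and the
breakpoint/marker geometry — not robustness to capture artifacts or mapping
ambiguity beyond this locus.

## Read simulation

`simulate_pairs` draws `round(mean_len · coverage / (2 · read_length))`
fragments (defaults: 200X, 2×150 bp), picking a haplotype per fragment by
fair coin, a Normal(300, 100) length resampled until it fits in
`[read_length, len(hap)]` (never truncated), a uniform start, and a random
strand flip for the mate-1/mate-2 roles. Errors are i.i.d. per-base
substitutions at 0.1% with the matching constant Phred quality (Q30);
indel errors, quality profiles, chimeras, contamination and PCR duplicates
are not simulated (a coordinate-identity dedup hook exists in the caller,
off by default). This simplification is justified because the method's
output depends on allele identity at three sites, not on error spectra.
Haplotype molecules always carry the *natural* base at the marker offset —
the engineered scaffold base exists only in the MU scaffold, which is what
makes the marker call predetermined.

The per-haplotype pair count uses the mean haplotype length in the coverage
formula (haplotypes differ by 68 bp for heterozygous insertion genotypes).
Read length must exceed the insertion length for the marker-coverage
guarantee (every marker-covering read spans a junction); the caller warns if
violated.

## Aligner

Seed-and-extend: exact 15-mers sampled every 10 read positions vote for
diagonals per scaffold; a full-length exact match at the top diagonal is
accepted directly (it is necessarily optimal), otherwise an affine-gap
local DP (Smith-Waterman with traceback, numba-compiled) runs over the
window spanned by the candidate diagonals padded by 90 bp (diagonals more
than 220 from the best are dropped; this comfortably covers the ±68
junction shift). Local alignment with free ends is exactly "soft clips are
free, clipped bases score 0". Scores: +1/−4, gap of length g costs
6 + (g − 1); the defaults were chosen so one 68 bp gap (−73) outweighs four
divergent-base mismatches (−16), reproducing forced soft-clip alignment of
insertion reads on the WT scaffold, and are fully configurable. Placements
aligning fewer than 25 read bases are unmapped. Both orientations are tried
per scaffold (forward wins ties). Equal-scoring placements resolve to the
first maximal DP cell in row-major order — a deterministic leftmost-end
rule; a production aligner's random assignment of non-specific matches is
deliberately not reproduced, and the downstream pileup competition makes the
choice irrelevant (such pairs tie across scaffolds).

Mates are paired per scaffold; the pair score is the sum over placed mates
(a mate unmapped on one scaffold contributes 0 there; the pair is unmapped
on a scaffold only if both mates are). The proper-pair flag requires FR
orientation with insert within mean ± 4 sd; impropriety only clears the
flag, it does not change the score. SAM export (one file per scaffold,
MAPQ 60/0 for strict/tied) is offered for inspection but is not part of the
calling path.

## Calling policy

Pair classification: MU_STRICT iff `score(MU) − score(WT) ≥ 1` (one match
score), symmetrically WT_STRICT, else TIE. The pileup policy is the central
design decision the competition enables:

* MU sites (marker 3210, cis image 3252) count **only strictly-MU pairs** —
  under error-free input every counted base at the marker is the natural
  allele (fraction exactly 1.0 when any haplotype carries the insertion,
  depth 0 otherwise), and the 3252 fraction reads out which insertion
  haplotypes carry the SNV (HOM = all of them = cis complex; HET = half =
  insertion in trans with complex).
* The WT SNV site 3184 counts **every** mate's WT placement except reads
  whose WT placement has a soft clip ≥ 12 bases (12 = distance from the
  insertion breakpoint to the SNV), mimicking a caller that ignores
  soft-clipped evidence. Reference-allele bases leaked by insertion-homolog
  reads that survive the clip filter are what keep this site heterozygous
  (not hom) for SNV-in-trans-with-complex genotypes, and near-zero for
  complex-only carriers.
* Single-reference mode counts all WT placements (clip filter applied) and
  reports the naive zygosity — the comparison mode that shows the suppressed
  allele fraction for cis carriers.

Bases under clips or gaps never count; bases below Q13 are dropped (guards
the fraction thresholds against simulated errors); both mates of an
overlapping pair contribute (base evidence is not deduplicated within a
fragment). Zygosity bands: absent < 0.20 ≤ het < 0.80 ≤ hom, minimum depth
15 (the screening assay's minimum base coverage).

The decision table gates on the marker: insertion present iff the marker is
HOM with adequate strictly-MU depth. With no marker evidence the WT site
alone separates wild-type from SNV het/hom; with a HOM marker the
(WT, cis) states select among the five insertion-bearing rows. A HET marker,
or cis-image evidence without marker evidence, cannot arise from clean
competition and yields NO_CALL. Of the 27 three-state signatures, 8 are
valid (SNV het and hom are separate signatures of one table row) and
pairwise distinct; everything else is NO_CALL. Complex-variant *dosage*
(het vs hom) is intentionally not resolved — both produce (absent, HOM,
HOM), matching the table's granularity — and the call is reported as
"insertion zygosity undetermined". The same applies to the insertion-only
row.

## Cohort statistics

Carrier rates are 100·k/n rounded half-up to two decimals. The two-sided
Fisher's exact test (sum of hypergeometric probabilities ≤ the observed
table's, the convention of standard statistical software) is delegated to
scipy; tests cross-check it against an exact rational enumeration oracle.
Zero-margin tables are defined as p = 1. The packaged fixture stores the
published per-population carrier counts and totals verbatim, including four
printed-rate cells that are arithmetically inconsistent with their own
counts (flagged in the fixture's `note` column); p-values are always
recomputed from the counts. No multiple-testing correction is applied, and
confidence intervals are out of scope.

## Problem sizes and determinism

The acceptance script and the full-scale tests use the method's study
conditions: 5000 bp region, 200X, 2×150 bp, N(300, 100) fragments, 0.1%
errors, 7 genotypes × 20 replicates (140 end-to-end calls, ~3 minutes on one
CPU). Unit tests use 30–80X, which still saturates the 15× depth gate at the
informative sites. All randomness flows through numpy `SeedSequence`-derived
seeds; identical seeds give byte-identical FASTQ and identical calls.

## Known limitations

* Single-locus scope: no genome-scale mapping, no capture/duplicate
  artifacts, no base-quality-aware alignment scoring.
* Deletion-type scaffolds are a straightforward extension but are not
  implemented or tested.
* The het/hom dosage of the insertion (alone or in the complex allele) is
  not resolved; a depth-ratio heuristic could be added but is deliberately
  absent from the decision table.
* The equivalence check for shifted insertion descriptions compares applied
  allele strings; it does not parse or validate HGVS.
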