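# Methods

This note records the models, statistics and numerical choices behind
`mirtarget`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one reasonable convention
exists.

## Seed words and hierarchical site counting

A mature miRNA (RNA, 5′→3′, ≥ 8 nt) defines four target-strand DNA words:

| class   | definition                                   | miR-145    |
|---------|----------------------------------------------|------------|
| 6mer    | reverse complement of miRNA positions 2–7    | `ACTGGA`   |
| 7mer-m8 | reverse complement of positions 2–8          | `AACTGGA`  |
| 7mer-1A | 6mer followed by `A`                         | `ACTGGAA`  |
| 8mer    | 7mer-m8 followed by `A`                      | `AACTGGAA` |

The `A` opposite miRNA position 1 is matched literally regardless of its
pairing potential. Counting is *hierarchical*: every raw occurrence of the
6mer core is assigned to exactly one class by its flanking bases
(preceding base completing the 7mer-m8 → m8 context; following `A` → 1A
context; both → 8mer; neither → plain 6mer). This is equivalent to
discarding occurrences contained inside a longer site's interval, and it
makes the class counts sum exactly to the raw core count — an identity
the tests verify against an independently coded containment oracle.

Conventions: scanning is sense-strand only (miRNA targeting acts on the
mRNA); any window containing `N` is a non-match and an `N` flank is a
non-matching flank, as are sequence ends; overlapping occurrences of the
same class are each counted. Site positions are exported 0-based,
half-open, starting at the full site word (8mer/7mer-m8 sites start one
base 5′ of their core).

## Regulation sets

Expression input is a matrix of normalised log2 intensities with ≥ 2
replicates per condition. Probesets mapping to more than two genes are
discarded; a two-gene probeset contributes to both genes; among probesets
serving one gene the largest inter-quartile range across all samples wins
(ties → lexicographically smallest probeset id, for determinism).
Non-specific filtering removes genes with across-array variance < 0.25
(unbiased, n−1 denominator; a variance exactly at the cutoff is kept — the
boundary is a package convention, stated here because the cutoff alone
does not fix it).

Differential statistics are a per-gene Welch t-test (two-sided) with
Benjamini–Hochberg correction; logFC = mean(treated) − mean(control) in
log2 units. A moderated-variance statistic would differ mainly at very
small replicate numbers; users with externally computed tables (e.g. from
limma) can supply them directly as TSV and skip this stand-in entirely.

Sets: FDR < 0.25 with logFC > 0 → up, with logFC < 0 → down; FDR > 0.8 →
no-change. Genes in the middle band 0.25 ≤ FDR ≤ 0.8 (and the measure-zero
case FDR < 0.25, logFC = 0) are retained as *unassigned* rather than
silently dropped. The functional-export set takes |logFC| > log2(1.1) by
default — reading the published threshold of 1.1 as a fold change; the
literal log2-units reading (cutoff 1.1) is available by argument, since
both readings appear in the source material and they differ by a factor
of ~8 in stringency.

## Enrichment tests

All set comparisons use a two-sided pooled two-proportion z-test without
continuity correction (identical to the 1-df chi-square test, which the
tests use as an oracle at 1e-10 relative tolerance); a degenerate pooled
proportion (0 or 1) returns p = 1. Three metrics:

- **percent of genes**: genes with ≥ 1 site over genes in the set;
- **per kb**: class counts over scanned positions Σ(len − k + 1) — valid
  start positions, not raw length; the distinction is negligible at UTR
  scale but must be pinned for reproducibility;
- **downscaled counts**: sets first subsampled without replacement to the
  smallest set's size (seeded), then counts compared over positions.

The four exclusive classes are reported alongside a pooled
7mer-m8 + 7mer-1A + 8mer class (`pooled_7_8mer`); the 6mer class stays out
of the pool because it is both the weakest and the noisiest class. Tests
are two-sided throughout (the null is a point null with no direction).

## Unbiased word analysis

For word *w* and sequence *s*: *m* = occurrences of *w* in *s* (sliding
window, overlaps counted, `N` windows excluded). The null is *B*
mononucleotide permutations of *s* (uniform Fisher–Yates; `N` permuted
with the rest), preserving length and composition exactly. With *N(m)* the
number of shuffles containing ≥ *m* occurrences, the score is

    score(w, s) = −log10((N(m) + 1) / (B + 1))

which is 0 when the word is no rarer than chance (and exactly 0 when
m = 0, so absent words need not be materialised) and log10(B+1) ≈ 3.7 at
B = 5000 when no shuffle reaches the observed count. The +1 is a small-
sample correction that also avoids log(0). Any monotone transform of the
null tail would give identical word *rankings*; this specific form is
pinned so that scores are comparable across runs. B defaults to 5000;
tests and quick CLI runs use B = 200, which changes scores only through
sampling noise in N(m) (the planted-signal rank-1 outcome is stable
across B ∈ {100, 200, 1000}).

Sequences are ranked by ascending logFC (most down-regulated first), so
down-regulation enrichment produces an early peak of the running sum
S_i = Σ_{j≤i}(score_j − mean score). The word statistic is max_i S_i
(one-tailed for top-of-list enrichment; the opposite tail is a matter of
reversing the ranking). S_n = 0 by construction up to float error
(tolerance 1e-9·n), and the profile is invariant to adding a constant to
all scores.

z-scores standardise the observed statistic against the same word's
statistic under P random permutations of the ranked order (sample sd,
ddof 1; z = 0 when sd = 0, which also covers words absent everywhere).
The FDR at a word's z is the fraction of *pooled* permutation z-values at
or above it divided by the fraction of observed z-values at or above it,
clipped to [0, 1]; the raw ratio is then made monotone non-increasing in
z by the q-value convention (running minimum over less-significant
thresholds). Its resolution floor is 1/(P·4^k) — published word tables
that report only bounds like "< 0.002" are consistent with exactly this
kind of floor. Per-sequence shuffle streams and the permutation stream
are independent children of one seed (`numpy` `SeedSequence.spawn`), so
results are bit-reproducible and a sequence's scores depend only on its
content and list position, not on its label.

Word annotation marks complete matches to a seed word with the miRNA id
and class, and partial matches (longest common substring with the 8mer
word ≥ 5 nt) as `partial` — mirroring the usual presentation of word
tables where near-seed variants are underlined.

Memory/runtime: the score matrix is dense float32 (n × 4^k); k is guarded
to [4, 8]. At n = 2000, k = 7, B = 200, P = 100 a full analysis takes
~2–3 minutes on one CPU.

## Promoter TFBS enrichment

PSSM construction from a count matrix with column totals n_j:
w(b, j) = log2(((c(b,j) + q) / (n_j + 4q)) / 0.25) with pseudocount q = 1
applied per cell (standard Laplace smoothing) and a uniform background. A
window's relative score is (S − S_min)/(S_max − S_min) where S_min/S_max
are the column-wise minimal/maximal sums, so the consensus scores 1 and
the anti-consensus 0 for every matrix; hits are windows with relative
score ≥ 0.8. A relative threshold was chosen over an absolute log-odds
cutoff because a fixed bit threshold is not comparable across matrices of
different lengths. Scanning covers both strands by default (promoters are
double-stranded regulatory DNA; plus-only is available); minus-strand hit
coordinates are reported on the input frame; `N` windows are skipped.

Only presence/absence (≥ 1 hit) per promoter enters the set comparison —
matching how such results are conventionally tabulated as percentages —
via the same two-proportion test. The negative control permutes a
matrix's columns (never the identity), preserving composition and
per-column information content while destroying positional structure.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes:

- **Sequences**: i.i.d. bases (default uniform composition); lengths
  log-normal — 3′UTR median 1000 nt (σ = 0.6), CDS median 1300 nt
  (σ = 0.5), 5′UTR median 150 nt (σ = 0.5), chosen as round figures in
  the range of human transcript annotations; promoters fixed at 2000 nt
  (the window upstream of the TSS used for motif scanning).
- **Targets**: 15% of genes. Each target independently receives one
  planted site per class with probabilities 0.3/0.6/0.4/0.4
  (8mer/7mer-m8/7mer-1A/6mer) and a per-site logFC shift of
  −0.6/−0.4/−0.3/−0.1 — the ordering follows the canonical site-strength
  hierarchy; the magnitudes are free parameters chosen so planted signals
  are strong but not trivial at a few hundred genes per set.
- **Planting** is rejection-sampled: a placement is accepted only if the
  full hierarchical classification changes by exactly the planted site,
  so ground truth is category-exact (`n_planted_*`), and pre-existing
  chance sites are recorded separately (`n_sites_*` = planted + chance).
- **Expression**: control replicates = gene baseline + N(0, 0.25²) noise;
  treated replicates add the gene's total true shift plus a global
  displacement of +0.226 logFC applied to *every* gene — reproducing the
  technical artefact observed in the motivating dataset so that
  set-definition code is exercised on displaced data. 4 vs 4 replicates
  by default (configurable to 4 vs 3 to emulate a dropped array).
- **Regulons** (optional): a member fraction gets the motif consensus
  planted in their promoters at one rate, everyone else at a background
  rate, plus a coherent expression shift.

What the generator does **not** emulate: real base composition and
repeat structure of UTRs, probe-level noise and normalisation artifacts,
correlated genes, conservation, or non-canonical sites. Passing tests
therefore demonstrate that the statistics recover the structure they
assume — planted sites, coherent shifts, calibrated nulls — not that the
pipeline is robust to every artifact of real microarray data.

A note on the displacement: at default effects the global +0.226 shift
pushes the mean logFC to ≈ 0.14 (targets pull it down); with effects
zeroed the mean equals the displacement. The shift also makes the *down*
set scarce under weak effects — an intended stress: genes only enter the
down set when their planted shift beats the displacement plus noise.

## Problem sizes used in validation

The test suite runs the site-classifier oracle on 1000 random sequences
(50–3000 nt), the shuffle-null enumeration on all arrangements of ≤ 8 nt
sequences at B = 5000, the planted-word recovery at n = 2000 sequences
(B = 200, P = 100, k ∈ {6, 7}), the PSSM controls at 500 promoters per
set over 100 seeds, and the end-to-end chain at 800 genes over 100 seeds;
`scripts/acceptance.py` uses 2000 genes with B = 200, P = 50. These sizes
keep a full validation run in the ten-minute range on one CPU while
leaving every statistic far from its decision boundaries.

## Known limitations

- Welch t + BH is a stand-in for moderated statistics; at n = 4 vs 4 its
  p-values are noisier than limma's, which mainly thins the regulated
  sets rather than biasing enrichment.
- The two-proportion z-test is asymptotic; with very small sets (a few
  genes) its p-values are approximate and the downscaled metric is noisy.
- The word-analysis FDR inherits the permutation floor 1/(P·4^k); P = 100
  cannot distinguish FDR 1e-3 from 1e-6.
- The mononucleotide null conditions on composition only; dinucleotide
  structure (CpG depletion, repeats) in real UTRs can inflate scores of
  repeat-like words — in ranked-list comparisons this cancels between
  permutations but can still shape which words reach the top.
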