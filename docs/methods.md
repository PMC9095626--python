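# Methods

## Problem and model

Return-to-growth (RTG) starts meiosis in a polyploid *Saccharomyces
cerevisiae* hybrid, lets Spo11-induced double-strand breaks (DSBs) recombine
the replicated homologs during prophase, and returns the cells to mitotic
growth before commitment to sporulation. The 2p chromatids (p homologs, two
sisters each) then segregate one-sister-per-homolog into the mother and
daughter of the first mitotic division. A crossover (CO) whose two
recombinant chromatids end up in different cells produces complementary
loss-of-heterozygosity (LOH) tracts — reciprocal allele-dosage changes over
the same interval — while a non-crossover (NCO) gene conversion is a
one-sided copy of donor sequence onto the broken chromatid and therefore
shows in at most one cell.

In short-read data the observable is, at each heterozygous marker, the
alternative-allele read fraction (AF). With parental Alt dosage k of ploidy
p the expected AF is k/p; recombination moves it to k'/p. The pipeline
infers k' per marker, assembles runs of consecutively shifted markers into
AF-shift regions, filters artifacts, and interprets mother–daughter (M-D)
pairs jointly.

## Per-marker shift call

For a marker with parental dosage k of p and observed AF a (from the AD
field), the inferred dosage k' is the integer nearest p·a, with exact ties
resolved toward k. A marker is *shifted* when:

* total depth ≥ `min_depth` (default 10 reads, the floor also used when
  declaring an unreported position "sequenced"),
* k' ≠ k, and
* |a − k/p| ≥ guard, with guard defaulting to **0.4/p** dosage steps.

Markers between the guard and the rounding midpoint are assigned the
adjacent dosage in the direction of movement. The guard's operating point
is deliberately inside the midpoint (0.5/p): the region rule below demands
nine *consecutive* shifted markers, so isolated per-marker false positives
are almost free (a false region needs nine in a row), whereas a per-marker
miss splits a run and can drop whole sub-runs. Quantitatively, with
per-marker miss rate q the expected marker-level recovery of a long tract
is ≈ (1−q)(1−36q²); at 50× depth a tetraploid ±1-dosage transition has
q ≈ 0.03 under a midpoint rule (recovery ≈ 0.94) but q ≤ 0.01 under the
0.4/p rule (recovery ≥ 0.98), at a per-marker false-shift cost fully
absorbed by the run requirement (measured precision ≥ 0.999). The guard is
configurable; an exact binomial test of AF = k/p (`method="binomial"`,
configurable α) is available as an alternative criterion.

Markers absent from a sample's VCF are homozygous-reference candidates when
the depth track shows ≥ `min_depth` coverage at the position (AF treated as
0, k' = 0), and `missing` otherwise. A present record whose alleles do not
match the catalogued ancestral ref/alt is set to `missing` and counted in
the QC report. Missing markers break runs — a stricter choice than
skipping them, avoiding regions bridged across unsequenced gaps.

## Regions, percentage, filters

Maximal runs of ≥ `min_run` (default 9) consecutive shifted markers become
regions spanning first-to-last shifted marker (exported BED, 0-based
half-open). Mixed shift directions are allowed within a run: without
phased haplotypes, locally homozygous stretches between the two recombining
haplotypes fragment one physical event into runs of varying direction. The
percentage of the genome recombined is reported as markers inside retained
regions over all catalogue markers, excluding configured chromosomes (e.g.
one carrying an engineered selection locus) and subtelomeric margins
(default 25 kbp per end; user-overridable with a BED — subtelomere
coordinates are otherwise not well defined).

Filters run in a fixed order and can only remove or shrink regions:

1. **Recurrence** — within a dataset, a region covered for > 80% of its
   length by a single region in ≥ 70% of samples (focal sample included in
   both counts) is treated as pre-meiotic and removed. Datasets with < 3
   samples skip this filter; the fractions are against the focal region's
   own length.
2. **T0** — regions covered ≥ 90% of their length by the union of the
   unsporulated control's regions.
3. **Positional** — subtelomere margins, parental CNVs, parental engineered
   regions: a region losing > 50% of its length is dropped, otherwise
   trimmed (both thresholds and a forced drop/trim mode are configurable).

## Coverage, CNV, aneuploidy

Depth tracks are averaged over non-overlapping windows (10 kbp, plus a
1 kbp small-scale pass) and normalized by the chromosome median, so c of p
haplotypes sit at ratio c/p. Runs of ≥ 3 windows beyond ratio 0.8 / 1.2
become loss/gain calls with copy change round(ratio·p) − p; the thresholds
replace a manual log2-profile inspection step and are configurable.
Chromosome-median normalization is blind to whole-chromosome changes by
construction, so aneuploidy screening uses genome-median normalization and
flags a chromosome when its median log2 ratio exceeds half the one-copy
shift log2((p±1)/p). A warning is emitted when terminal windows
systematically deviate (positional coverage bias); no correction is
attempted.

## M-D pairs and phasing

Mother and daughter regions are matched at ≥ 50% reciprocal span overlap
(of the shorter region); a match is *reciprocal* when ≥ 80% of the markers
shifted in both cells move in opposite directions, otherwise (and for
unmatched regions) *non-reciprocal* — the gene-conversion candidates,
typically small (< 2 kbp), which a 9-marker threshold under-detects; a
low-stringency pass (`min_run` down to 3) is available for exploration.
Thresholds are package defaults, not literature values.

Within a reciprocal region, each marker shifted by one dosage unit exposes
two haplotypes: the gained allele belonged to the donor haplotype and its
complement to the recipient, and the remaining p−2 haplotypes carry k−1 Alt
alleles in total (for a triploid this pins the third haplotype exactly; for
a tetraploid the remaining two haplotypes are determined as a multiset —
the dosage algebra generalization beyond the triploid case is an extension
of this package). Recipient/donor labels are arbitrary per block;
cross-validation against a second pair covering the same interval compares
both labelings and reports the better agreement together with the number of
comparable markers. Pairwise recombination landscapes are compared as
Jaccard distances between shifted-marker sets (empty vs non-empty = 1 by
convention).

## URA3-loss assay

LOH rate at a timepoint is 100 × CFU(5-FOA)/CFU(YPD) after explicit
dilution correction (corrected counts are the canonical representation;
plating dilutions are inputs, not assumptions). Fold increase and absolute
difference compare timepoint means with T0 (per-replicate values are also
exported); the increase is tested with a one-sided Wilcoxon rank-sum:
exact by full enumeration for small tie-free groups (5-vs-5 complete
separation gives exactly 1/252), exact permutation enumeration with
midranks when small groups contain ties, normal approximation with
continuity and tie corrections otherwise. Two identical groups return
p = 1 with a warning. Note the discreteness of the exact null: at n = 5
vs 5 the attainable p-values are multiples of 1/252, so a nominal α = 0.05
realizes a type-I rate of 11/252 ≈ 0.044.

## The simulator

The generator emulates the study system: a ~12 Mb, 16-chromosome genome at
triploid or tetraploid ploidy with ~3.4 heterozygous markers/kbp (~40 K
genome-wide), optional aneuploid chromosomes, pre-existing LOH blocks
(marker-free), and subtelomeric margins.

* **Ancestry blocks.** The parent is a lineage mosaic: marker dosage and
  the carrier-haplotype set are constant within exponential blocks (mean
  50 kbp, configurable; dosage distribution over {1..p−1} uniform by
  default and configurable per ploidy). This is what makes a single
  recombination event shift long runs of consecutive markers, as in real
  hybrids; with independent per-marker draws (`haplotype_block_mean=None`)
  the two recombining haplotypes agree at about half the markers and
  9-consecutive-marker runs essentially never form.
* **Recombination.** DSBs are Poisson-uniform along chromosomes (an
  optional intensity track supports hotspot maps; none is bundled because
  no per-strain map exists). Each DSB picks two chromatids of two distinct
  homologs (aneuploid extras pair randomly per event) and resolves as CO
  with probability `p_crossover` (default 0.5) or NCO; conversion tracts
  are geometric with 2 kbp means (gene conversions are generally < 2 kbp).
  Conversion *copies* donor over recipient — the non-Mendelian, 3:1-style
  outcome — so allele counts across the chromatid pool are conserved only
  outside conversion tracts; CO exchange downstream of the tract is a swap
  and conserves counts everywhere. `n_dsb_per_Mb` defaults to 3.0, a free
  parameter (no published DSB count exists for these strains) chosen once
  to put simulated per-clone genome-recombined fractions in the ~10% range
  the study setting implies.
* **Segregation.** One random sister per homolog to each cell; with
  probability `p_missegregation` one homolog of one chromosome segregates
  2:0. Raw mother+daughter allele counts remain conserved under
  missegregation (both sisters exist, in one cell); the equality that
  breaks — only on that chromosome — is in dosages expressed at nominal
  ploidy, i.e. in AF space, which is what the caller and the depth track
  see.
* **Observations.** Per-marker depth is Poisson (negative binomial
  optional), Alt reads binomial at the true allele fraction folded with a
  per-read error rate (default 0.002), dropout optional. A record enters
  the emitted VCF 4.2 (GT:AD:DP, unphased polyploid GT) when at least one
  Alt read was seen; the GT field carries the simulated genotype at nominal
  ploidy while AD/DP carry the noisy depths — the pipeline's genotype
  evidence is AD, and no genotype-estimation model is imposed on the
  simulated caller. Depth tracks are per-window Poisson with expectation
  mean_depth × (local chromatid count)/(base ploidy); planted CNVs adjust
  the local count. All randomness flows from one seed; identical seeds
  give byte-identical files.

What the simulator does **not** model: read-level artifacts (mapping bias,
the "smiley" positional coverage pattern, repeat-driven miscalls),
GC-dependent coverage, linked errors across nearby markers, variant-caller
idiosyncrasies, and selection on colony phenotype. Passing recovery
studies therefore demonstrate correctness of the inference given the
dosage/AF model, not robustness to alignment artifacts — on real data the
positional filters carry that weight.

## Validation studies and problem sizes

The test suite regenerates everything programmatically: run-length and
interval arithmetic against brute-force/bitmap oracles (1000 random vectors
up to 10⁴ markers; 100 random interval cases up to 1 Mb), chromatid
conservation over 100 seeded simulations, marker-level recovery on 3n and
4n genomes of 2 × 1 Mb at 3.4 markers/kbp, 50× depth, error 0.002 over 20
seeds (pooled sensitivity/precision ≥ 0.95 required; measured ≈ 0.99/0.999
for 3n and 0.987/0.999 for 4n, per-seed percent-shifted within one point of
truth), noise-free reciprocity/phasing (agreement and cross-pair
concordance exactly 1.0), filter boundary cases, CNV/aneuploidy recovery,
and the rank-sum test (exact 1/252; Monte-Carlo type-I error at α = 0.05
over 10⁴ i.i.d.-null trials within ±0.01). `scripts/acceptance.py` re-runs
the same studies at 12 seeds per ploidy and scales the genome-wide marker
count check to the full 16-chromosome genome.

## Known limitations

* Breakpoints are resolved to the marker grid; sub-marker refinement and
  CO/NCO typing from a single sample are out of scope.
* Tetraploid phasing rests on the dosage algebra alone and leaves the
  remaining-haplotype multiset unordered.
* Recurrence filtering is rule-based (no statistical model of hotspot
  sharing); per-sample single-region coverage is used for the > 80%
  criterion rather than a union across regions.
* The coverage module does no GC correction, HMM/CBS segmentation or
  mappability masking.
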