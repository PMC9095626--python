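# rtgpoly

Loss-of-heterozygosity (LOH) mapping and recombination simulation for
polyploid *Saccharomyces cerevisiae* evolved by return-to-growth (RTG).

Many industrial yeasts are sterile triploid/tetraploid hybrids that cannot
be improved by breeding. RTG sidesteps sterility: cells enter meiosis,
Spo11-induced recombination takes place during prophase, and the cells
return to mitotic growth before committing to sporulation. The mother and
daughter of the first division inherit complementary recombinant
chromatids, visible in short-read sequencing as *reciprocal allele-frequency
(AF) shifts* across the hybrid's dense heterozygous markers. `rtgpoly` is
the analysis side of that experiment, for genomicists working with
polyploid evolved clones:

* **Marker catalogue** — reliable heterozygous SNPs from a parental VCF
  (QUAL > 20, DP > 10, het at the contig's ploidy), sample VCFs joined by
  exact (chrom, pos, ref, alt); 50 kbp window scan for pre-existing LOH
  (≤ 10 het markers per window).
* **AF-shift calling** — per-marker dosage inference: with parental Alt
  dosage k of ploidy p and observed AF a, k' = round(p·a) (ties toward k);
  a marker is shifted when depth ≥ 10, k' ≠ k and |a − k/p| ≥ 0.4/p. Runs
  of ≥ 9 consecutive shifted markers, any mix of directions, become
  AF-shift regions; the recombined genome fraction is the percentage of
  markers inside retained regions.
* **Artifact filters** — recurrence across a cohort (> 80% of a region's
  length in ≥ 70% of samples ⇒ pre-meiotic), overlap with unsporulated T0
  controls (≥ 90%), subtelomeres / parental CNVs / engineered loci.
* **Coverage** — 10 kbp (and 1 kbp small-scale) windowed depth normalized
  by chromosome median for CNV calls; genome-median log2 profiles for
  whole-chromosome aneuploidy flags.
* **Mother–daughter analysis** — reciprocity classification (crossover vs
  gene-conversion candidates), Jaccard distances between recombination
  landscapes, and local haplotype phasing: at each shifted marker the
  gained allele identifies the donor haplotype, its complement the
  recipient, and the allele-dosage identity (sum over haplotypes = k)
  solves the remaining haplotype(s).
* **URA3-loss assay** — LOH rate = 100 × CFU(5-FOA)/CFU(YPD) with explicit
  dilution correction, fold increase and absolute difference vs T0, and an
  exact one-sided Wilcoxon rank-sum test.
* **Simulator** — a truth-tracking generator of the entire process
  (ancestry-mosaic polyploid parent, DSB → CO/NCO resolution, chromatid
  segregation, optional 2:0 missegregation, binomial read sampling) that
  emits the same VCF/TSV formats the pipeline consumes. Every detection
  component is validated against it.

See `docs/methods.md` for the model, parameter defaults and the simulator's
scope.

## Worked example

Simulate a triploid M-D pair at 50× and run detection (library API; the
same flow is available as `rtgpoly simulate / markers / call / mdpair`
shell commands):

```python
from rtgpoly.simulate import (GenomeSpec, NoiseModel, simulate_parent,
                              simulate_rtg, emit_observations)
from rtgpoly import afshift, mdpairs

spec = GenomeSpec(chrom_lengths=(600_000, 400_000), ploidy=(3, 3),
                  marker_density=3.4, seed=7)
parent = simulate_parent(spec)
mother, daughter, truth = simulate_rtg(parent, n_dsb_per_Mb=4.0, seed=7)
noise = NoiseModel(mean_depth=50, error_rate=0.002)

calls = {}
for cell, s in ((mother, 1), (daughter, 2)):
    table = emit_observations(cell, noise, seed=s)
    calls[cell.name] = afshift.classify_sample(table)

regions = {name: afshift.call_regions(c) for name, c in calls.items()}
catalog = parent.marker_frame()
for name in ("mother", "daughter"):
    pct = afshift.percent_shifted_markers(regions[name], catalog)
    print(f"{name}: {len(regions[name])} AF-shift regions, "
          f"{pct:.2f}% of markers recombined")

pair = mdpairs.MDPair("mother", "daughter", calls["mother"], calls["daughter"],
                      regions["mother"], regions["daughter"])
rec = mdpairs.classify_reciprocity(pair)
print(rec["call"].value_counts().to_string())
print(f"mean direction agreement in matched regions: "
      f"{rec.loc[rec['cells'] == 'both', 'agreement'].mean():.3f}")
```

Output:

```
mother: 2 AF-shift regions, 28.50% of markers recombined
daughter: 3 AF-shift regions, 29.00% of markers recombined
call
reciprocal        2
non_reciprocal    1
mean direction agreement in matched regions: 1.000
```

This simulated pair recombined ~28–29% of its markers; two regions are
shared between mother and daughter with perfectly opposite per-marker
directions (crossovers whose recombinant chromatids split between the
cells), and one region is private to the daughter (a gene-conversion
candidate). The percentage excludes any configured chromosomes and
subtelomeric margins from both numerator and denominator.

For file-based work, `rtgpoly run --config study.yaml` executes the whole
workflow (catalogue → join → call → filter → CNV/aneuploidy → summaries →
declared M-D pairs) and writes deterministic TSV/BED outputs plus a
manifest with input checksums; `rtgpoly validate --config study.yaml`
checks a config without running.

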