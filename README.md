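# zwmap

Linkage-based analysis of young ZW sex chromosomes in octoploid
pseudo-testcross F1 designs: phase-resolved recombination-event counting,
segment-wise recombination-rate heterogeneity tests, fine-mapping of a
sex-determining region (SDR) from recombinant breakpoints, and W-specific
divergence / sex-association statistics — together with a synthetic cross
generator so every stage is testable without access to the original
plants.

The package is written for geneticists mapping sex determination in
outbred, polyploid species (the motivating system is a dioecious
allo-octoploid strawberry: 2n = 8x = 56, seven homeologous groups × four
diploidized subgenomes × two parents = 56 linkage groups, with a small
female-heterogametic SDR at the distal end of one maternal group).

## The model

**Pseudo-testcross.** Markers heterozygous in exactly one parent segregate
1:1 in the F1, so each offspring's het/hom call identifies the inherited
parental haplotype up to marker *phase* — whether the alternative allele is
in *coupling* (same haplotype) or *repulsion* with an anchor. On the sex
group the anchor is the W: a marker is in coupling when its heterozygous
calls travel with male sterility / female fertility.

**Count-based maps.** Map distance is d(cM) = 100 · (recombination
events) / n, and a segment's rate is

    rate (cM/Mb) = 100 · (events / n) / length(Mb)

Events are phase switches along the reference marker order after excluding
*singletons* — a lone marker of deviant phase flanked by the opposite phase
on both sides, attributed to genotyping error rather than a double
crossover.

**Two-point linkage.** For a testcross pair with R recombinants among n
informative offspring, r̂ = R/n and

    LOD = (n − R)·log10(2(1 − r̂)) + R·log10(2 r̂)

with LOD = n·log10 2 at r̂ = 0. Binary male function is scanned as a trait
pseudo-marker with this statistic; quantitative female fertility by
single-marker regression, LOD = (n/2)·log10(RSS0/RSS1).

**SDR bounding.** The male-function region is bounded by the closest
recombination events upstream and downstream whose recombinant genotypes
mismatch male function; mismatching but non-recombinant offspring are
reported and do not move bounds. The female-function region is the
contiguous run of sites whose genotype–fertility correlation is not
significantly different from the best site's, by Williams' t for
overlapping dependent correlations (df = n − 3).

**Divergence and association.** Within a cross, W-specific divergence is
the density of coupling-phase SNPs over the sequenced footprint; W vs Z SNP
counts are tested against 1:3 haplotype shares by Pearson χ² (no continuity
correction anywhere — required for count-based arithmetic to match). In
unrelated panels, sites are ranked by concordance = (het among ZW + hom
among ZZ) / total.

## Worked example

`python examples/fine_map_sdr.py` simulates a 1,200-offspring amplicon
panel, phases the maternal SDR-vicinity markers against male function and
bounds the SDR from mismatch-causing recombinants:

```
male-function region: 37.471-37.696 Mb (225 kb)
true causal locus:    37.594 Mb
non-recombinant mismatches: 10
female-function region: 37.571-37.653 Mb (peak LOD 183.1)
```

The breakpoint-bounded interval (a few hundred kb, shrinking with panel
size) contains the simulated causal locus; the ~1% of offspring whose
phenotype mismatches their genotype are non-recombinant and leave the
bounds untouched. `python examples/association_screen.py` screens a
22-plant unrelated panel:

```
               n_het_in_ZW  n_ZW  n_hom_in_ZZ  n_ZZ  concordance
site_id
Fvb6_37594072            8    10           12    12        0.909
Fvb6_37567962            8    10           10    12        0.818
...
top-ranked site: Fvb6_37594072 (concordance 0.909)
```

The sex-associated site tops the ranking; flanking sites from the same W
haplotype block rank lower because their alleles also segregate on Z
haplotypes.

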