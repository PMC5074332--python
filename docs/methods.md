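# Methods

## Scope and data model

zwmap analyses F1 pseudo-testcross families from outbred, fully
diploidized allopolyploid parents. Genotypes are per-marker het/hom/missing
calls (`H`/`A`/`.`), each marker heterozygous in exactly one parent and
anchored to a diploid reference coordinate (Fvb-style chromosome + bp).
Marker order within a linkage group is taken from the reference, never
re-estimated: multipoint ordering is out of scope, and order
inconsistencies are instead *flagged* as candidate rearrangements when
swapping an adjacent pair would remove apparent double recombinants in at
least two offspring. Coordinates are 1-based closed intervals in memory;
interval widths are end − start; BED output converts to 0-based half-open
on write only.

## Phasing and event counting

Markers on the sex group are phased against male function (sterile =
W-carrier) by majority concordance; exact 50:50 splits are left unphased
and excluded downstream. Autosomal groups are phased by chaining adjacent
markers (majority co-inheritance with the nearest previously phased
neighbour), which stays reliable because adjacent-marker recombination
fractions are small even where marker–anchor fractions approach 0.5.

Recombination events are phase switches along the bp order, skipping
missing calls. Two error filters operationalize the exclusion of events
attributable to genotyping error:

- **Interior singletons** (always on): a single deviant marker flanked by
  the opposite phase on both sides is excluded; runs of ≥2 deviant markers
  count as two genuine events. The run-length threshold is fixed at 1
  deviant marker; at a 0.5% per-call error rate interior errors are ~200×
  more likely than the double crossovers they mimic within one marker
  spacing.
- **Terminal runs** (`min_terminal_run`, default 1 = off): a deviant run of
  fewer than `min_terminal_run` markers at a group end has only one flank
  and is equally attributable to error. Rate estimation uses
  `min_terminal_run = 2`, which censors the outermost marker gap at each
  end; the detectable span then runs from the second to the
  second-to-last marker, and all expectations in the package's own
  analyses use that span. Events beyond the first/last informative marker
  are undetectable regardless (documented censoring).

Map length per group is 100 × retained events / n (count-based cM); no
mapping function (Kosambi/Haldane) is applied anywhere, matching the
count-based definition of the rate.

## Rates and heterogeneity tests

Linkage groups are tiled greedily into 10 Mb segments from the group
start, restarting after each flagged rearrangement; a remainder piece is
kept as a single segment if ≥5 Mb, else dropped. Rates are
100·(events/n)/Mb. All χ² statistics are Pearson sums without continuity
correction — with the Yates correction the 2×2 event-count comparison at
small counts is visibly deflated (≈3.9 instead of 4.7 on the motivating
counts) and no longer matches count arithmetic; a flag can re-enable it.
Goodness-of-fit expectations must be strictly positive and total to the
observed sum within 5% (rounding slack for printed inputs). The
maternal-vs-paternal rate comparison is a two-sided Wilcoxon rank-sum:
exact enumeration when both samples have n ≤ 10 without ties, otherwise
the normal approximation with tie correction and no continuity correction.

## SDR mapping

Binary male function is scanned with the two-point testcross LOD (the
trait as a pseudo-marker), not logistic regression: it reproduces the
count-based linkage evidence exactly and is the natural statistic for a
1:1 locus. Peak ties break toward the smaller bp. The quantitative scan
uses LOD = (n/2)·log10(RSS0/RSS1) per marker, +∞ for perfect fits; a
two-QTL additive model is "supported" only when the best eligible pair
(different groups, or ≥10 Mb apart) beats the best single-marker LOD by ≥3.

**Breakpoint bounding.** Each informative recombinant constrains the
causal locus: if its phenotype matches the distal side of the breakpoint
the locus lies downstream of its last mismatching marker, and symmetric
upstream. Bounds are reported at marker positions, not interpolated.
Because a phenotype-scoring error on a recombinant produces a constraint
on the wrong side — possibly crossing all others — the region is placed
where the maximum number of constraints is satisfied, and the conflicting
minority is reported in the evidence rather than obeyed; with no conflict
this reduces to max(lower candidates), min(upper candidates). Mismatching
non-recombinant offspring never move bounds. An unbounded side falls back
to the marker span end and is flagged.

**Female-function region.** The dependent-correlation comparison uses
Williams' (1959) t for overlapping correlations sharing the trait,

t = (r1 − r2)·sqrt[(n−1)(1+r12) / (2((n−1)/(n−3))|R| + r̄²(1−r12)³)],
|R| = 1 − r1² − r2² − r12² + 2 r1 r2 r12, df = n − 3, two-sided,

computed on complete cases across the peak site, the tested site and the
trait; the region is the maximal contiguous bp run containing the peak
with p ≥ α (default 0.05). Williams' t was chosen over Steiger's z as the
standard small-sample option for this comparison; the choice is exposed at
the function level. A caveat the tests document: at large n the test
resolves correlation differences of the size produced by 0.5% genotyping
error, so with noisy genotypes the region can be narrower than the true
equivalence class — the simulation check of locus coverage therefore uses
error-free genotypes.

## Divergence and association

Maternal-het sites are W/Z-classified directly from phase. Paternal-het
sites are split between the father's two Z haplotypes by cosegregation
with the first paternal site: agreement >0.9 joins its cluster, <0.1 the
mirror cluster, anything between is left unknown (the two haplotypes
mirror each other exactly, so signed agreement is the discriminant).
Divergence denominators are explicit callable-footprint sizes supplied by
the caller — the sequenced amplicon footprint is not recoverable from
genotype tables — and Z density divides additionally by the number of
assayable Z haplotypes (3 in a ZW × ZZ cross). The high-divergence window
is a sliding-window maximum of W-SNP counts (150 kb window, 10 kb step by
default) trimmed to the outermost W SNPs inside the best window; a
single-SNP window is returned degenerate and flagged. Panel association is
plain concordance with ties broken toward the smaller coordinate.

## The synthetic cross generator

The generator is first-class, tested code; its defaults are the study
conditions every acceptance-style check runs under.

- **Genome**: 7 homeologs × 4 subgenomes × 2 parents = 56 groups;
  approximate diploid-reference lengths with the sex homeolog at
  38.873 Mb. Subgenomes are fully diploidized (disomic inheritance); no
  polysomic segregation.
- **Meiosis**: crossovers are a Poisson process with intensity
  rate/100 per Mb from a piecewise-constant rate map — no interference,
  consistent with count-based cM. Defaults: genome 2.5 cM/Mb; the maternal
  sex group 3.3 with a 330 kb SDR-centred window at 1.5; its paternal
  homologue 1.7 with the window at 4.1.
- **SDR**: interval 37.428–37.708 Mb on VI-Av-m; the causal locus is a
  point at the sex-associated marker position (37,594,072 bp), the best
  available estimate of the determinant's location, and W-carrier status is
  the inherited maternal haplotype there. Breakpoint-containment checks
  therefore test coverage of this locus, not of the full configured
  interval — a breakpoint landing between an interval edge and the locus
  legitimately narrows the mapped region past that edge.
- **Panels**: 42 offspring genotyped genome-wide ("capture", ~1.2
  markers/Mb ≈ 2,500 markers) and the remainder of 1,275 offspring
  genotyped only at SDR-vicinity amplicon sites (18 coupling — 10 of them
  in the 143 kb high-divergence window — 18 repulsion, and 9 + 15 paternal
  sites on the two Z haplotypes).
- **Phenotypes**: male sterility = W-carrier XOR a 1% mismatch
  (misscoring / rare modifiers); 693 offspring scored for male function and
  619 for female fertility by default. Female fertility is
  fruits/pollinated flowers with flower counts ≥1 Poisson(15.5) and latent
  fruit-set Beta(3, 1) (mean 0.75) for W carriers vs Beta(0.45, 4.05)
  (mean 0.10) for ZZ — the ZZ shape calibrated once so ~25% of offspring
  fall below the 5% female-sterile cutoff, the observed bimodal pattern.
  Within-class variances are not identifiable from the source material;
  the component shapes are config.
- **Noise**: genotype calls flip H↔A at 0.5% and go missing at 5% per
  call, both config. One `numpy` Generator seeded once drives all
  randomness; identical seeds give byte-identical output files.
- **Unrelated panels**: each plant's focal-site genotype reflects its sex
  at the stated concordance (defaults 9/10 het among ZW, 11/12 hom among
  ZZ). Flanking sites are *nested* LD-degraded copies of the focal call —
  retention of the focal het decays slowly with distance in ZW plants
  (decay 200 kb: the W block travels as a unit) while extra heterozygous
  calls accrue with distance in ZZ plants (decay 25 kb: flank alleles also
  segregate on Z haplotypes). The constants were calibrated once so flank
  marginals sit at the centres of the observed ranges (~83% het among
  steriles, ~63% hom among fertiles). Under this structure a flank can tie
  but never exceed the focal site's concordance; exact ties are the sole
  way the focal site loses rank 1, at a few percent per panel. Independent
  per-site draws would be both unrealistic and unable to reproduce the
  per-sex flank associations.

What the generator does **not** emulate: read-level data and
coverage-dependent genotype quality, segregation distortion, population
structure in panels, real LD beyond the single nested block, selfing, and
polysomic inheritance. Passing recovery tests therefore demonstrate the
pipeline's correctness under the stated inheritance and noise model, not
robustness to artifacts outside it.

## Numerical and reporting choices

- Rates and χ² are reported to 1 decimal, concordance R² to 2, matching
  report-table precision; comparisons at printed precision use
  round-half-away-from-zero.
- LOD at r̂ = 0 uses the exact limit n·log10 2; r̂ = 1 (complete repulsion)
  relabels to the same evidence. Perfect regression fits return +∞ by a
  relative 1e-12 RSS tolerance.
- Phase-confidence ties (exactly 50:50) exclude the marker rather than
  guess; ambiguous phenotype records are excluded listwise per analysis.
- Problem sizes in the test battery: rate recovery uses one 42-offspring
  genome-wide cross plus one 1,215-offspring amplicon panel; SDR
  containment and the panel screen use 100 replicates each at 1,200
  offspring / 22 plants, matching the study's sample sizes while keeping
  the default suite in the minutes range.

## Known limitations

- Bounding resolution is limited to marker positions; no interpolation or
  interval-mapping EM between markers.
- The Williams-test region is sensitive to genotyping error at large n
  (see above); a bootstrap alternative is cross-checked in tests but not
  exposed.
- `expected_events` takes the genome fraction as an input; it does not
  re-derive chromosome-share fractions from marker tables.
- The terminal-run error filter trades the outermost marker gap's real
  events for robustness; analyses must use the matching detectable span,
  as the package's own analyses do.
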