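"""Screen an unrelated panel for sex-associated sites.

Simulates a small panel of wild-collected plants (10 male-sterile ZW, 12
male-fertile ZZ) genotyped at SDR-vicinity sites, then ranks sites by
genotype-sex concordance: het in ZW plants, hom in ZZ plants.
"""

import zwmap as z

genotypes, sexes, positions = z.simulate_unrelated_panel(
    n_females=10, n_males=12, seed=4
)
ranked = z.sex_association_screen(genotypes, sexes, positions)

print(ranked[["n_het_in_ZW", "n_ZW", "n_hom_in_ZZ", "n_ZZ", "concordance"]]
      .head(6).round(3).to_string())
top = ranked.index[0]
print(f"\ntop-ranked site: {top} "
      f"(concordance {ranked.loc[top, 'concordance']:.3f})")

# A site het in 9/10 ZW plants and hom in 11/12 ZZ plants scores 20/22 =
# 0.909; flanking sites in the same haplotype block rank below it because
# their alleles also segregate on some Z haplotypes.
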