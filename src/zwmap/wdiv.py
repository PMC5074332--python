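"""W/Z haplotype classification of SNPs, W-specific divergence, the W-vs-Z
SNP density test, high-divergence window location, and the unrelated-panel
sex-association screen.

Within a cross, a maternally heterozygous SNP in coupling with male
sterility / female fertility sits on the W haplotype; one in repulsion sits
on the maternal Z.  Paternally heterozygous SNPs segregate on one of the
father's two Z haplotypes, recovered by cosegregation clustering.
W-specific divergence is the density of W-coupled SNPs over the callable
(sequenced) footprint; the Z comparison divides by the number of assayable
Z haplotypes (three in a ZW x ZZ cross: one maternal, two paternal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HET, HOM, MISSING
from .phase import COUPLING, REPULSION
from .rates import CountTest, chisq_gof
from .sdr import RegionCall

W_COUPLING = "W_coupling"
Z_REPULSION = "Z_repulsion"
PATERNAL_Z1 = "paternal_Z1"
PATERNAL_Z2 = "paternal_Z2"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class DivergenceEstimate:
    """SNP density of the W and Z haplotypes over a callable footprint."""

    start_bp: int
    end_bp: int
    n_w_snps: int
    n_z_snps: int
    callable_bp: int
    n_z_haplotypes: int

    @property
    def w_divergence(self) -> float:
        return self.n_w_snps / self.callable_bp

    @property
    def z_divergence(self) -> float:
        return self.n_z_snps / (self.callable_bp * self.n_z_haplotypes)


def classify_snps(
    genotypes: pd.DataFrame,
    markers: pd.DataFrame,
    phase: pd.DataFrame | pd.Series,
    cluster_agreement: float = 0.9,
) -> pd.Series:
    """Assign each segregating site to a sex-chromosome haplotype class.

    Maternal-het sites become W_coupling / Z_repulsion from their phase
    relative to male sterility (unphased sites are 'unknown' and excluded
    from divergence).  Paternal-het sites are greedily clustered into the
    father's two Z haplotypes by cosegregation: a site joins the first
    cluster whose seed it matches (or mirrors) in > ``cluster_agreement``
    of doubly informative offspring.
    """
    if isinstance(phase, pd.DataFrame):
        phase = phase["phase"]
    out: dict[str, str] = {}
    maternal = [m for m in genotypes.columns if markers.loc[m, "seg_parent"] == "m"]
    paternal = [m for m in genotypes.columns if markers.loc[m, "seg_parent"] == "p"]
    for m in maternal:
        ph = phase.get(m)
        if ph == COUPLING:
            out[m] = W_COUPLING
        elif ph == REPULSION:
            out[m] = Z_REPULSION
        else:
            out[m] = UNKNOWN

    # the father's two Z haplotypes mirror each other at every site, so
    # cosegregation with the first paternal site splits them: high agreement
    # -> same haplotype, high disagreement -> the other one
    reference: str | None = None
    for m in sorted(paternal, key=lambda s: markers.loc[s, "ref_pos_bp"]):
        if reference is None:
            reference = m
            out[m] = PATERNAL_Z1
            continue
        a, b = genotypes[m], genotypes[reference]
        ok = (a != MISSING) & (b != MISSING)
        n = int(ok.sum())
        if n == 0:
            out[m] = UNKNOWN
            continue
        match = float(((a[ok] == HET) == (b[ok] == HET)).mean())
        if match > cluster_agreement:
            out[m] = PATERNAL_Z1
        elif match < 1 - cluster_agreement:
            out[m] = PATERNAL_Z2
        else:
            out[m] = UNKNOWN
    return pd.Series(out, name="snp_class").reindex(genotypes.columns)


def class_counts(classes: pd.Series) -> pd.Series:
    """Tally of sites per haplotype class (conserved: sums to n sites)."""
    return classes.value_counts().reindex(
        [W_COUPLING, Z_REPULSION, PATERNAL_Z1, PATERNAL_Z2, UNKNOWN], fill_value=0
    )


def w_divergence(
    classes: pd.Series,
    positions: pd.Series,
    window: tuple[int, int],
    callable_bp: int,
    n_z_haplotypes: int = 3,
) -> DivergenceEstimate:
    """W-SNP and Z-SNP density within a window over a callable footprint.

    ``callable_bp`` is the sequenced amplicon footprint inside the window,
    supplied as an explicit mask size; Z density is per assayable Z
    haplotype.
    """
    if callable_bp <= 0:
        raise ValueError("callable_bp must be positive")
    lo, hi = window
    inside = positions.reindex(classes.index).between(lo, hi)
    n_w = int(((classes == W_COUPLING) & inside).sum())
    n_z = int((classes.isin([Z_REPULSION, PATERNAL_Z1, PATERNAL_Z2]) & inside).sum())
    return DivergenceEstimate(lo, hi, n_w, n_z, callable_bp, n_z_haplotypes)


def w_vs_z_test(
    n_w: int, n_z: int, n_w_haplotypes: int = 1, n_z_haplotypes: int = 3
) -> CountTest:
    """Chi-square of observed W:Z SNP counts against haplotype-share
    expectations (equal per-haplotype SNP probability)."""
    total = n_w + n_z
    shares = np.array([n_w_haplotypes, n_z_haplotypes], dtype=float)
    expected = total * shares / shares.sum()
    return chisq_gof([n_w, n_z], expected)


def high_divergence_window(
    classes: pd.Series,
    positions: pd.Series,
    window_bp: int = 150_000,
    step_bp: int = 10_000,
    group_id: str = "",
) -> RegionCall:
    """Locate the window of maximal W-SNP density by sliding-window scan.

    Scans windows of ``window_bp`` advanced by ``step_bp`` across the span
    of classified sites, then trims the best window (ties: smallest start)
    to the outermost W-coupled SNPs inside it.  A single W SNP yields a
    degenerate zero-width window, flagged in the evidence.
    """
    pos = positions.reindex(classes.index)
    w_pos = np.sort(pos[classes == W_COUPLING].to_numpy(dtype=float))
    if len(w_pos) == 0:
        raise ValueError("no W-coupled SNPs to scan")
    lo, hi = float(pos.min()), float(pos.max())
    best_count, best_start = -1, lo
    start = lo
    while True:
        count = int(((w_pos >= start) & (w_pos <= start + window_bp)).sum())
        if count > best_count:
            best_count, best_start = count, start
        if start + window_bp >= hi:
            break
        start += step_bp
    inside = w_pos[(w_pos >= best_start) & (w_pos <= best_start + window_bp)]
    return RegionCall(
        "high_divergence",
        group_id,
        int(inside.min()),
        int(inside.max()),
        evidence={"n_w_snps": int(len(inside)), "degenerate": bool(len(inside) < 2)},
    )


# ---------------------------------------------------------------------------
# unrelated-panel association


def sex_association_screen(
    genotypes: pd.DataFrame,
    sexes: pd.Series,
    positions: pd.Series | None = None,
) -> pd.DataFrame:
    """Rank panel sites by genotype-sex concordance.

    ``sexes`` codes male-sterile (ZW, female) plants as ``S`` (or True)
    and male-fertile (ZZ) as ``F``/False.  Concordance at a site is
    (het among ZW + hom among ZZ) / (informative ZW + informative ZZ);
    sites are ranked by concordance, ties broken by ascending bp.
    """
    s = sexes.reindex(genotypes.index)
    if s.dtype != bool:
        s = s.map({"S": True, "F": False})
    if s.dropna().nunique() < 2:
        raise ValueError("panel must contain both sexes")
    zw = (s == True).to_numpy()  # noqa: E712 - NaN-safe elementwise compare
    zz = (s == False).to_numpy()  # noqa: E712
    arr = genotypes.to_numpy()
    het = arr == HET
    hom = arr == HOM
    inf = het | hom
    n_zw = (inf & zw[:, None]).sum(axis=0)
    n_zz = (inf & zz[:, None]).sum(axis=0)
    het_zw = (het & zw[:, None]).sum(axis=0)
    hom_zz = (hom & zz[:, None]).sum(axis=0)
    with np.errstate(invalid="ignore"):
        conc = (het_zw + hom_zz) / (n_zw + n_zz)
    out = pd.DataFrame(
        {
            "n_het_in_ZW": het_zw,
            "n_ZW": n_zw,
            "n_hom_in_ZZ": hom_zz,
            "n_ZZ": n_zz,
            "concordance": conc,
        },
        index=genotypes.columns.rename("site_id"),
    )
    if positions is not None:
        out["ref_pos_bp"] = positions.reindex(out.index)
        out = out.sort_values(["concordance", "ref_pos_bp"], ascending=[False, True])
    else:
        out = out.sort_values("concordance", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
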