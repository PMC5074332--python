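"""Sex-determining-region mapping: QTL scans for binary male function and
quantitative female fertility, recombinant-breakpoint bounding of the
male-function region, and dependent-correlation bounding of the
female-function region.

The binary trait is scanned with the testcross two-point LOD (the trait is
treated as a pseudo-marker), which is the natural statistic for a
1:1-segregating ZW locus.  The quantitative trait is scanned by
single-marker regression, LOD = (n/2) log10(RSS0/RSS1).  The
female-function region is the contiguous run of sites whose correlation
with fertility is not significantly different (Williams' t for overlapping
dependent correlations) from the best site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import HET, MISSING
from .phase import count_events, twopoint


@dataclass(frozen=True)
class ScanResult:
    """Per-marker LOD profile with its peak."""

    lod: pd.Series
    peak_marker: str
    peak_lod: float
    peak_r2: float
    peak_mismatches: int | None = None


@dataclass
class RegionCall:
    """A 1-based closed genomic interval call with its bounding evidence."""

    region_type: str  # male_function / female_function / high_divergence
    group_id: str
    start_bp: int
    end_bp: int
    bounded_lower: bool = True
    bounded_upper: bool = True
    evidence: dict = field(default_factory=dict)

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp


def _peak(lod: pd.Series, positions: pd.Series) -> str:
    """Argmax marker; ties broken toward the smallest bp position."""
    best = lod.max()
    tied = lod.index[lod == best]
    return positions.loc[tied].idxmin()


# ---------------------------------------------------------------------------
# scans


def scan_binary(
    genotypes: pd.DataFrame,
    male_function: pd.Series,
    positions: pd.Series | None = None,
) -> ScanResult:
    """Two-point testcross LOD of each marker against binary male function.

    ``male_function`` holds F/S/. codes (or booleans, True = sterile =
    W-carrier); offspring with unknown phenotype are dropped per marker.
    """
    trait = _sterile_indicator(male_function.reindex(genotypes.index))
    if pd.Series(trait).dropna().nunique() < 2:
        raise ValueError("male function is monomorphic")
    if positions is None:
        positions = pd.Series(range(len(genotypes.columns)), index=genotypes.columns)
    lods, mism = {}, {}
    for m in genotypes.columns:
        g = genotypes[m].map({HET: 1.0, MISSING: np.nan}).fillna(0.0)
        g[genotypes[m] == MISSING] = np.nan
        tp = twopoint(g.to_numpy(), trait)
        lods[m] = tp.lod
        mism[m] = tp.R
    lod = pd.Series(lods, name="lod")
    peak = _peak(lod, positions)
    # phi^2 of the genotype x phenotype 2x2 table at the peak
    g = genotypes[peak]
    ok = (g != MISSING) & ~np.isnan(trait)
    table = pd.crosstab(g[ok] == HET, trait[ok] == 1.0).reindex(
        index=[False, True], columns=[False, True], fill_value=0
    )
    return ScanResult(lod, peak, float(lod[peak]), concordance_r2(table.to_numpy()), mism[peak])


def _sterile_indicator(male_function: pd.Series) -> np.ndarray:
    """Sterile (= W-carrier) as 1.0 / 0.0 / NaN from F/S/. codes or booleans."""
    values = set(male_function.dropna().unique())
    if values <= {"S", "F", "."}:
        return male_function.map({"S": 1.0, "F": 0.0}).to_numpy(dtype=float)
    return male_function.astype(float).to_numpy()


def scan_quant(
    genotypes: pd.DataFrame,
    trait: pd.Series,
    positions: pd.Series | None = None,
    min_lod: float = 3.0,
) -> tuple[ScanResult, pd.Index]:
    """Single-marker regression LOD scan of a quantitative trait.

    LOD = (n/2) log10(RSS0/RSS1) per marker (het = 1, hom = 0); a perfect
    fit (RSS1 = 0) is reported as +inf.  Returns the scan plus the index
    of markers reaching ``min_lod`` (candidate QTL).
    """
    y_all = trait.reindex(genotypes.index).astype(float)
    if y_all.dropna().nunique() < 2:
        raise ValueError("trait is constant")
    if positions is None:
        positions = pd.Series(range(len(genotypes.columns)), index=genotypes.columns)
    lods = {}
    for m in genotypes.columns:
        g = genotypes[m]
        ok = (g != MISSING) & y_all.notna()
        n = int(ok.sum())
        if n < 3:
            raise ValueError(f"marker {m}: need >=3 complete records")
        x = (g[ok] == HET).to_numpy(dtype=float)
        y = y_all[ok].to_numpy()
        lods[m] = _regression_lod(np.column_stack([x]), y)
    lod = pd.Series(lods, name="lod")
    peak = _peak(lod, positions)
    r = _pointbiserial(genotypes[peak], y_all)
    candidates = lod.index[lod >= min_lod]
    return ScanResult(lod, peak, float(lod[peak]), float(r * r)), candidates


def _regression_lod(x: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    rss0 = float(((y - y.mean()) ** 2).sum())
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss1 = float(((y - design @ beta) ** 2).sum())
    if rss1 <= 1e-12 * max(rss0, 1.0):  # perfect fit up to float error
        return float("inf")
    if rss0 == 0.0:
        return 0.0
    return (n / 2.0) * np.log10(rss0 / rss1)


def _pointbiserial(g: pd.Series, y: pd.Series) -> float:
    ok = (g != MISSING) & y.notna()
    x = (g[ok] == HET).to_numpy(dtype=float)
    yy = y[ok].to_numpy()
    if x.std() == 0 or yy.std() == 0:
        return 0.0
    return float(np.corrcoef(x, yy)[0, 1])


def two_qtl_additive(
    genotypes: pd.DataFrame,
    trait: pd.Series,
    best_single_lod: float,
    groups: pd.Series | None = None,
    positions: pd.Series | None = None,
    min_distance_bp: int = 10_000_000,
    delta_lod: float = 3.0,
) -> tuple[bool, tuple[str, str] | None, float]:
    """Exhaustive additive two-QTL search.

    Pairs on different linkage groups, or at least ``min_distance_bp``
    apart on the same group, are fitted with an additive two-predictor
    regression.  The two-QTL model is supported iff the best pair LOD
    reaches ``best_single_lod + delta_lod``.
    """
    y_all = trait.reindex(genotypes.index).astype(float)
    cols = list(genotypes.columns)
    het = (genotypes == HET).astype(float)
    het[genotypes == MISSING] = np.nan
    best_pair, best_lod = None, -np.inf
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if groups is not None and positions is not None:
                same = groups[a] == groups[b]
                if same and abs(positions[a] - positions[b]) < min_distance_bp:
                    continue
            xa, xb = het[a], het[b]
            ok = xa.notna() & xb.notna() & y_all.notna()
            if ok.sum() < 4:
                continue
            x = np.column_stack([xa[ok], xb[ok]])
            lod = _regression_lod(x, y_all[ok].to_numpy())
            if lod > best_lod:
                best_lod, best_pair = lod, (a, b)
    supported = bool(best_lod >= best_single_lod + delta_lod)
    return supported, best_pair, float(best_lod)


# ---------------------------------------------------------------------------
# breakpoint bounding of the male-function region


def male_function_region(
    haplotypes: pd.DataFrame,
    male_function: pd.Series,
    positions: pd.Series,
    group_id: str = "",
) -> RegionCall:
    """Bound the male-function region by mismatch-causing recombinants.

    ``haplotypes`` is the offspring x marker W-indicator matrix (1 = W
    haplotype inherited) in bp order.  Offspring phenotype predicts a
    W-indicator (sterile = 1) that should hold at the causal locus; for a
    recombinant offspring the markers disagreeing with the phenotype
    ("mismatches") lie on the far side of the breakpoint from the locus.
    The lower bound is the largest-bp upstream mismatching marker across
    recombinants whose mismatch run is a prefix; the upper bound is the
    smallest-bp downstream mismatching marker across recombinants whose
    mismatch run is a suffix.  Mismatching but non-recombinant offspring
    (phenotyping errors or rare modifiers) are reported in the evidence and
    do not move the bounds.  An unbounded side falls back to the marker
    span end and is flagged.
    """
    cols = [c for c in positions.sort_values().index if c in haplotypes.columns]
    hap = haplotypes[cols]
    trait = _sterile_indicator(male_function.reindex(hap.index))

    lower_cands: list[tuple[int, str, str]] = []
    upper_cands: list[tuple[int, str, str]] = []
    nonrec_mismatches: list[str] = []
    for oid, row in hap.iterrows():
        t = float(trait[hap.index.get_loc(oid)])
        if np.isnan(t):
            continue
        x = row.to_numpy(dtype=float)
        obs = ~np.isnan(x)
        if obs.sum() < 2:
            continue
        pc = count_events(x, cols, offspring_id=str(oid))
        mism_markers = [m for m, v in zip(pc.markers, pc.phases) if v != t and m not in pc.singletons]
        if not mism_markers:
            continue
        if pc.n_events == 0:
            nonrec_mismatches.append(str(oid))
            continue
        match_markers = [m for m, v in zip(pc.markers, pc.phases) if v == t and m not in pc.singletons]
        if not match_markers:
            nonrec_mismatches.append(str(oid))
            continue
        last_mism = max(positions[m] for m in mism_markers)
        first_mism = min(positions[m] for m in mism_markers)
        first_match = min(positions[m] for m in match_markers)
        last_match = max(positions[m] for m in match_markers)
        if last_mism < first_match:  # mismatch prefix -> locus downstream
            lower_cands.append((int(last_mism), str(oid), cols[0]))
        elif first_mism > last_match:  # mismatch suffix -> locus upstream
            upper_cands.append((int(first_mism), str(oid), cols[-1]))
        # interleaved mismatches (multiple breakpoints) contribute the
        # tightest consistent bounds on both sides
        else:
            up = [positions[m] for m in mism_markers if positions[m] < first_match]
            down = [positions[m] for m in mism_markers if positions[m] > last_match]
            if up:
                lower_cands.append((int(max(up)), str(oid), cols[0]))
            if down:
                upper_cands.append((int(min(down)), str(oid), cols[-1]))

    span_lo = int(positions[cols[0]])
    span_hi = int(positions[cols[-1]])
    # Each informative recombinant constrains the locus to lie above its
    # lower candidate or below its upper candidate.  A recombinant whose
    # phenotype is itself wrong (scoring error, rare modifier) produces a
    # contradictory constraint — possibly crossing the others — so the
    # region is placed where the largest number of constraints is
    # satisfied, and the conflicting minority is reported, not obeyed.
    lows = sorted(p for p, _, _ in lower_cands)
    ups = sorted(p for p, _, _ in upper_cands)
    cuts = sorted({*lows, *ups, span_lo - 1, span_hi + 1})
    best_x, best_sat = None, -1
    for a, b in zip(cuts, cuts[1:]):
        x = (a + b) / 2
        sat = sum(p < x for p in lows) + sum(q > x for q in ups)
        if sat > best_sat:
            best_sat, best_x = sat, x
    sat_lows = [p for p in lows if p < best_x]
    sat_ups = [q for q in ups if q > best_x]
    conflicts = sorted(
        {o for p, o, _ in lower_cands if p not in sat_lows}
        | {o for q, o, _ in upper_cands if q not in sat_ups}
    )
    bounded_lower = bool(sat_lows)
    bounded_upper = bool(sat_ups)
    start = max(sat_lows) if bounded_lower else span_lo
    end = min(sat_ups) if bounded_upper else span_hi
    return RegionCall(
        "male_function",
        group_id,
        start,
        end,
        bounded_lower,
        bounded_upper,
        evidence={
            "lower_recombinants": sorted({o for p, o, _ in lower_cands if p == start}),
            "upper_recombinants": sorted({o for p, o, _ in upper_cands if p == end}),
            "nonrecombinant_mismatches": sorted(set(nonrec_mismatches)),
            "conflicting_recombinants": conflicts,
        },
    )


# ---------------------------------------------------------------------------
# dependent-correlation bounding of the female-function region


def williams_t(r1: float, r2: float, r12: float, n: int) -> tuple[float, float]:
    """Williams' t for two overlapping dependent correlations.

    Tests H0: rho(X1, Y) = rho(X2, Y) when both correlations share Y and
    the predictors correlate r12, with

        t = (r1 - r2) * sqrt( (n-1)(1+r12) /
              ( 2 (n-1)/(n-3) |R| + rbar^2 (1-r12)^3 ) ),
        |R| = 1 - r1^2 - r2^2 - r12^2 + 2 r1 r2 r12,  rbar = (r1+r2)/2,

    on n-3 degrees of freedom, two-sided.
    """
    if n <= 3:
        raise ValueError("need n > 3 for Williams' t")
    for name, r in (("r1", r1), ("r2", r2), ("r12", r12)):
        if not -1 <= r <= 1:
            raise ValueError(f"{name} out of [-1, 1]")
    if r1 == r2:
        return 0.0, 1.0
    det = 1 - r1**2 - r2**2 - r12**2 + 2 * r1 * r2 * r12
    rbar = (r1 + r2) / 2
    denom = 2 * ((n - 1) / (n - 3)) * abs(det) + rbar**2 * (1 - r12) ** 3
    t = (r1 - r2) * np.sqrt((n - 1) * (1 + r12) / denom)
    p = 2 * float(stats.t.sf(abs(t), n - 3))
    return float(t), p


def female_function_region(
    genotypes: pd.DataFrame,
    female_fertility: pd.Series,
    positions: pd.Series,
    alpha: float = 0.05,
    group_id: str = "",
) -> tuple[RegionCall, pd.DataFrame]:
    """Bound the female-function region by dependent-correlation comparison.

    The peak site maximises the regression LOD; every other site's
    genotype-fertility correlation is compared with the peak's using
    Williams' t (complete cases across the peak site, the tested site and
    the trait).  The region is the maximal contiguous run of sites in bp
    order containing the peak whose comparison p-value is >= alpha.
    """
    y = female_fertility.reindex(genotypes.index).astype(float)
    n_complete = int(y.notna().sum())
    if n_complete <= 3:
        raise ValueError("need more than 3 complete records")
    cols = [c for c in positions.sort_values().index if c in genotypes.columns]
    scan, _ = scan_quant(genotypes[cols], y, positions[cols])
    peak = scan.peak_marker
    g_peak = genotypes[peak]

    rows = []
    for m in cols:
        g = genotypes[m]
        ok = (g != MISSING) & (g_peak != MISSING) & y.notna()
        n = int(ok.sum())
        if m == peak:
            rows.append((m, int(positions[m]), 0.0, 1.0, n))
            continue
        if n <= 3:
            rows.append((m, int(positions[m]), np.nan, np.nan, n))
            continue
        x1 = (g_peak[ok] == HET).to_numpy(dtype=float)
        x2 = (g[ok] == HET).to_numpy(dtype=float)
        yy = y[ok].to_numpy()
        r1 = _safe_corr(x1, yy)
        r2 = _safe_corr(x2, yy)
        r12 = _safe_corr(x1, x2)
        t, p = williams_t(abs(r1), abs(r2), abs(r12), n)
        rows.append((m, int(positions[m]), t, p, n))
    table = pd.DataFrame(
        rows, columns=["site_id", "ref_pos_bp", "t", "p", "n"]
    ).set_index("site_id")

    keep = (table["p"] >= alpha).reindex(cols).fillna(False).to_numpy()
    i_peak = cols.index(peak)
    lo = i_peak
    while lo > 0 and keep[lo - 1]:
        lo -= 1
    hi = i_peak
    while hi < len(cols) - 1 and keep[hi + 1]:
        hi += 1
    region = RegionCall(
        "female_function",
        group_id,
        int(positions[cols[lo]]),
        int(positions[cols[hi]]),
        bounded_lower=lo > 0,
        bounded_upper=hi < len(cols) - 1,
        evidence={"peak_site": peak, "peak_lod": scan.peak_lod},
    )
    return region, table


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def concordance_r2(table) -> float:
    """Squared phi coefficient of a 2x2 genotype x binary-phenotype table
    (equals the OLS R^2 between the two binary codings)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    a, b, c, d = t.ravel()
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    phi = (a * d - b * c) / np.sqrt(denom)
    return float(phi * phi)
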