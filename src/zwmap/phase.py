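"""Coupling/repulsion phasing, two-point linkage and recombination-event
counting for pseudo-testcross markers.

In a pseudo-testcross every informative marker is heterozygous in exactly
one parent, so an offspring's H/A call at a marker identifies which of the
two parental haplotypes it inherited there — up to the unknown *phase* of
the marker (whether the heterozygous parent's alternative allele sits on
haplotype 1 or haplotype 2).  On the sex linkage group the natural anchor
haplotype is the W, and a marker is *in coupling* when its heterozygous
calls travel with male sterility / female fertility.

Recombination events are counted as phase switches along the reference
(Fvb) marker order, after excluding single-marker switches flanked by the
opposite phase on both sides ("singletons"), which are overwhelmingly
genotyping errors rather than double crossovers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HET, HOM, MISSING

COUPLING = "coupling"
REPULSION = "repulsion"


# ---------------------------------------------------------------------------
# phase assignment


def assign_phase(
    genotypes: pd.DataFrame,
    anchor: pd.Series | str,
) -> pd.DataFrame:
    """Phase each marker relative to an anchor.

    Parameters
    ----------
    genotypes
        Offspring x marker H/A/. matrix (markers heterozygous in one parent).
    anchor
        Either a boolean/0-1 Series over offspring that is True for carriers
        of the anchor haplotype (e.g. male-sterile = W-carrying offspring),
        or the name of an anchor marker column whose heterozygous calls
        define the anchor haplotype.

    Returns
    -------
    DataFrame indexed by marker with columns ``phase`` (coupling/repulsion/
    NaN for unphaseable 50:50 splits, which are excluded downstream) and
    ``confidence`` (concordance fraction among informative offspring).
    """
    if isinstance(anchor, str):
        col = genotypes[anchor]
        carrier = col.map({HET: True, HOM: False, MISSING: np.nan})
    else:
        carrier = anchor.reindex(genotypes.index).astype(float)
    carrier = carrier.astype(float)
    if carrier.dropna().nunique() < 2:
        raise ValueError("anchor must have both carrier classes represented")

    arr = genotypes.to_numpy()
    het = arr == HET
    hom = arr == HOM
    informative = het | hom
    c = carrier.to_numpy()[:, None]
    known = ~np.isnan(c) & informative
    # concordant with coupling: het among carriers, hom among non-carriers
    concord = np.where(known, np.where(c == 1, het, hom), False).sum(axis=0)
    n_inf = known.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = concord / n_inf
    phase = np.where(frac > 0.5, COUPLING, REPULSION).astype(object)
    phase[(n_inf == 0) | (frac == 0.5)] = None  # ties -> unphased, excluded
    confidence = np.where(frac > 0.5, frac, 1 - frac)
    confidence[n_inf == 0] = np.nan
    return pd.DataFrame(
        {"phase": phase, "confidence": confidence, "n_informative": n_inf},
        index=genotypes.columns.rename("marker_id"),
    )


def chain_phase(genotypes: pd.DataFrame) -> pd.Series:
    """Phase markers along a linkage group by chaining adjacent markers.

    Columns must already be ordered by reference position.  The first
    marker anchors haplotype labels; each subsequent marker is phased
    against its nearest previously phased neighbour by majority
    co-inheritance.  An exact 50:50 split leaves the marker unphased (NaN).
    Suitable for autosomes where no trait anchor exists; adjacent markers
    are tightly linked so the majority vote is reliable even though distant
    pairs approach r = 0.5.
    """
    arr = genotypes.to_numpy()
    het = arr == HET
    informative = het | (arr == HOM)
    n_markers = arr.shape[1]
    phase = np.full(n_markers, np.nan, dtype=object)
    phase[0] = COUPLING
    last = 0
    for k in range(1, n_markers):
        both = informative[:, k] & informative[:, last]
        n = int(both.sum())
        if n == 0:
            continue
        agree = int((het[both, k] == het[both, last]).sum())
        if 2 * agree == n:
            continue  # tie -> unphased
        same = agree > n - agree
        prev = phase[last]
        if same:
            phase[k] = prev
        else:
            phase[k] = REPULSION if prev == COUPLING else COUPLING
        last = k
    return pd.Series(phase, index=genotypes.columns.rename("marker_id"), name="phase")


def haplotype_matrix(genotypes: pd.DataFrame, phase: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Translate H/A calls into inherited-haplotype indicators.

    Returns an offspring x marker float matrix with 1.0 where the offspring
    inherited the anchor haplotype (W on the sex group), 0.0 for the
    alternative, NaN for missing calls or unphased markers.
    """
    if isinstance(phase, pd.DataFrame):
        phase = phase["phase"]
    phase = phase.reindex(genotypes.columns)
    arr = genotypes.to_numpy()
    het = (arr == HET).astype(float)
    out = np.where(arr == MISSING, np.nan, het)
    flip = (phase == REPULSION).to_numpy()[None, :]
    out = np.where(flip, 1 - out, out)
    unphased = phase.isna().to_numpy()[None, :]
    out = np.where(unphased, np.nan, out)
    return pd.DataFrame(out, index=genotypes.index, columns=genotypes.columns)


# ---------------------------------------------------------------------------
# two-point linkage


@dataclass(frozen=True)
class TwoPointResult:
    """Testcross two-point estimate: recombinant count R out of n
    informative offspring, MLE recombination fraction and its LOD."""

    r_hat: float
    R: int
    n: int
    lod: float


def twopoint_lod(n: int, R: int) -> float:
    """Testcross LOD at the MLE r = R/n.

    LOD = (n-R) log10(2(1-r)) + R log10(2r); the r=0 limit is n log10 2,
    and R = n/2 gives LOD = 0.
    """
    if n <= 0:
        raise ValueError("need at least one informative offspring")
    if not 0 <= R <= n:
        raise ValueError("recombinant count must lie in [0, n]")
    r = R / n
    if R == 0:
        return n * math.log10(2.0)
    if R == n:
        return n * math.log10(2.0)  # complete repulsion: relabel, same evidence
    return (n - R) * math.log10(2 * (1 - r)) + R * math.log10(2 * r)


def twopoint(a: pd.Series | np.ndarray, b: pd.Series | np.ndarray) -> TwoPointResult:
    """Two-point linkage between two haplotype-indicator vectors (0/1/NaN).

    Offspring missing either call are ignored.  ``b`` may be a trait
    pseudo-marker (e.g. male sterility coded 1).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need >=2 informative offspring for two-point linkage")
    R = int((x[ok] != y[ok]).sum())
    # phase between the two vectors is unknown: choose the orientation
    # with fewer recombinants (r <= 0.5)
    R = min(R, n - R)
    return TwoPointResult(r_hat=R / n, R=R, n=n, lod=twopoint_lod(n, R))


def group_markers(pairs: pd.DataFrame, lod_threshold: float = 3.0) -> pd.Series:
    """Single-linkage clustering of markers from a pairwise LOD table.

    ``pairs`` has columns ``marker_a, marker_b, lod``; edges with
    lod >= lod_threshold join markers into one linkage group.  Returns a
    Series marker -> group index (0-based, ordered by first appearance).
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    markers: list[str] = []
    for m in pd.concat([pairs["marker_a"], pairs["marker_b"]]):
        if m not in parent:
            parent[m] = m
            markers.append(m)
    for _, row in pairs.iterrows():
        if row["lod"] >= lod_threshold:
            ra, rb = find(row["marker_a"]), find(row["marker_b"])
            if ra != rb:
                parent[rb] = ra
    roots: dict[str, int] = {}
    out = {}
    for m in markers:
        r = find(m)
        out[m] = roots.setdefault(r, len(roots))
    return pd.Series(out, name="linkage_group")


# ---------------------------------------------------------------------------
# event counting


@dataclass
class PhasedChromosome:
    """Per-offspring phase sequence along one linkage group with its
    error-filtered recombination events."""

    offspring_id: str
    group_id: str
    markers: list[str]
    phases: np.ndarray  # 0/1 over the non-missing markers, in bp order
    events: list[tuple[str, str]] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)


def count_events(
    calls: pd.Series | np.ndarray,
    markers: list[str] | None = None,
    offspring_id: str = "",
    group_id: str = "",
    min_terminal_run: int = 1,
) -> PhasedChromosome:
    """Count phase switches along one offspring's ordered haplotype calls.

    ``calls`` is a 0/1/NaN vector in reference-bp order; NaN (missing or
    unphased) entries are skipped, and switches are assessed between the
    nearest non-missing neighbours.  A single marker of deviant phase
    flanked on both sides by the opposite phase is flagged as a singleton
    (putative genotyping error) and excluded: the two apparent switches it
    creates are not retained events.  Runs of >=2 deviant markers count as
    two genuine events.

    ``min_terminal_run`` optionally extends the error filter to the group
    ends: a terminal run shorter than this is also flagged as a putative
    error rather than a retained event (a lone deviant first or last marker
    is as attributable to genotyping error as an interior singleton, but
    has only one flank).  The default 1 keeps all terminal runs; analyses
    that raise it trade the outermost marker gap's events for robustness,
    shrinking the detectable span to the second .. second-to-last markers.
    """
    if isinstance(calls, pd.Series):
        if markers is None:
            markers = list(calls.index)
        calls = calls.to_numpy()
    x = np.asarray(calls, dtype=float)
    if markers is None:
        markers = [str(i) for i in range(len(x))]
    keep = ~np.isnan(x)
    obs = x[keep].astype(int)
    names = [markers[i] for i in np.nonzero(keep)[0]]
    if len(obs) < 2:
        return PhasedChromosome(offspring_id, group_id, names, obs)

    # run-length encode, drop interior runs of length 1 (singletons)
    boundaries = np.nonzero(np.diff(obs))[0]
    run_starts = np.concatenate([[0], boundaries + 1])
    run_ends = np.concatenate([boundaries, [len(obs) - 1]])  # inclusive
    singles: list[str] = []
    kept_runs = []
    n_runs = len(run_starts)
    for i, (s, e) in enumerate(zip(run_starts, run_ends)):
        interior_singleton = s == e and 0 < i < n_runs - 1
        short_terminal = (
            n_runs > 1
            and (i == 0 or i == n_runs - 1)
            and (e - s + 1) < min_terminal_run
        )
        if interior_singleton or short_terminal:
            singles.extend(names[s : e + 1])
        else:
            kept_runs.append((s, e))
    events: list[tuple[str, str]] = []
    for (s1, e1), (s2, e2) in zip(kept_runs, kept_runs[1:]):
        if obs[s1] != obs[s2]:
            events.append((names[e1], names[s2]))
    return PhasedChromosome(offspring_id, group_id, names, obs, events, singles)


def count_events_matrix(
    haplotypes: pd.DataFrame, group_id: str = "", min_terminal_run: int = 1
) -> list[PhasedChromosome]:
    """Apply :func:`count_events` to every offspring row of a
    haplotype-indicator matrix (columns in bp order)."""
    cols = list(haplotypes.columns)
    return [
        count_events(
            row.to_numpy(),
            cols,
            offspring_id=str(oid),
            group_id=group_id,
            min_terminal_run=min_terminal_run,
        )
        for oid, row in haplotypes.iterrows()
    ]


def events_table(chromosomes: list[PhasedChromosome]) -> pd.DataFrame:
    """Flatten retained events and singleton flags into a tidy table."""
    rows = []
    for pc in chromosomes:
        for left, right in pc.events:
            rows.append((pc.offspring_id, pc.group_id, left, right, False))
        for m in pc.singletons:
            rows.append((pc.offspring_id, pc.group_id, m, m, True))
    return pd.DataFrame(
        rows, columns=["offspring_id", "group_id", "left_marker", "right_marker", "singleton"]
    )


# ---------------------------------------------------------------------------
# rearrangement flags and map positions


def flag_rearrangements(
    haplotypes: pd.DataFrame,
    positions: pd.Series,
    min_support: int = 2,
) -> list[tuple[str, str]]:
    """Flag adjacent marker pairs whose reference order looks wrong.

    For each adjacent pair in bp order, count offspring whose local event
    count would drop if the two markers were swapped (i.e. the swap removes
    an apparent double recombinant).  Pairs supported by at least
    ``min_support`` offspring genotypes are flagged as potential genomic
    rearrangements relative to the reference.
    """
    cols = [c for c in positions.sort_values().index if c in haplotypes.columns]
    arr = haplotypes[cols].to_numpy()
    flags: list[tuple[str, str]] = []
    for k in range(len(cols) - 1):
        support = 0
        for row in arr:
            window = row[max(0, k - 1) : k + 3]
            window = window[~np.isnan(window)]
            if len(window) < 2:
                continue
            cur = int(np.count_nonzero(np.diff(window)))
            w = row[max(0, k - 1) : k + 3].copy()
            ai = k - max(0, k - 1)
            if ai + 1 >= len(w):
                continue
            w[ai], w[ai + 1] = w[ai + 1], w[ai]
            w = w[~np.isnan(w)]
            swapped = int(np.count_nonzero(np.diff(w)))
            if swapped < cur:
                support += 1
        if support >= min_support:
            flags.append((cols[k], cols[k + 1]))
    return flags


def map_positions(
    chromosomes: list[PhasedChromosome],
    marker_order: list[str],
    n_offspring: int | None = None,
) -> pd.Series:
    """Cumulative cM positions from retained event counts.

    The cM increment between adjacent markers is 100 x (retained events in
    the interval) / n, the count-based map distance; positions accumulate
    from 0 at the first marker.  Events whose flanking interval spans
    several marker gaps (because of missing calls) are assigned to the gap
    between the flanking non-missing markers' positions, spread at the
    leftmost gap boundary.
    """
    if n_offspring is None:
        n_offspring = len(chromosomes)
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    idx = {m: i for i, m in enumerate(marker_order)}
    gap_events = np.zeros(max(len(marker_order) - 1, 0))
    for pc in chromosomes:
        for left, right in pc.events:
            gap_events[idx[left]] += 1
    increments = 100.0 * gap_events / n_offspring
    cm = np.concatenate([[0.0], np.cumsum(increments)])
    return pd.Series(cm, index=pd.Index(marker_order, name="marker_id"), name="cM")
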