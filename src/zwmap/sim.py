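"""Synthetic octoploid pseudo-testcross F1 crosses with known truth.

The generator emulates a dioecious allo-octoploid design: two outbred
parents, each contributing 28 linkage groups (7 homeologous groups x 4
fully diploidized subgenomes), with markers heterozygous in exactly one
parent segregating 1:1.  One maternal group (VI-Av-m by default) carries a
distal W-linked sex-determining region: offspring inheriting the W
haplotype at the causal locus are male-sterile (up to a small phenotype
mismatch rate) and have high female fertility, while ZZ offspring are
male-fertile and mostly female-sterile, giving the bimodal fertility
distribution seen in real crosses.

Meiosis is modelled as a crossover Poisson process without interference,
with a piecewise-constant intensity map (cM/Mb) per linkage group, so the
expected count-based map length equals the integral of the rate map.  Two
genotyping panels mirror the study design: a small set of offspring
genotyped genome-wide ("capture") and a large set genotyped only near the
SDR ("amplicon").
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as zio

MB = 1_000_000

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII"]
SUBGENOMES = ("Av", "B1", "B2", "Bi")

#: approximate Fvb (diploid reference) chromosome lengths, bp; Fvb6 matches
#: the 38.873 Mb sex chromosome exactly
FVB_LENGTHS_BP = {
    "I": 23_400_000,
    "II": 28_800_000,
    "III": 35_000_000,
    "IV": 32_700_000,
    "V": 29_000_000,
    "VI": 38_873_000,
    "VII": 23_000_000,
}


# ---------------------------------------------------------------------------
# rate maps and haplotypes


@dataclass(frozen=True)
class RateMap:
    """Piecewise-constant recombination intensity along one linkage group.

    ``pieces`` are (start_bp, end_bp, rate_cM_per_Mb) tiles covering
    [0, length_bp) without overlap; rates are finite and non-negative.
    """

    group_id: str
    length_bp: int
    pieces: tuple[tuple[int, int, float], ...]

    def __post_init__(self):
        if not self.pieces:
            raise ValueError("rate map must contain at least one piece")
        cursor = 0
        for start, end, r in self.pieces:
            if start != cursor or end <= start:
                raise ValueError("pieces must tile [0, length) without gaps/overlap")
            if not np.isfinite(r) or r < 0:
                raise ValueError("rates must be finite and non-negative")
            cursor = end
        if cursor != self.length_bp:
            raise ValueError("pieces must end at length_bp")

    @classmethod
    def uniform(cls, group_id: str, length_bp: int, rate: float) -> "RateMap":
        return cls(group_id, length_bp, ((0, length_bp, rate),))

    def with_interval(self, start_bp: int, end_bp: int, rate: float) -> "RateMap":
        """Override the rate on [start_bp, end_bp), splitting tiles."""
        if not 0 <= start_bp < end_bp <= self.length_bp:
            raise ValueError("interval outside the group")
        pieces: list[tuple[int, int, float]] = []
        for s, e, r in self.pieces:
            if e <= start_bp or s >= end_bp:
                pieces.append((s, e, r))
                continue
            if s < start_bp:
                pieces.append((s, start_bp, r))
            if e > end_bp:
                pieces.append((end_bp, e, r))
        pieces.append((start_bp, end_bp, rate))
        return RateMap(self.group_id, self.length_bp, tuple(sorted(pieces)))

    @property
    def expected_crossovers(self) -> float:
        """Integral of rate over the map: expected crossovers per meiosis."""
        return sum((e - s) / MB * r / 100.0 for s, e, r in self.pieces)

    def rate_at(self, pos_bp: float) -> float:
        for s, e, r in self.pieces:
            if s <= pos_bp < e:
                return r
        raise ValueError("position outside the rate map")

    def sample_crossovers(self, rng: np.random.Generator) -> np.ndarray:
        """Crossover positions for one meiosis (Poisson, no interference)."""
        positions = []
        for s, e, r in self.pieces:
            lam = (e - s) / MB * r / 100.0
            k = rng.poisson(lam)
            if k:
                positions.append(rng.uniform(s, e, size=k))
        if not positions:
            return np.empty(0)
        return np.sort(np.concatenate(positions))


@dataclass(frozen=True)
class ParentalHaplotypes:
    """One parent's two haplotypes over the markers of one linkage group.

    ``hap1``/``hap2`` are 0/1 alternative-allele indicators at
    ``positions_bp`` (sorted); ``w_flag`` marks haplotype 1 as the W (set
    on exactly one maternal group of a cross).
    """

    group_id: str
    positions_bp: np.ndarray
    hap1: np.ndarray
    hap2: np.ndarray
    w_flag: bool = False

    def __post_init__(self):
        if not (len(self.positions_bp) == len(self.hap1) == len(self.hap2)):
            raise ValueError("haplotype vectors must match marker positions")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("markers must be sorted by bp, strictly increasing")


def simulate_gamete(
    parent: ParentalHaplotypes, rates: RateMap, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One meiotic product: allele vector at the markers + crossover positions.

    The starting strand is a fair coin; the strand switches at each
    crossover.  The zero-rate limit returns a pure parental haplotype.
    """
    if len(parent.positions_bp) and parent.positions_bp.max() > rates.length_bp:
        raise ValueError("rate map does not cover all marker positions")
    crossovers = rates.sample_crossovers(rng)
    start = int(rng.integers(0, 2))
    strand = (start + np.searchsorted(crossovers, parent.positions_bp)) % 2
    alleles = np.where(strand == 0, parent.hap1, parent.hap2)
    return alleles, crossovers


# ---------------------------------------------------------------------------
# cross configuration


@dataclass
class CrossConfig:
    """Study-design parameters of the synthetic cross.

    Defaults mirror the primary cross: 1275 offspring, 42 genotyped
    genome-wide, the rest on SDR-vicinity amplicons; chromosome-wide ZW /
    ZZ rates 3.3 / 1.7 cM/Mb against a 2.5 genome background, with the
    330 kb SDR window at 1.5 (maternal) / 4.1 (paternal); 0.5% genotyping
    error and 5% missingness; 1% genotype-phenotype mismatch for male
    function.
    """

    n_offspring: int = 1275
    n_capture_offspring: int = 42
    capture_markers_per_mb: float = 1.2
    homeolog_lengths_bp: dict = field(default_factory=lambda: dict(FVB_LENGTHS_BP))
    sex_homeolog: str = "VI"
    sex_subgenome: str = "Av"
    # rates, cM/Mb
    rate_genome: float = 2.5
    rate_zw: float = 3.3
    rate_zz: float = 1.7
    rate_sdr_maternal: float = 1.5
    rate_sdr_paternal: float = 4.1
    sdr_rate_window: tuple = (37_378_000, 37_708_000)
    # SDR and amplicon design (bp on the sex homeolog)
    sdr_start_bp: int = 37_428_000
    sdr_end_bp: int = 37_708_000
    #: causal sex locus: defaults to the sex-associated marker position,
    #: the best available point estimate of the sex determinant inside the SDR
    sdr_locus_bp: int = 37_594_072
    sdr_vicinity: tuple = (37_378_000, 38_873_000)
    high_div_window: tuple = (37_565_000, 37_708_000)
    n_amplicon_coupling: int = 18
    n_amplicon_coupling_highdiv: int = 10
    n_amplicon_repulsion: int = 18
    n_amplicon_paternal: tuple = (9, 15)
    # phenotype model
    male_mismatch_rate: float = 0.01
    n_male_phenotyped: int = 693
    n_female_phenotyped: int = 619
    fert_w_beta: tuple = (3.0, 1.0)
    fert_zz_beta: tuple = (0.45, 4.05)
    mean_flowers: float = 15.5
    # genotyping noise
    genotyping_error: float = 0.005
    missing_rate: float = 0.05

    @property
    def sex_group_maternal(self) -> str:
        return f"{self.sex_homeolog}-{self.sex_subgenome}-m"

    @property
    def sex_group_paternal(self) -> str:
        return f"{self.sex_homeolog}-{self.sex_subgenome}-p"

    def validate(self) -> None:
        length = self.homeolog_lengths_bp[self.sex_homeolog]
        if not 0 < self.sdr_start_bp < self.sdr_end_bp <= length:
            raise ValueError("SDR interval outside the sex chromosome")
        if not self.sdr_start_bp <= self.sdr_locus_bp <= self.sdr_end_bp:
            raise ValueError("SDR causal locus outside the SDR interval")
        if self.n_offspring <= 0 or self.n_capture_offspring <= 0:
            raise ValueError("offspring counts must be positive")
        if self.n_capture_offspring > self.n_offspring:
            raise ValueError("capture panel larger than the cross")
        for r in (0.0, self.genotyping_error, self.missing_rate, self.male_mismatch_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CrossConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()})
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def rate_maps(self) -> dict[str, RateMap]:
        """Per-group rate maps implied by the configuration."""
        maps = {}
        for hom, length in self.homeolog_lengths_bp.items():
            for sub in SUBGENOMES:
                for par in ("m", "p"):
                    gid = f"{hom}-{sub}-{par}"
                    rm = RateMap.uniform(gid, length, self.rate_genome)
                    if gid == self.sex_group_maternal:
                        rm = RateMap.uniform(gid, length, self.rate_zw).with_interval(
                            *self.sdr_rate_window, self.rate_sdr_maternal
                        )
                    elif gid == self.sex_group_paternal:
                        rm = RateMap.uniform(gid, length, self.rate_zz).with_interval(
                            *self.sdr_rate_window, self.rate_sdr_paternal
                        )
                    maps[gid] = rm
        return maps


@dataclass
class CrossTruth:
    """Ground truth of a simulated cross for parameter-recovery tests."""

    sdr_interval: tuple[int, int]
    sdr_locus_bp: int
    w_carrier: pd.Series  # offspring -> bool
    crossovers: dict  # group_id -> list of per-offspring position arrays
    haplotypes: dict  # group_id -> ParentalHaplotypes
    male_mismatch_rate: float

    def crossover_frame(self) -> pd.DataFrame:
        rows = []
        offspring = list(self.w_carrier.index)
        for gid, arrs in self.crossovers.items():
            for oid, pos in zip(offspring, arrs):
                rows.append(
                    (
                        oid,
                        gid,
                        ",".join(f"{p:.0f}" for p in pos),
                        bool(self.w_carrier[oid]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["offspring_id", "group_id", "crossover_bp", "w_carrier"]
        )


@dataclass
class SimulatedCross:
    """A synthetic cross: marker table, genotype matrix, phenotypes, truth."""

    markers: pd.DataFrame
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: CrossTruth
    capture_ids: list[str]
    config: CrossConfig

    @property
    def amplicon_markers(self) -> pd.Index:
        return self.markers.index[self.markers["panel"] == "amplicon"]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        zio.write_markers(self.markers, outdir / "markers.tsv")
        zio.write_genotypes(self.genotypes, outdir / "genotypes.tsv")
        zio.write_phenotypes(self.phenotypes, outdir / "phenotypes.tsv")
        self.truth.crossover_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# cross simulation


def _unique_positions(rng, n, lo, hi, used: set) -> np.ndarray:
    out: list[int] = []
    while len(out) < n:
        cand = int(rng.integers(lo, hi))
        if cand not in used:
            used.add(cand)
            out.append(cand)
    return np.sort(np.array(out, dtype=np.int64))


def _group_markers(cfg: CrossConfig, rng, used_by_chrom) -> dict[str, pd.DataFrame]:
    """Lay out capture and amplicon markers per linkage group."""
    tables = {}
    for hom, length in cfg.homeolog_lengths_bp.items():
        chrom = f"Fvb{ROMAN.index(hom) + 1}"
        used = used_by_chrom.setdefault(chrom, set())
        for sub in SUBGENOMES:
            for par in ("m", "p"):
                gid = f"{hom}-{sub}-{par}"
                n_cap = max(2, int(round(length / MB * cfg.capture_markers_per_mb)))
                pos = _unique_positions(rng, n_cap, 1, length, used)
                df = pd.DataFrame(
                    {
                        "ref_chrom": chrom,
                        "ref_pos_bp": pos,
                        "group_id": gid,
                        "seg_parent": par,
                        "panel": "capture",
                        "amplicon_id": "",
                    }
                )
                tables[gid] = df
    # amplicon sites on the two sex groups
    hom = cfg.sex_homeolog
    chrom = f"Fvb{ROMAN.index(hom) + 1}"
    used = used_by_chrom[chrom]
    vic_lo, vic_hi = cfg.sdr_vicinity
    hd_lo, hd_hi = cfg.high_div_window

    def amp(gid, par, n, lo, hi, kind):
        pos = _unique_positions(rng, n, lo, hi, used)
        return pd.DataFrame(
            {
                "ref_chrom": chrom,
                "ref_pos_bp": pos,
                "group_id": gid,
                "seg_parent": par,
                "panel": "amplicon",
                "amplicon_id": [f"amp_{kind}_{i}" for i in range(n)],
                "amp_kind": kind,
            }
        )

    gm, gp = cfg.sex_group_maternal, cfg.sex_group_paternal
    n_hd = cfg.n_amplicon_coupling_highdiv
    pieces = [
        amp(gm, "m", n_hd, hd_lo, hd_hi, "coupling"),
        amp(gm, "m", cfg.n_amplicon_coupling - n_hd, vic_lo, vic_hi, "coupling"),
        amp(gm, "m", cfg.n_amplicon_repulsion, vic_lo, vic_hi, "repulsion"),
        amp(gp, "p", cfg.n_amplicon_paternal[0], vic_lo, vic_hi, "z1"),
        amp(gp, "p", cfg.n_amplicon_paternal[1], vic_lo, vic_hi, "z2"),
    ]
    for piece in pieces:
        gid = piece["group_id"].iloc[0]
        base = tables[gid]
        if "amp_kind" not in base.columns:
            base["amp_kind"] = ""
        tables[gid] = (
            pd.concat([base, piece], ignore_index=True)
            .sort_values("ref_pos_bp")
            .reset_index(drop=True)
        )
    return tables


def _parental_haplotypes(
    cfg: CrossConfig, tables: dict[str, pd.DataFrame], rng
) -> dict[str, ParentalHaplotypes]:
    haps = {}
    for gid, tab in tables.items():
        pos = tab["ref_pos_bp"].to_numpy()
        n = len(pos)
        hap1 = rng.integers(0, 2, n)
        hap2 = 1 - hap1  # marker het in this parent: alt on exactly one haplotype
        kind = tab["amp_kind"].to_numpy() if "amp_kind" in tab.columns else np.full(n, "")
        w_flag = gid == cfg.sex_group_maternal
        if w_flag:
            # coupling sites carry the alt allele on W (= haplotype 1)
            hap1 = np.where(kind == "coupling", 1, hap1)
            hap1 = np.where(kind == "repulsion", 0, hap1)
            hap2 = 1 - hap1
        if gid == cfg.sex_group_paternal:
            hap1 = np.where(kind == "z1", 1, np.where(kind == "z2", 0, hap1))
            hap2 = 1 - hap1
        haps[gid] = ParentalHaplotypes(gid, pos, hap1.astype(np.int8), hap2.astype(np.int8), w_flag)
    return haps


def simulate_cross(config: CrossConfig | None = None, seed: int = 0) -> SimulatedCross:
    """Simulate the full F1 cross with both genotyping panels.

    All randomness flows from a single generator seeded with ``seed``;
    reruns with the same seed and configuration are byte-identical.
    """
    cfg = config or CrossConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    tables = _group_markers(cfg, rng, {})
    haps = _parental_haplotypes(cfg, tables, rng)
    maps = cfg.rate_maps()

    n = cfg.n_offspring
    offspring = [f"off{i:04d}" for i in range(n)]
    capture_ids = offspring[: cfg.n_capture_offspring]

    marker_frames = []
    geno_cols: dict[str, np.ndarray] = {}
    crossovers: dict[str, list[np.ndarray]] = {}
    w_strand = np.zeros(n, dtype=int)

    for gid, tab in tables.items():
        hp = haps[gid]
        rm = maps[gid]
        ids = [f"{gid}_{p}" for p in tab["ref_pos_bp"]]
        tab = tab.assign(marker_id=ids)
        marker_frames.append(tab)
        alleles = np.empty((n, len(hp.positions_bp)), dtype=np.int8)
        xovers: list[np.ndarray] = []
        for i in range(n):
            a, x = simulate_gamete(hp, rm, rng)
            alleles[i] = a
            xovers.append(x)
        crossovers[gid] = xovers
        if gid == cfg.sex_group_maternal:
            # strand (haplotype index) at the causal locus for every offspring
            for i, x in enumerate(xovers):
                start_strand = _strand_at(hp, x, alleles[i])
                w_strand[i] = (start_strand + np.searchsorted(x, cfg.sdr_locus_bp)) % 2
        for j, mid in enumerate(ids):
            geno_cols[mid] = alleles[:, j]

    markers = (
        pd.concat(marker_frames, ignore_index=True)
        .set_index("marker_id")
        .sort_values(["ref_chrom", "ref_pos_bp"])
    )

    w_carrier = pd.Series(w_strand == 0, index=pd.Index(offspring, name="offspring_id"))

    # genotype calls: H where the inherited allele is the alternative
    order = list(markers.index)
    mat = np.column_stack([geno_cols[m] for m in order]).astype(np.int8)
    calls = np.where(mat == 1, zio.HET, zio.HOM).astype(object)

    # genotyping error: flip H <-> A
    flip = rng.random(calls.shape) < cfg.genotyping_error
    calls = np.where(flip, np.where(calls == zio.HET, zio.HOM, zio.HET), calls)
    # missingness per call
    miss = rng.random(calls.shape) < cfg.missing_rate
    calls = np.where(miss, zio.MISSING, calls)
    # panel structure: amplicon-only offspring lack capture-panel genotypes
    capture_mask = markers["panel"].to_numpy() == "capture"
    amplicon_only = np.array([o not in set(capture_ids) for o in offspring])
    calls[np.ix_(amplicon_only, capture_mask)] = zio.MISSING

    genotypes = pd.DataFrame(
        calls, index=pd.Index(offspring, name="offspring_id"), columns=order
    )

    phenotypes = _phenotypes(cfg, rng, offspring, w_carrier)
    truth = CrossTruth(
        sdr_interval=(cfg.sdr_start_bp, cfg.sdr_end_bp),
        sdr_locus_bp=cfg.sdr_locus_bp,
        w_carrier=w_carrier,
        crossovers=crossovers,
        haplotypes=haps,
        male_mismatch_rate=cfg.male_mismatch_rate,
    )
    return SimulatedCross(markers, genotypes, phenotypes, truth, capture_ids, cfg)


def _strand_at(hp: ParentalHaplotypes, crossovers: np.ndarray, alleles: np.ndarray) -> int:
    """Recover the starting strand of a gamete from its allele vector."""
    # at the first marker: parity of crossovers before it maps start -> observed
    k = int(np.searchsorted(crossovers, hp.positions_bp[0]))
    first = alleles[0]
    strand_first = 0 if first == hp.hap1[0] else 1
    if hp.hap1[0] == hp.hap2[0]:  # uninformative first marker: scan forward
        for j in range(len(alleles)):
            if hp.hap1[j] != hp.hap2[j]:
                kj = int(np.searchsorted(crossovers, hp.positions_bp[j]))
                strand_j = 0 if alleles[j] == hp.hap1[j] else 1
                return (strand_j - kj) % 2
        return 0
    return (strand_first - k) % 2


def _phenotypes(cfg: CrossConfig, rng, offspring, w_carrier: pd.Series) -> pd.DataFrame:
    n = len(offspring)
    w = w_carrier.to_numpy()
    mismatch = rng.random(n) < cfg.male_mismatch_rate
    sterile = w ^ mismatch
    male = np.where(sterile, "S", "F").astype(object)

    aw, bw = cfg.fert_w_beta
    az, bz = cfg.fert_zz_beta
    latent = np.where(w, rng.beta(aw, bw, n), rng.beta(az, bz, n))
    flowers = np.maximum(1, rng.poisson(cfg.mean_flowers, n))
    fruits = rng.binomial(flowers, latent)

    # phenotyping coverage mirrors the study: subsets scored for each trait
    male_obs = np.zeros(n, dtype=bool)
    male_obs[rng.choice(n, size=min(cfg.n_male_phenotyped, n), replace=False)] = True
    fem_obs = np.zeros(n, dtype=bool)
    fem_obs[rng.choice(n, size=min(cfg.n_female_phenotyped, n), replace=False)] = True

    male = np.where(male_obs, male, ".")
    fruits_o = np.where(fem_obs, fruits.astype(float), np.nan)
    flowers_o = np.where(fem_obs, flowers.astype(float), np.nan)
    df = pd.DataFrame(
        {
            "male_function": male,
            "fruits": fruits_o,
            "pollinated_flowers": flowers_o,
            "total_flowers": flowers.astype(float),
        },
        index=pd.Index(offspring, name="offspring_id"),
    )
    df["female_fertility"] = df["fruits"] / df["pollinated_flowers"]
    return df


def sex_chromosome_config(
    n_offspring: int = 1200, n_capture_offspring: int = 42, **overrides
) -> CrossConfig:
    """A reduced configuration restricted to homeologous group VI.

    Simulates only the eight VI linkage groups (including the ZW/ZZ pair),
    which is all that SDR fine-mapping and amplicon-panel analyses consume;
    useful for replicate studies where the 56-group genome is unnecessary.
    """
    cfg = CrossConfig(
        n_offspring=n_offspring,
        n_capture_offspring=n_capture_offspring,
        homeolog_lengths_bp={"VI": FVB_LENGTHS_BP["VI"]},
        **overrides,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# unrelated panel


def simulate_unrelated_panel(
    n_females: int = 10,
    n_males: int = 12,
    concordance: float | tuple[float, float] = (0.9, 11.0 / 12.0),
    seed: int = 0,
    focal_pos_bp: int = 37_594_072,
    flank_positions_bp: tuple = (37_565_581, 37_565_641, 37_567_599, 37_567_962),
    n_background: int = 10,
    decay_zw_bp: float = 200_000.0,
    decay_zz_bp: float = 25_000.0,
    vicinity: tuple = (37_378_000, 38_873_000),
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Unrelated plants genotyped at SDR-vicinity sites.

    At the focal sex-associated site, females (ZW) are heterozygous with
    probability ``concordance[0]`` and males (ZZ) homozygous with
    probability ``concordance[1]`` (a scalar applies to both).

    Flanking sites sit on the same W haplotype block as the focal site, so
    their calls are nested within the focal genotype rather than drawn
    independently: in ZW plants a flank keeps the focal heterozygous call
    with a retention probability that decays slowly with distance
    (``decay_zw_bp``; the W block travels as a unit), while in ZZ plants
    the flank's minor allele also segregates on Z haplotypes, adding
    heterozygous calls at a rate that rises with distance (``decay_zz_bp``;
    sex association erodes quickly on the Z side).  Marginally the flank's
    per-sex association is 0.5 + (c - 0.5) exp(-d/decay); jointly a flank
    can tie the focal site's concordance but never exceed it, the LD
    structure real haplotype blocks show.  Background sites are
    unassociated.

    Returns (genotypes, sexes, positions); ``sexes`` is True for
    male-sterile (ZW) plants.
    """
    if n_females <= 0 or n_males <= 0:
        raise ValueError("panel sizes must be positive")
    cf, cm = (concordance, concordance) if np.isscalar(concordance) else concordance
    for c in (cf, cm):
        if not 0 <= c <= 1:
            raise ValueError("concordance must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    plants = [f"F{i:02d}" for i in range(n_females)] + [f"M{i:02d}" for i in range(n_males)]
    n_plants = len(plants)
    is_zw = np.array([True] * n_females + [False] * n_males)
    used: set[int] = {focal_pos_bp, *flank_positions_bp}
    bg = _unique_positions(rng, n_background, vicinity[0], vicinity[1], used)

    focal_het = rng.random(n_plants) < np.where(is_zw, cf, 1 - cm)
    cols = {}
    positions = {}
    for p in sorted([focal_pos_bp, *flank_positions_bp, *bg.tolist()]):
        if p == focal_pos_bp:
            het = focal_het
        elif p in flank_positions_bp:
            d = abs(p - focal_pos_bp)
            w_f = np.exp(-d / decay_zw_bp)
            w_m = np.exp(-d / decay_zz_bp)
            # marginal het rate = 0.5 + (cf-0.5) w_f in ZW (retention of the
            # focal het) and 0.5 - (cm-0.5) w_m in ZZ (extra Z-segregating
            # hets on top of the focal call)
            keep = (0.5 + (cf - 0.5) * w_f) / cf if cf > 0 else 0.0
            add = (cm - 0.5) * (1 - w_m) / cm if cm > 0 else 0.0
            u = rng.random(n_plants)
            het = np.where(
                is_zw,
                focal_het & (u < min(keep, 1.0)),
                focal_het | (u < add),
            )
        else:
            het = rng.random(n_plants) < 0.5
        sid = f"Fvb6_{p}"
        cols[sid] = np.where(het, zio.HET, zio.HOM)
        positions[sid] = p
    genotypes = pd.DataFrame(cols, index=pd.Index(plants, name="plant_id"))
    sexes = pd.Series(is_zw, index=genotypes.index, name="male_sterile")
    return genotypes, sexes, pd.Series(positions, name="ref_pos_bp")
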