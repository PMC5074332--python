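"""Tabular input/output, site filtering and phenotype derivations.

Canonical interchange formats are plain TSV:

``markers.tsv``
    ``marker_id  ref_chrom  ref_pos_bp  group_id  seg_parent  [amplicon_id]``
    Coordinates are 1-based bp on the diploid reference (Fvb1-7).
    ``group_id`` names the linkage group (homeolog I-VII, subgenome, parent),
    e.g. ``VI-Av-m``; ``seg_parent`` is ``m`` or ``p``.

``genotypes.tsv``
    Offspring rows x marker columns.  Cells are ``H`` (heterozygous),
    ``A`` (homozygous) or ``.`` (missing).  In a pseudo-testcross each
    marker is heterozygous in exactly one parent, so a single letter per
    call suffices.

``phenotypes.tsv``
    ``offspring_id  male_function  fruits  pollinated_flowers  total_flowers``
    with ``male_function`` in ``{F, S, .}`` (fertile / sterile / unknown).
    Female fertility is derived as fruits / pollinated_flowers.

``regions.bed``
    Written 0-based half-open (BED convention); all in-memory coordinates
    are 1-based closed intervals and converted on output only.

Optional read-only VCF input is supported through cyvcf2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GENOTYPE_CODES = frozenset({"H", "A", "."})
HET, HOM, MISSING = "H", "A", "."

FEMALE_STERILE_CUTOFF = 0.05


class ParseError(ValueError):
    """Raised when an input file violates the documented format."""


# ---------------------------------------------------------------------------
# readers / writers


def read_markers(path: str | Path) -> pd.DataFrame:
    """Read a marker table, indexed by marker_id and sorted by position.

    Validates uniqueness of marker ids and of (ref_chrom, ref_pos_bp)
    pairs, and that every segregating parent is ``m`` or ``p``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["marker_id", "ref_chrom", "ref_pos_bp", "group_id", "seg_parent"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"markers file missing columns: {missing_cols}")
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ParseError(f"duplicate marker_id {dup!r}")
    try:
        df["ref_pos_bp"] = df["ref_pos_bp"].astype(np.int64)
    except ValueError as exc:
        raise ParseError(f"malformed ref_pos_bp: {exc}") from exc
    if (df["ref_pos_bp"] < 1).any():
        raise ParseError("ref_pos_bp must be 1-based positive integers")
    if df.duplicated(["ref_chrom", "ref_pos_bp"]).any():
        raise ParseError("duplicate (ref_chrom, ref_pos_bp) coordinate")
    bad = set(df["seg_parent"]) - {"m", "p"}
    if bad:
        raise ParseError(f"seg_parent must be 'm' or 'p', got {sorted(bad)}")
    if "amplicon_id" not in df.columns:
        df["amplicon_id"] = ""
    df["amplicon_id"] = df["amplicon_id"].fillna("")
    df = df.set_index("marker_id")
    return df.sort_values(["ref_chrom", "ref_pos_bp"])


def write_markers(markers: pd.DataFrame, path: str | Path) -> None:
    markers.reset_index().rename(columns={"index": "marker_id"}).to_csv(
        path, sep="\t", index=False
    )


def read_genotypes(path: str | Path, markers: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read an offspring x marker genotype matrix (cells H/A/.)."""
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if df.shape[0] == 0:
        raise ParseError("genotype matrix has no offspring rows")
    if df.shape[1] == 0:
        raise ParseError("genotype matrix has no marker columns")
    if df.index.duplicated().any():
        raise ParseError("duplicate offspring ids")
    if df.columns.duplicated().any():
        raise ParseError("duplicate marker columns")
    df = df.fillna(MISSING)
    bad = set(np.unique(df.to_numpy())) - GENOTYPE_CODES
    if bad:
        raise ParseError(f"unknown genotype codes {sorted(bad)}; expected H/A/.")
    if markers is not None:
        unknown = df.columns.difference(markers.index)
        if len(unknown):
            raise ParseError(f"genotype columns absent from marker table: {list(unknown)[:5]}")
    df.index.name = "offspring_id"
    return df


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes.to_csv(path, sep="\t", index_label="offspring_id")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read phenotypes and derive female fertility = fruits / pollinated flowers.

    Rows with missing counts get NaN fertility; fruits must not exceed
    pollinated flowers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"offspring_id": str})
    required = ["offspring_id", "male_function", "fruits", "pollinated_flowers", "total_flowers"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ParseError(f"phenotype file missing columns: {missing_cols}")
    if df["offspring_id"].duplicated().any():
        raise ParseError("duplicate offspring ids in phenotypes")
    df = df.set_index("offspring_id")
    df["male_function"] = df["male_function"].fillna(".")
    bad = set(df["male_function"]) - {"F", "S", "."}
    if bad:
        raise ParseError(f"male_function must be F/S/., got {sorted(bad)}")
    for col in ["fruits", "pollinated_flowers", "total_flowers"]:
        df[col] = pd.to_numeric(df[col].replace(".", np.nan), errors="raise")
    if (df["fruits"] > df["pollinated_flowers"]).any():
        raise ParseError("fruits exceed pollinated_flowers for some offspring")
    df["female_fertility"] = df["fruits"] / df["pollinated_flowers"]
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    cols = ["male_function", "fruits", "pollinated_flowers", "total_flowers"]
    phenotypes[cols].to_csv(path, sep="\t", index_label="offspring_id", na_rep=".")


def write_regions(regions: pd.DataFrame, path: str | Path) -> None:
    """Write region calls as BED (0-based half-open on disk).

    ``regions`` has 1-based closed columns ``ref_chrom, start_bp, end_bp,
    name``; the conversion start-1 is applied on output only.
    """
    out = regions.copy()
    out["start_bp"] = out["start_bp"].astype(np.int64) - 1
    out["end_bp"] = out["end_bp"].astype(np.int64)
    out[["ref_chrom", "start_bp", "end_bp", "name"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read biallelic SNPs from a VCF into H/A/. coding (optional input path).

    Returns (genotypes, sites) where genotypes is samples x sites and sites
    has ref_chrom / ref_pos_bp per column.  Requires cyvcf2.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF input requires the optional cyvcf2 dependency") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, list[str]] = {}
    meta = []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        site_id = f"{var.CHROM}_{var.POS}"
        calls = []
        for gt in var.gt_types:  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
            calls.append({0: HOM, 1: HET, 3: HOM}.get(int(gt), MISSING))
        cols[site_id] = calls
        meta.append((site_id, var.CHROM, var.POS))
    if not cols:
        raise ParseError("no biallelic SNPs found in VCF")
    genotypes = pd.DataFrame(cols, index=pd.Index(samples, name="offspring_id"))
    sites = pd.DataFrame(meta, columns=["marker_id", "ref_chrom", "ref_pos_bp"]).set_index(
        "marker_id"
    )
    return genotypes, sites


# ---------------------------------------------------------------------------
# site statistics and filtering


def site_stats(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-site counts of missing / homozygous / heterozygous calls."""
    arr = genotypes.to_numpy()
    return pd.DataFrame(
        {
            "n_missing": (arr == MISSING).sum(axis=0),
            "n_hom": (arr == HOM).sum(axis=0),
            "n_het": (arr == HET).sum(axis=0),
        },
        index=genotypes.columns.rename("site_id"),
    )


def filter_sites(
    stats: pd.DataFrame,
    max_missing: int = 200,
    min_hom: int = 40,
    min_het: int = 40,
) -> pd.Series:
    """Pass/fail per site: missing <= max_missing, hom >= min_hom, het >= min_het.

    Defaults are the large-cross thresholds; small crosses and unrelated
    panels use (10, 4, 4).
    """
    if min(max_missing, min_hom, min_het) < 0:
        raise ValueError("filter thresholds must be non-negative")
    return (
        (stats["n_missing"] <= max_missing)
        & (stats["n_hom"] >= min_hom)
        & (stats["n_het"] >= min_het)
    )


def female_sterile(female_fertility):
    """Classify female-sterility: fertility strictly below 5%."""
    x = np.asarray(female_fertility, dtype=float)
    valid = ~np.isnan(x)
    if ((x[valid] < 0) | (x[valid] > 1)).any():
        raise ValueError("female_fertility must lie in [0, 1]")
    out = x < FEMALE_STERILE_CUTOFF
    if np.ndim(female_fertility) == 0:
        return bool(out)
    return out


# ---------------------------------------------------------------------------
# sex-function regressions


@dataclass(frozen=True)
class SexFunctionRegression:
    """OLS of female fertility on binary male function, without and with
    total flower number as a covariate."""

    simple_coef: float
    simple_r2: float
    simple_p: float
    multi_r2: float
    multi_p: float
    n: int


def regress_sex_functions(phenotypes: pd.DataFrame) -> SexFunctionRegression:
    """Regress female fertility on male function (fertile=1, sterile=0),
    then add total flower number as a second predictor.

    Rows with any missing value among the three variables are dropped
    (listwise deletion).  Raises on a constant predictor.
    """
    import statsmodels.api as sm

    df = phenotypes.loc[phenotypes["male_function"].isin(["F", "S"])].copy()
    df["male_binary"] = (df["male_function"] == "F").astype(float)
    df = df.dropna(subset=["female_fertility", "male_binary", "total_flowers"])
    if len(df) < 3:
        raise ValueError("need at least 3 complete phenotype records")
    if df["male_binary"].nunique() < 2:
        raise ValueError("male function is constant; regression undefined")

    y = df["female_fertility"].to_numpy()
    x1 = sm.add_constant(df[["male_binary"]].to_numpy())
    fit1 = sm.OLS(y, x1).fit()
    x2 = sm.add_constant(df[["male_binary", "total_flowers"]].to_numpy())
    fit2 = sm.OLS(y, x2).fit()
    return SexFunctionRegression(
        simple_coef=float(fit1.params[1]),
        simple_r2=float(fit1.rsquared),
        simple_p=float(fit1.f_pvalue),
        multi_r2=float(fit2.rsquared),
        multi_p=float(fit2.f_pvalue),
        n=int(len(df)),
    )
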