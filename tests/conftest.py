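"""Shared fixtures: small synthetic crosses reused across test modules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import zwmap as z

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sex_cross():
    """A 600-offspring cross restricted to homeologous group VI (ZW/ZZ pair
    plus six autosomal homeologs), with default noise."""
    cfg = z.sex_chromosome_config(n_offspring=600, n_capture_offspring=42)
    return z.simulate_cross(cfg, seed=11)


@pytest.fixture(scope="session")
def clean_sex_cross():
    """Noise-free VI-only cross: no genotyping error, no missingness, no
    phenotype mismatch; every offspring fully phenotyped."""
    cfg = z.sex_chromosome_config(
        n_offspring=400,
        n_capture_offspring=42,
        genotyping_error=0.0,
        missing_rate=0.0,
        male_mismatch_rate=0.0,
        n_male_phenotyped=400,
        n_female_phenotyped=400,
    )
    return z.simulate_cross(cfg, seed=7)


@pytest.fixture(scope="session")
def genome_cross():
    """A full 56-linkage-group cross at reduced offspring count."""
    cfg = z.CrossConfig(
        n_offspring=60,
        n_capture_offspring=60,
        n_male_phenotyped=60,
        n_female_phenotyped=60,
    )
    return z.simulate_cross(cfg, seed=3)


def sterile_series(cross) -> pd.Series:
    return cross.phenotypes["male_function"].map({"S": 1.0, "F": 0.0})


def maternal_sex_markers(cross) -> pd.Index:
    mk = cross.markers
    return mk.index[mk["group_id"] == cross.config.sex_group_maternal]


def truth_phase(cross) -> pd.Series:
    """True coupling/repulsion labels of maternal sex-group markers."""
    gid = cross.config.sex_group_maternal
    hp = cross.truth.haplotypes[gid]
    cols = maternal_sex_markers(cross)
    return pd.Series(
        np.where(hp.hap1 == 1, "coupling", "repulsion"), index=cols, name="phase"
    )
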