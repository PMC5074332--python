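"""QTL scans, breakpoint bounding and dependent-correlation comparison."""

import numpy as np
import pandas as pd
import pytest

import zwmap as z
from zwmap.io import HET, HOM

from conftest import maternal_sex_markers, sterile_series


def binary_cross(n=42, mismatches=0, seed=0):
    """A single perfectly W-linked marker plus an unlinked one."""
    rng = np.random.default_rng(seed)
    sterile = np.zeros(n, dtype=bool)
    sterile[: n // 2] = True
    geno = np.where(sterile, HET, HOM).astype(object)
    for i in range(mismatches):
        geno[i] = HOM  # sterile offspring with a Z-looking genotype
    unlinked = np.where(rng.random(n) < 0.5, HET, HOM)
    idx = [f"o{i}" for i in range(n)]
    g = pd.DataFrame({"sdr": geno, "far": unlinked}, index=idx)
    return g, pd.Series(sterile, index=idx), pd.Series({"sdr": 100, "far": 200})


class TestScanBinary:
    def test_perfect_cosegregation_lod(self):
        g, sterile, pos = binary_cross(42)
        scan = z.scan_binary(g, sterile, pos)
        assert scan.peak_marker == "sdr"
        assert scan.peak_lod == pytest.approx(42 * np.log10(2))
        assert scan.peak_r2 == pytest.approx(1.0)
        assert scan.peak_mismatches == 0

    def test_single_mismatch_gives_published_style_lod(self):
        g, sterile, pos = binary_cross(42, mismatches=1)
        scan = z.scan_binary(g, sterile, pos)
        assert round(scan.peak_lod, 1) == 10.6
        assert scan.peak_mismatches == 1

    def test_unlinked_marker_has_negligible_lod(self):
        g, sterile, pos = binary_cross(200, seed=3)
        scan = z.scan_binary(g, sterile, pos)
        assert scan.lod["far"] < 1.0

    def test_monomorphic_trait_rejected(self):
        g, sterile, pos = binary_cross(10)
        with pytest.raises(ValueError, match="monomorphic"):
            z.scan_binary(g, pd.Series(True, index=g.index), pos)


class TestScanQuant:
    @staticmethod
    def _fixture(n=30, effect=1.0, seed=1):
        rng = np.random.default_rng(seed)
        het = rng.random(n) < 0.5
        y = effect * het + rng.normal(0, 0.5, n)
        g = pd.DataFrame(
            {"q": np.where(het, HET, HOM)}, index=[f"o{i}" for i in range(n)]
        )
        return g, pd.Series(y, index=g.index)

    def test_independent_trait_has_low_lod(self):
        g, y = self._fixture(effect=0.0, seed=2)
        scan, cands = z.scan_quant(g, y)
        assert scan.peak_lod < 3
        assert len(cands) == 0

    def test_perfect_fit_reported_as_infinite(self):
        g, _ = self._fixture()
        y = pd.Series((g["q"] == HET).astype(float), index=g.index)
        scan, _ = z.scan_quant(g, y)
        assert np.isinf(scan.peak_lod)

    def test_matches_likelihood_ratio_oracle(self):
        """(n/2) log10(RSS0/RSS1) equals the Gaussian ML likelihood-ratio
        LOD computed from explicit likelihoods."""
        g, y = self._fixture(n=30)
        scan, _ = z.scan_quant(g, y)
        x = (g["q"] == HET).to_numpy(float)
        yy = y.to_numpy()
        n = len(yy)
        rss0 = ((yy - yy.mean()) ** 2).sum()
        beta = np.polyfit(x, yy, 1)
        rss1 = ((yy - np.polyval(beta, x)) ** 2).sum()
        # profile log10-likelihood difference of the two Gaussian models
        ll0 = -n / 2 * np.log10(rss0 / n)
        ll1 = -n / 2 * np.log10(rss1 / n)
        assert scan.peak_lod == pytest.approx(ll1 - ll0)

    def test_lod_invariant_under_affine_trait_transform(self):
        g, y = self._fixture(n=50, seed=4)
        lod1 = z.scan_quant(g, y)[0].peak_lod
        lod2 = z.scan_quant(g, 3.5 * y - 2.0)[0].peak_lod
        assert lod1 == pytest.approx(lod2)

    def test_constant_trait_rejected(self):
        g, _ = self._fixture()
        with pytest.raises(ValueError, match="constant"):
            z.scan_quant(g, pd.Series(1.0, index=g.index))


class TestTwoQtlAdditive:
    @staticmethod
    def _genotypes(n, rng, n_markers=4):
        return pd.DataFrame(
            {f"m{j}": np.where(rng.random(n) < 0.5, HET, HOM) for j in range(n_markers)},
            index=[f"o{i}" for i in range(n)],
        )

    def test_duplicate_peak_adds_nothing(self):
        rng = np.random.default_rng(0)
        g = self._genotypes(80, rng)
        g["dup"] = g["m0"]
        y = pd.Series(
            (g["m0"] == HET).astype(float) + rng.normal(0, 0.3, 80), index=g.index
        )
        single, _ = z.scan_quant(g, y)
        supported, pair, best = z.two_qtl_additive(g[["m0", "dup"]], y, single.peak_lod)
        assert not supported
        assert best - single.peak_lod < 1.0

    def test_two_qtl_trait_supported(self):
        rng = np.random.default_rng(1)
        g = self._genotypes(150, rng)
        y = pd.Series(
            (g["m0"] == HET).astype(float)
            + (g["m2"] == HET).astype(float)
            + rng.normal(0, 0.4, 150),
            index=g.index,
        )
        single, _ = z.scan_quant(g, y)
        supported, pair, _ = z.two_qtl_additive(g, y, single.peak_lod)
        assert supported
        assert set(pair) == {"m0", "m2"}

    def test_one_qtl_trait_rarely_supported(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = self._genotypes(100, rng)
            y = pd.Series(
                (g["m0"] == HET).astype(float) + rng.normal(0, 0.5, 100), index=g.index
            )
            single, _ = z.scan_quant(g, y)
            supported, *_ = z.two_qtl_additive(g, y, single.peak_lod)
            hits += supported
        assert hits <= 1  # >=95% of replicates reject the two-QTL model


class TestMaleFunctionRegion:
    # haplotype-indicator fixture on the published marker grid: the causal
    # locus lies between 37.428 and 37.708 Mb
    POSITIONS = pd.Series(
        {
            "a": 37_391_000,
            "b": 37_428_000,
            "c": 37_566_000,
            "d": 37_682_000,
            "e": 37_708_000,
            "f": 37_858_000,
        }
    )

    def _region(self, rows, trait):
        hap = pd.DataFrame(rows, columns=list("abcdef"), dtype=float)
        mf = pd.Series(trait, index=hap.index).astype(bool)
        return z.male_function_region(hap, mf, self.POSITIONS, group_id="VI-Av-m")

    def test_breakpoint_bounding_reproduces_280kb_interval(self):
        rows = [
            [0, 0, 1, 1, 1, 1],  # upstream recombinant, sterile: mismatch prefix to b
            [1, 1, 0, 0, 0, 0],  # upstream recombinant, fertile (mirror)
            [1, 1, 1, 1, 0, 0],  # downstream recombinant, sterile: mismatch from e
            [0, 0, 0, 0, 1, 1],  # downstream recombinant, fertile (mirror)
            [1, 1, 1, 1, 1, 1],  # non-recombinant W carrier
            [0, 0, 0, 0, 0, 0],  # non-recombinant ZZ
        ]
        trait = [True, False, True, False, True, False]
        region = self._region(rows, trait)
        assert (region.start_bp, region.end_bp) == (37_428_000, 37_708_000)
        assert region.width_bp == 280_000

    def test_no_informative_recombinants_spans_markers_and_flags(self):
        rows = [[1] * 6, [0] * 6]
        region = self._region(rows, [True, False])
        assert (region.start_bp, region.end_bp) == (37_391_000, 37_858_000)
        assert not region.bounded_lower and not region.bounded_upper

    def test_nonrecombinant_mismatch_does_not_move_bounds(self):
        rows = [
            [0, 0, 1, 1, 1, 1],
            [1, 1, 1, 1, 0, 0],
            [0, 0, 0, 0, 0, 0],  # sterile but ZZ genotype throughout: phenotype error
        ]
        trait = [True, True, True]
        region = self._region(rows, trait)
        assert (region.start_bp, region.end_bp) == (37_428_000, 37_708_000)
        assert region.evidence["nonrecombinant_mismatches"] == ["2"]

    def test_singleton_error_does_not_create_false_bound(self):
        rows = [
            [0, 0, 1, 1, 1, 1],
            [1, 1, 1, 1, 0, 0],
            [1, 1, 0, 1, 1, 1],  # W carrier with a lone genotyping error at c
        ]
        trait = [True, True, True]
        region = self._region(rows, trait)
        assert (region.start_bp, region.end_bp) == (37_428_000, 37_708_000)


class TestWilliamsT:
    def test_peak_against_itself(self):
        t, p = z.williams_t(0.8, 0.8, 1.0, 100)
        assert (t, p) == (0.0, 1.0)

    def test_equal_correlations_any_overlap(self):
        t, _ = z.williams_t(0.5, 0.5, 0.2, 50)
        assert t == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            z.williams_t(0.5, 0.4, 0.3, 3)

    def test_sign_follows_correlation_difference(self):
        t_pos, _ = z.williams_t(0.8, 0.5, 0.6, 60)
        t_neg, _ = z.williams_t(0.5, 0.8, 0.6, 60)
        assert t_pos > 0 > t_neg
        assert t_pos == pytest.approx(-t_neg)

    def test_agrees_with_bootstrap_on_fixture(self):
        """Williams' t p-value matches a 10^4-resample bootstrap comparison
        of the two dependent correlations within +-0.02."""
        rng = np.random.default_rng(7)
        n = 100
        w = rng.normal(size=n)
        x1 = w + rng.normal(0, 0.9, n)
        x2 = w + rng.normal(0, 1.3, n)
        y = w + rng.normal(0, 1.0, n)

        def corr(a, b):
            return np.corrcoef(a, b)[0, 1]

        r1, r2, r12 = corr(x1, y), corr(x2, y), corr(x1, x2)
        _, p = z.williams_t(r1, r2, r12, n)
        boots = np.empty(10_000)
        for i in range(10_000):
            idx = rng.integers(0, n, n)
            boots[i] = corr(x1[idx], y[idx]) - corr(x2[idx], y[idx])
        p_boot = 2 * min((boots <= 0).mean(), (boots >= 0).mean())
        assert p == pytest.approx(p_boot, abs=0.02)


class TestFemaleFunctionRegion:
    @staticmethod
    def _cross_slice(cross):
        cols = list(maternal_sex_markers(cross))
        mk = cross.markers
        lo, hi = cross.config.sdr_vicinity
        vic = [c for c in cols if lo <= mk.loc[c, "ref_pos_bp"] <= hi]
        g = cross.genotypes[vic]
        fert = cross.phenotypes["female_fertility"]
        pos = mk.loc[vic, "ref_pos_bp"]
        return g, fert, pos

    def test_region_contains_peak_and_widens_with_alpha(self, sex_cross):
        g, fert, pos = self._cross_slice(sex_cross)
        region_05, table = z.female_function_region(g, fert, pos, alpha=0.05)
        peak_pos = int(pos[table.index[table["p"] == 1.0][0]])
        assert region_05.start_bp <= peak_pos <= region_05.end_bp
        region_20, _ = z.female_function_region(g, fert, pos, alpha=0.20)
        # stricter alpha keeps more sites equivalent to the peak: the
        # alpha=0.05 region can never be narrower than the alpha=0.20 one
        assert region_05.start_bp <= region_20.start_bp
        assert region_05.end_bp >= region_20.end_bp

    def test_region_covers_true_sdr_locus(self, clean_sex_cross):
        """With accurate genotypes the correlation-equivalence region spans
        the causal locus; genotyping error makes the dependent-correlation
        test hypersensitive at large n, so the clean cross is the right
        setting for this check."""
        g, fert, pos = self._cross_slice(clean_sex_cross)
        region, _ = z.female_function_region(g, fert, pos)
        assert region.start_bp <= clean_sex_cross.truth.sdr_locus_bp <= region.end_bp

    def test_too_few_records_rejected(self, sex_cross):
        g, fert, pos = self._cross_slice(sex_cross)
        with pytest.raises(ValueError):
            z.female_function_region(g.iloc[:3], fert.iloc[:3], pos)


class TestConcordanceR2:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[23, 1], [0, 18]], 0.91),  # 42 offspring, one mismatching individual
            ([[20, 0], [0, 22]], 1.0),
            ([[10, 10], [10, 10]], 0.0),
        ],
    )
    def test_phi_squared(self, table, expected):
        assert round(z.concordance_r2(table), 2) == pytest.approx(expected)

    def test_equals_ols_r_squared_for_binary_pair(self):
        rng = np.random.default_rng(7)
        x = rng.integers(0, 2, 200)
        y = np.where(rng.random(200) < 0.8, x, 1 - x)
        table = pd.crosstab(x, y).to_numpy()
        r = np.corrcoef(x, y)[0, 1]
        assert z.concordance_r2(table) == pytest.approx(r * r)
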