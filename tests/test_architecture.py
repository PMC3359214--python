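import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rileqtl import architecture as arch
from rileqtl.types import EqtlRecord, GeneAnnotation, RileqtlError


def rec(trait="g1", chrom="1", peak_bp=5_000_000, inf=None, sup=None,
        add=-0.5, classification="unclassified"):
    inf = peak_bp if inf is None else inf
    sup = peak_bp if sup is None else sup
    return EqtlRecord(
        trait=trait, chrom=chrom, peak_cm=0.0, peak_bp=peak_bp,
        inf_bp=inf, sup_bp=sup, inf_cm=0.0, sup_cm=0.0,
        lod=3.0, add=add, rsq=0.1, classification=classification,
    )


def annot(**positions):
    df = pd.DataFrame(
        [(t, c, b, ".") for t, (c, b) in positions.items()],
        columns=["trait", "chrom", "bp", "strand"],
    ).set_index("trait")
    return GeneAnnotation(df)


class TestClassify:
    def test_peak_at_gene_is_local(self):
        rs = arch.classify_eqtls([rec()], annot(g1=("1", 5_000_000)))
        assert rs[0].classification == "local"

    def test_other_chromosome_is_distant(self):
        rs = arch.classify_eqtls([rec()], annot(g1=("2", 5_000_000)))
        assert rs[0].classification == "distant"

    def test_1mb_boundary(self):
        a = annot(g1=("1", 5_000_000))
        assert arch.classify_eqtls([rec(peak_bp=5_999_999)], a)[0].classification == "local"
        assert arch.classify_eqtls([rec(peak_bp=6_000_000)], a)[0].classification == "local"
        assert arch.classify_eqtls([rec(peak_bp=6_000_001)], a)[0].classification == "distant"

    def test_unannotated_trait_unclassified(self):
        rs = arch.classify_eqtls([rec(trait="gX")], annot(g1=("1", 1)))
        assert rs[0].classification == "unclassified"


class TestMakeBins:
    def test_short_remainder_merged(self):
        # 3.4 Mb: remainder 400 kb < 500 kb merges into the previous bin
        g = arch.make_bins({"1": 3_400_000})
        assert g.n_bins == 3
        assert tuple(g.bins.iloc[-1][["start", "end"]]) == (2_000_001, 3_400_000)

    def test_long_remainder_kept(self):
        g = arch.make_bins({"1": 3_600_000})
        assert g.n_bins == 4
        assert tuple(g.bins.iloc[-1][["start", "end"]]) == (3_000_001, 3_600_000)

    def test_bins_tile_without_gaps(self):
        g = arch.make_bins({"1": 30_400_000, "2": 19_700_000})
        for chrom, length in (("1", 30_400_000), ("2", 19_700_000)):
            sub = g.bins[g.bins["chrom"] == chrom]
            assert sub["start"].iloc[0] == 1
            assert sub["end"].iloc[-1] == length
            np.testing.assert_array_equal(
                sub["start"].to_numpy()[1:], sub["end"].to_numpy()[:-1] + 1
            )

    def test_chromosome_shorter_than_bin(self):
        g = arch.make_bins({"1": 700_000})
        assert g.n_bins == 1 and g.bins.iloc[0]["end"] == 700_000


def _distant(n, length=116_000_000, seed=0, concentrate_at=None):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        bp = concentrate_at if concentrate_at else int(rng.integers(1, length))
        out.append(rec(trait=f"t{i}", peak_bp=bp, classification="distant"))
    return out


class TestHotspots:
    def test_empty_input(self):
        grid = arch.make_bins({"1": 10_000_000})
        res = arch.hotspot_test([], grid, n_perm=200)
        assert not res.table["hotspot"].any()

    def test_extreme_concentration_flagged(self):
        grid = arch.make_bins({"1": 116_000_000})
        recs = _distant(500, concentrate_at=3_500_000)
        res = arch.hotspot_test(recs, grid, n_perm=500, seed=1)
        flagged = res.hotspot_bins
        assert len(flagged) == 1
        assert flagged.iloc[0]["start"] == 3_000_001

    def test_counts_conserved(self):
        grid = arch.make_bins({"1": 116_000_000})
        recs = _distant(777, seed=2)
        res = arch.hotspot_test(recs, grid, n_perm=200, seed=3)
        assert res.table["count"].sum() == 777

    def test_threshold_monotone_in_peak_count(self):
        grid = arch.make_bins({"1": 116_000_000})
        thr = [
            arch.hotspot_test(_distant(n, seed=4), grid, n_perm=300, seed=5).threshold
            for n in (500, 2145, 4868)
        ]
        assert thr[0] <= thr[1] <= thr[2]

    def test_threshold_near_poisson_max_approximation(self):
        # oracle: quantile of the max of B iid Poisson(n/B) counts
        n, B = 2145, 116
        grid = arch.make_bins({"1": B * 1_000_000})
        res = arch.hotspot_test(_distant(n, seed=6), grid, n_perm=1000, seed=7)
        lam = n / B
        ks = np.arange(0, 200)
        cdf = stats.poisson.cdf(ks, lam)
        analytic = int(ks[np.searchsorted(cdf**B, 0.95)])
        assert abs(res.threshold - analytic) <= 2

    def test_non_distant_rejected(self):
        grid = arch.make_bins({"1": 10_000_000})
        with pytest.raises(RileqtlError, match="non-distant"):
            arch.hotspot_test([rec(classification="local")], grid, n_perm=200)


class TestDensityRegression:
    def test_constant_counts(self):
        out = arch.density_regression(np.full(20, 3.0), np.arange(20.0))
        assert out["slope"] == pytest.approx(0.0)
        assert out["rsq"] == pytest.approx(0.0)

    def test_exact_linear_relation(self):
        genes = np.arange(1.0, 117.0)
        out = arch.density_regression(2 * genes, genes)
        assert out["slope"] == pytest.approx(2.0)
        assert out["rsq"] == pytest.approx(1.0)
        assert out["p"] < 1e-10

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        ps = [
            arch.density_regression(rng.poisson(5, 116).astype(float),
                                    rng.normal(size=116))["p"]
            for _ in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_covariate(self):
        with pytest.raises(RileqtlError, match="zero-variance"):
            arch.density_regression(np.arange(5.0), np.ones(5))


class TestComparePopulations:
    @staticmethod
    def _local(trait, inf, sup, add=0.5, chrom="1"):
        peak = (inf + sup) // 2
        return rec(trait=trait, chrom=chrom, peak_bp=peak, inf=inf, sup=sup,
                   add=add, classification="local")

    def test_identical_lists(self):
        a = [self._local(f"g{i}", 1_000_000 * i + 1, 1_000_000 * (i + 2), 0.1 * (i + 1))
             for i in range(5)]
        out = arch.compare_populations(a, a)
        assert out["n_shared"] == 5
        assert out["concordance"] == 1.0
        assert out["pearson_r"] == pytest.approx(1.0)

    def test_disjoint_traits(self):
        a = [self._local("g1", 1, 2_000_000)]
        b = [self._local("g2", 1, 2_000_000)]
        assert arch.compare_populations(a, b)["n_shared"] == 0

    def test_interval_overlap_rule(self):
        a = [self._local("g1", 1_000_000, 2_000_000)]
        b_overlap = [self._local("g1", 1_800_000, 2_500_000)]
        b_apart = [self._local("g1", 2_100_000, 2_500_000)]
        assert arch.compare_populations(a, b_overlap)["n_shared"] == 1
        assert arch.compare_populations(a, b_apart)["n_shared"] == 0

    def test_sign_discordance_counted(self):
        a = [self._local("g1", 1, 2_000_000, add=0.5),
             self._local("g2", 1, 2_000_000, add=0.5)]
        b = [self._local("g1", 1, 2_000_000, add=0.5),
             self._local("g2", 1, 2_000_000, add=-0.5)]
        out = arch.compare_populations(a, b)
        assert out["concordance"] == 0.5
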