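import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepkit import (
    dosage_r2,
    ld_decay,
    log2_pi_ratio,
    site_pi,
    tajimas_d,
    wc_fst_site,
    windowed_fst,
    windowed_pi,
    zscore,
)
from sweepkit.io_formats import MISSING, GenotypeMatrix, VariantRecord
from . import oracles
from .conftest import make_gm


class TestSitePi:
    @pytest.mark.parametrize(
        "j,n,expected",
        [(1, 2, 1.0), (0, 6, 0.0), (6, 6, 0.0), (2, 4, 2.0 / 3.0), (5, 10, 2 * 5 * 5 / 90)],
    )
    def test_spot_values(self, j, n, expected):
        assert site_pi(j, n) == pytest.approx(expected, abs=1e-12)

    def test_undefined_below_two_alleles(self):
        with pytest.raises(ValueError):
            site_pi(0, 1)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(n=st.integers(2, 200), j=st.integers(0, 200))
    def test_symmetric_and_maximal_at_half(self, n, j):
        j = min(j, n)
        assert site_pi(j, n) == pytest.approx(site_pi(n - j, n), abs=1e-15)
        assert site_pi(j, n) <= site_pi(n // 2, n) + 1e-15

    def test_matches_pair_enumeration(self):
        for n in (2, 5, 12):
            for j in range(n + 1):
                assert site_pi(j, n) == pytest.approx(oracles.site_pi_pairs(j, n), abs=1e-12)


class TestWindowedPi:
    def test_two_sites_in_10kb(self):
        """Site pi 1.0 and 0.5 in a 10 kb window -> 1.5e-4 per bp."""
        # 2 samples (n=4 alleles): j=2 -> 2/3? need exact 1.0 and 0.5:
        # j=1,n=2 gives 1.0; j=1,n=4 gives 0.5
        dosage = np.array([[1, 1], [MISSING, 0]], dtype=np.int16)
        gm = GenotypeMatrix(
            variants=[
                VariantRecord("chr1", 100, "A", ("C",)),
                VariantRecord("chr1", 200, "A", ("C",)),
            ],
            samples=["a", "b"],
            dosage=dosage,
        )
        import pandas as pd

        gm = gm.attach_metadata(
            pd.DataFrame({"population": ["P", "P"]}, index=pd.Index(["a", "b"], name="sample"))
        )
        assert windowed_pi(gm, "P", ("chr1", 1, 10_000)) == pytest.approx(1.5e-4, rel=1e-12)

    def test_empty_window_is_zero(self, rng):
        gm = make_gm(rng, n_variants=5, max_pos=1000)
        assert windowed_pi(gm, "popA", ("chr1", 5_000, 6_000)) == 0.0

    def test_matches_brute_force_on_fixture(self, rng):
        gm = make_gm(rng, n_samples=50, n_variants=500, missing_rate=0.1, max_pos=10**6)
        for window in [("chr1", 1, 10**6), ("chr1", 200_000, 400_000)]:
            for pop in ("popA", "popB"):
                assert windowed_pi(gm, pop, window) == pytest.approx(
                    oracles.window_pi_brute(gm, pop, window), abs=1e-15, rel=1e-12
                )


class TestWcFst:
    def test_fixed_difference_site(self):
        a, total = wc_fst_site(10, 1.0, 0.0, 10, 0.0, 0.0)
        assert a == pytest.approx(0.5, abs=1e-12)
        assert total == pytest.approx(0.5, abs=1e-12)
        assert a / total == pytest.approx(1.0, abs=1e-12)

    def test_identical_intermediate_site(self):
        a, total = wc_fst_site(10, 0.5, 0.5, 10, 0.5, 0.5)
        assert a == pytest.approx(-0.013889, abs=1e-6)
        assert total == pytest.approx(0.25, abs=1e-12)
        assert a / total == pytest.approx(-0.055556, abs=1e-6)

    def test_monomorphic_site_skipped(self):
        a, total = wc_fst_site(10, 0.0, 0.0, 10, 0.0, 0.0)
        # components are defined (0/0 handled at the window level)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_window_of_fixed_differences_is_one(self):
        dosage = np.array([[2, 2], [2, 2], [0, 0], [0, 0]], dtype=np.int16)
        gm = _two_pop_gm(dosage)
        assert windowed_fst(gm, "popA", "popB", ("chr1", 1, 1000)) == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self, rng):
        base = make_gm(rng, n_samples=10, n_variants=15, missing_rate=0, two_pops=False)
        dosage = np.vstack([base.dosage, base.dosage])
        gm = _two_pop_gm(dosage, variants=base.variants)
        got = windowed_fst(gm, "popA", "popB", ("chr1", 1, 10**6))
        brute = oracles.window_fst_brute(gm, "popA", "popB", ("chr1", 1, 10**6))
        assert got <= 1e-12
        assert got == pytest.approx(brute, abs=1e-12)

    def test_ratio_of_sums_not_mean_of_site_fst(self):
        # one fixed-difference site + one weakly differentiated site:
        # mean of site Fst differs from the ratio of summed components
        dosage = np.array(
            [[2, 1], [2, 1], [2, 0], [0, 1], [0, 0], [0, 1]], dtype=np.int16
        )
        gm = _two_pop_gm(dosage)
        comp = [
            oracles.wc_site_brute(
                [int(x) for x in dosage[:3, k]], [int(x) for x in dosage[3:, k]]
            )
            for k in range(2)
        ]
        ratio_of_sums = sum(c[0] for c in comp) / sum(c[1] for c in comp)
        mean_of_fst = np.mean([c[0] / c[1] for c in comp])
        got = windowed_fst(gm, "popA", "popB", ("chr1", 1, 1000))
        assert got == pytest.approx(ratio_of_sums, abs=1e-12)
        assert abs(got - mean_of_fst) > 1e-3

    def test_random_fixtures_match_brute_force(self):
        for seed in range(30):
            gm = make_gm(
                np.random.default_rng(seed), n_samples=20, n_variants=10, missing_rate=0.15
            )
            w = ("chr1", 1, 200_000)
            got = windowed_fst(gm, "popA", "popB", w)
            brute = oracles.window_fst_brute(gm, "popA", "popB", w)
            if np.isnan(brute):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(brute, abs=1e-12, rel=1e-12)


class TestTajimasD:
    def test_all_singletons_negative(self):
        gm = _counts_gm(js=[1] * 5, n_samples=5)
        d = tajimas_d(gm, "P", ("chr1", 1, 10_000))
        assert d < 0
        # frozen from an independent published implementation of the constants
        assert d == pytest.approx(-1.7410958652071464, abs=1e-10)

    def test_intermediate_frequencies_positive(self):
        gm = _counts_gm(js=[5] * 5, n_samples=5)
        assert tajimas_d(gm, "P", ("chr1", 1, 10_000)) > 0

    def test_no_segregating_sites_undefined(self):
        gm = _counts_gm(js=[0, 10], n_samples=5)
        assert np.isnan(tajimas_d(gm, "P", ("chr1", 1, 10_000)))

    def test_random_fixtures_match_brute_force(self):
        for seed in range(100):
            gm = make_gm(
                np.random.default_rng(seed), n_samples=12, n_variants=15, missing_rate=0.1
            )
            got = tajimas_d(gm, "popA", ("chr1", 1, 200_000))
            brute = oracles.window_tajd_brute(gm, "popA", ("chr1", 1, 200_000))
            if np.isnan(brute):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(brute, abs=1e-10, rel=1e-10)


class TestZscore:
    def test_simple(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1], atol=1e-12)

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="spread"):
            zscore([2.0, 2.0, 2.0])

    def test_mean_zero_unit_sd(self, rng):
        z = zscore(rng.normal(5, 3, size=500))
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1, abs=1e-12)

    def test_nan_passthrough(self):
        z = zscore([1.0, np.nan, 3.0])
        assert np.isnan(z[1])
        np.testing.assert_allclose(z[[0, 2]], [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12)


class TestLog2Ratio:
    @pytest.mark.parametrize("pa,pb,expected", [(0.002, 0.002, 0.0), (0.004, 0.001, 2.0)])
    def test_values(self, pa, pb, expected):
        assert log2_pi_ratio(pa, pb) == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_undefined(self):
        assert np.isnan(log2_pi_ratio(0.001, 0.0))
        assert np.isnan(log2_pi_ratio(0.0, 0.001))


class TestDosageR2:
    def test_identical_and_mirrored(self):
        assert dosage_r2([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)
        assert dosage_r2([0, 1, 2, 0], [2, 1, 0, 2]) == pytest.approx(1.0)

    def test_hand_example(self):
        # Pearson r = 2/sqrt(5.5) = 0.852803 -> r^2 = 8/11
        assert dosage_r2([0, 0, 1, 2], [0, 1, 1, 2]) == pytest.approx(8 / 11, abs=1e-9)

    def test_matches_scipy_on_random_pairs(self, rng):
        for _ in range(100):
            g1 = rng.integers(0, 3, size=30)
            g2 = rng.integers(0, 3, size=30)
            g1[rng.random(30) < 0.2] = MISSING
            g2[rng.random(30) < 0.2] = MISSING
            got, brute = dosage_r2(g1, g2), oracles.r2_brute(g1, g2)
            if np.isnan(brute):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(brute, abs=1e-10)

    def test_zero_variance_undefined(self):
        assert np.isnan(dosage_r2([1, 1, 1], [0, 1, 2]))


class TestLdDecay:
    def test_pair_binning(self, rng):
        gm = make_gm(rng, n_samples=30, n_variants=3, missing_rate=0)
        gm.variants[0] = gm.variants[0].__class__("chr1", 100, "A", ("C",))
        gm.variants[1] = gm.variants[1].__class__("chr1", 200, "A", ("C",))
        gm.variants[2] = gm.variants[2].__class__("chr1", 10_000, "A", ("C",))
        table = ld_decay(gm, max_dist=20_000, bin_width=1_000)
        assert table.loc[0, "n_pairs"] == 1  # (100,200), d=100
        assert table.loc[9, "n_pairs"] == 2  # d=9800, 9900
        assert table["n_pairs"].sum() == 3

    def test_single_snp_empty(self, rng):
        gm = make_gm(rng, n_variants=1)
        assert ld_decay(gm)["n_pairs"].sum() == 0

    def test_independent_loci_mean_r2_tracks_one_over_n(self):
        means = {}
        for n in (25, 100):
            rng = np.random.default_rng(99)
            gm = make_gm(rng, n_samples=n, n_variants=60, missing_rate=0, max_pos=50_000,
                         maf_range=(0.3, 0.7))
            t = ld_decay(gm, max_dist=50_000, bin_width=50_000)
            means[n] = float(t["mean_r2"].iloc[0])
        for n, m in means.items():
            assert abs(m - 1 / n) < 0.5 / n  # within 50% of the sampling expectation
        assert means[100] < means[25]


def _two_pop_gm(dosage, variants=None):
    import pandas as pd

    n, m = dosage.shape
    if variants is None:
        variants = [VariantRecord("chr1", 100 * (k + 1), "A", ("C",)) for k in range(m)]
    samples = [f"s{k}" for k in range(n)]
    half = n // 2
    meta = pd.DataFrame(
        {"population": ["popA"] * half + ["popB"] * (n - half)},
        index=pd.Index(samples, name="sample"),
    )
    return GenotypeMatrix(variants=variants, samples=samples, dosage=np.asarray(dosage, np.int16), sample_meta=meta)


def _counts_gm(js, n_samples):
    """One population of n_samples diploids; site k has exactly js[k] alt alleles."""
    import pandas as pd

    m = len(js)
    dosage = np.zeros((n_samples, m), dtype=np.int16)
    for k, j in enumerate(js):
        full, rem = divmod(j, 2)
        dosage[:full, k] = 2
        if rem:
            dosage[full, k] = 1
    variants = [VariantRecord("chr1", 10 * (k + 1), "A", ("C",)) for k in range(m)]
    samples = [f"s{k}" for k in range(n_samples)]
    meta = pd.DataFrame({"population": ["P"] * n_samples}, index=pd.Index(samples, name="sample"))
    return GenotypeMatrix(variants=variants, samples=samples, dosage=dosage, sample_meta=meta)
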