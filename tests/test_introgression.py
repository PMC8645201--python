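import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from introlens import (
    AlleleFreqMatrix,
    InsufficientSitesError,
    QuartetSimConfig,
    analyze_triad,
    bootstrap_z,
    d_statistic,
    polarize_to_derived,
    select_informative_sites,
    sim_quartet_freqs,
    site_pattern_weights,
)
from introlens.introgression import read_freq_tsv, read_triad_vcf, z_to_pvalue


def matrix(freq_rows, loci=None):
    rows = np.atleast_2d(np.asarray(freq_rows, float))
    n = len(rows)
    loci = np.asarray(loci if loci is not None else [f"L{i}" for i in range(n)])
    return AlleleFreqMatrix(rows, loci, np.arange(n))


class TestPolarize:
    def test_fixed_difference(self):
        m, counters = polarize_to_derived(
            alt_counts=[[0, 2, 2, 0]], called_alleles=[[2, 2, 2, 2]],
            locus_ids=["L1"], positions=[0],
        )
        assert m.freqs.tolist() == [[0.0, 1.0, 1.0, 0.0]]
        assert counters["n_used"] == 1

    def test_heterozygote_gives_half(self):
        m, _ = polarize_to_derived([[0, 1, 0, 0]], [[2, 2, 2, 2]], ["L1"], [0])
        assert m.freqs[0, 1] == pytest.approx(0.5)

    def test_outgroup_fixed_alt_flips_polarity(self):
        # alt is ancestral when the outgroup is fixed for it
        m, _ = polarize_to_derived([[2, 0, 0, 2]], [[2, 2, 2, 2]], ["L1"], [0])
        assert m.freqs.tolist() == [[0.0, 1.0, 1.0, 0.0]]

    def test_outgroup_tie_excluded(self):
        with pytest.raises(ValueError, match="all sites excluded"):
            polarize_to_derived([[0, 2, 2, 1]], [[2, 2, 2, 2]], ["L1"], [0])

    def test_missing_taxon_excluded(self):
        m, counters = polarize_to_derived(
            [[0, 2, 2, 0], [0, 2, 2, 0]], [[2, 0, 2, 2], [2, 2, 2, 2]],
            ["L1", "L2"], [0, 1],
        )
        assert counters["n_missing_taxon"] == 1 and m.n_sites == 1


class TestSitePatternWeights:
    @pytest.mark.parametrize(
        "freqs,expected",
        [
            ((0, 1, 1, 0), (1.0, 0.0)),  # canonical ABBA
            ((1, 0, 1, 0), (0.0, 1.0)),  # canonical BABA
            ((0.5, 0.5, 0.5, 0), (0.125, 0.125)),
            ((0, 0, 0, 0), (0.0, 0.0)),
        ],
    )
    def test_closed_forms(self, freqs, expected):
        abba, baba = site_pattern_weights(np.array([freqs]))
        assert (abba[0], baba[0]) == pytest.approx(expected)


class TestSelectInformative:
    def test_all_canonical_abba_retained(self):
        m = matrix([[0, 1, 1, 0]] * 4)
        assert select_informative_sites(m, None).n_sites == 4

    def test_weightless_sites_excluded(self):
        m = matrix([[0, 1, 1, 0], [0, 0, 0, 0], [1, 1, 1, 1]])
        assert select_informative_sites(m, None).n_sites == 1

    def test_subsample_reproducible(self):
        rng = np.random.default_rng(0)
        freqs = np.column_stack([
            rng.uniform(0, 1, 1000), rng.uniform(0, 1, 1000),
            rng.uniform(0.1, 1, 1000), np.zeros(1000),
        ])
        m = matrix(freqs, loci=[f"L{i % 50}" for i in range(1000)])
        a = select_informative_sites(m, 250, seed=42)
        b = select_informative_sites(m, 250, seed=42)
        assert a.n_sites == 250
        assert np.array_equal(a.freqs, b.freqs)
        assert np.array_equal(a.locus_ids, b.locus_ids)

    def test_insufficient_sites_signalled(self):
        with pytest.raises(InsufficientSitesError):
            select_informative_sites(matrix([[0, 1, 1, 0]]), 5)


class TestDStatistic:
    def test_symmetric_totals_give_zero(self):
        m = matrix([[0, 1, 1, 0], [1, 0, 1, 0]])
        assert d_statistic(m) == pytest.approx(0.0)

    def test_all_abba_attains_bound(self):
        assert d_statistic(matrix([[0, 1, 1, 0]] * 3)) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # sum(abba)=0.6, sum(baba)=0.4 -> D = 0.2
        m = matrix([[0, 0.6, 1, 0], [1, 0, 0.4, 0]])
        abba, baba = site_pattern_weights(m.freqs)
        assert abba.sum() == pytest.approx(0.6) and baba.sum() == pytest.approx(0.4)
        assert d_statistic(m) == pytest.approx(0.2)

    def test_no_weight_is_nan(self):
        assert math.isnan(d_statistic(matrix([[0, 0, 0, 0]])))

    @given(
        hnp.arrays(
            float, hnp.array_shapes(min_dims=2, max_dims=2, min_side=1, max_side=30)
            .map(lambda s: (s[0], 4)),
            elements=st.floats(0, 1),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_antisymmetry(self, freqs):
        m = matrix(freqs)
        d = d_statistic(m)
        swapped = d_statistic(matrix(freqs[:, [1, 0, 2, 3]]))
        if math.isnan(d):
            assert math.isnan(swapped)
        else:
            assert -1.0 <= d <= 1.0
            assert swapped == pytest.approx(-d, abs=1e-12)


class TestBootstrap:
    def test_fig1_z_to_p(self):
        # Z = 3.895 must reproduce the printed two-sided p = 9.81e-5
        assert z_to_pvalue(3.895) == pytest.approx(9.81e-5, rel=5e-3)

    def test_z_zero_p_one(self):
        assert z_to_pvalue(0.0) == pytest.approx(1.0)

    def test_two_locus_exhaustive_enumeration(self):
        # loci A: one ABBA site; B: one ABBA + one BABA site
        m = matrix(
            [[0, 1, 1, 0], [0, 1, 1, 0], [1, 0, 1, 0]],
            loci=["A", "B", "B"],
        )
        per_locus = {"A": (1.0, 0.0), "B": (1.0, 1.0)}
        reps = []
        for draw in itertools.product("AB", repeat=2):
            a = sum(per_locus[l][0] for l in draw)
            b = sum(per_locus[l][1] for l in draw)
            reps.append((a - b) / (a + b))
        exact_sd = np.std(reps)  # 4 equiprobable resamples
        res = bootstrap_z(m, n_boot=10_000, seed=1)
        assert res.sd_boot == pytest.approx(exact_sd, rel=0.05)

    def test_single_locus_rejected(self):
        with pytest.raises(ValueError, match="one locus"):
            bootstrap_z(matrix([[0, 1, 1, 0]] * 3, loci=["A"] * 3))

    def test_identical_replicates_flagged(self):
        # both loci identical -> every resample gives D = 1, sd = 0
        m = matrix([[0, 1, 1, 0], [0, 1, 1, 0]], loci=["A", "B"])
        res = bootstrap_z(m, n_boot=50, seed=0)
        assert res.sd_boot == 0.0 and math.isnan(res.z) and math.isnan(res.p)

    def test_significance_coding(self):
        m = matrix([[0, 1, 1, 0]] * 40 + [[1, 0, 1, 0]] * 10,
                   loci=[f"L{i}" for i in range(50)])
        res = bootstrap_z(m, n_boot=200, seed=3)
        assert res.z > 0 and res.significant == (res.p < 0.05)


class TestAnalyzeTriad:
    def test_antisymmetric_under_p1_p2_swap(self):
        cfg = QuartetSimConfig(gamma=0.3, n_loci=200, seed=5)
        m = sim_quartet_freqs(cfg)
        res = analyze_triad("t", m, None, seed=9)
        swapped = AlleleFreqMatrix(m.freqs[:, [1, 0, 2, 3]], m.locus_ids, m.positions)
        res_sw = analyze_triad("t", swapped, None, seed=9)
        assert res_sw.d == pytest.approx(-res.d, abs=1e-12)

    def test_msc_symmetry_and_admixture_direction(self):
        null = analyze_triad(
            "null", sim_quartet_freqs(QuartetSimConfig(gamma=0.0, n_loci=2000, seed=21)),
            None, seed=1,
        )
        assert abs(null.d) <= 3 * null.sd_boot  # consistent with E[D] = 0
        admixed = analyze_triad(
            "adm", sim_quartet_freqs(QuartetSimConfig(gamma=0.3, n_loci=2000, seed=22)),
            None, seed=1,
        )
        assert admixed.d > 0 and admixed.significant

    def test_records_bookkeeping(self):
        m = sim_quartet_freqs(QuartetSimConfig(gamma=0.0, n_loci=500, seed=2))
        res = analyze_triad("T9", m, 100, seed=77, n_boot=50)
        assert res.triad_id == "T9"
        assert res.n_sites_used == 100
        assert res.subsample_size == 100 and res.seed == 77


class TestIO:
    def test_freq_tsv_roundtrip(self, tmp_path):
        m = sim_quartet_freqs(QuartetSimConfig(n_loci=50, seed=4))
        p = tmp_path / "m.tsv"
        m.to_tsv(str(p))
        back = read_freq_tsv(str(p))
        assert np.allclose(back.freqs, m.freqs)
        assert list(back.locus_ids) == list(m.locus_ids)

    def test_vcf_polarization(self, tmp_path):
        vcf = """##fileformat=VCFv4.2
##contig=<ID=loc1>
##contig=<ID=loc2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4
loc1\t5\t.\tA\tG\t50\tPASS\t.\tGT\t0/0\t1/1\t1/1\t0/0
loc1\t9\t.\tC\tT\t50\tPASS\t.\tGT\t0/1\t0/0\t1/1\t0/0
loc2\t3\t.\tG\tA\t50\tPASS\t.\tGT\t1/1\t0/0\t0/0\t1/1
loc2\t7\t.\tG\tGA\t50\tPASS\t.\tGT\t0/0\t1/1\t0/0\t0/0
loc2\t8\t.\tT\tC\t50\tPASS\t.\tGT\t0/0\t0/1\t0/0\t0/1
"""
        path = tmp_path / "triad.vcf"
        path.write_text(vcf)
        m, counters = read_triad_vcf(
            str(path), {"p1": "s1", "p2": "s2", "p3": "s3", "out": "s4"}
        )
        assert counters["n_not_snp"] == 1  # the indel
        assert counters["n_outgroup_tie"] == 1  # the 0/1 outgroup site
        assert m.n_sites == 3
        # site loc2:3 is polarized against the alt-fixed outgroup
        assert m.freqs[2].tolist() == [0.0, 1.0, 1.0, 0.0]
        assert m.freqs[1].tolist() == [0.5, 0.0, 1.0, 0.0]
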