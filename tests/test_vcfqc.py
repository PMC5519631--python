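"""QC cascade: normalization, genotype/site filters, Mendel masking, HWE."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from founderpanel import vcfqc as qc
from founderpanel.core import GenotypeMatrix, Individual, Pedigree, Sites
from conftest import make_gm, make_sites, trio_pedigree


class TestNormalize:
    def _gm(self, chrom, pos, ref, alt):
        n = len(pos)
        sites = Sites(np.array(chrom, dtype=object), np.array(pos),
                      np.array(ref, dtype=object), np.array(alt, dtype=object),
                      np.zeros(n))
        return make_gm(np.ones((2, n), dtype=int), sites=sites)

    def test_multiallelic_dropped(self):
        gm = self._gm(["1", "1"], [100, 200], ["A", "C"], ["A,T", "G"])
        out, counts = qc.normalize_and_restrict(gm)
        assert counts["multiallelic"] == 1
        assert out.n_sites == 1 and out.sites.pos[0] == 200

    def test_non_autosomal_dropped(self):
        gm = self._gm(["X", "1", "chrX", "MT"], [1, 2, 3, 4],
                      ["A"] * 4, ["G"] * 4)
        out, counts = qc.normalize_and_restrict(gm)
        assert counts["non_autosomal"] == 3
        assert out.n_sites == 1

    def test_trim_example(self):
        # "pos 100 REF CA ALT CT" -> "pos 101 REF A ALT T"
        gm = self._gm(["1"], [100], ["CA"], ["CT"])
        out, _ = qc.normalize_and_restrict(gm)
        assert (out.sites.pos[0], out.sites.ref[0], out.sites.alt[0]) == \
            (101, "A", "T")

    def test_trim_exhaustive_small_strings(self):
        # oracle: independent exhaustive trim over all <=3-mers of {A,C}
        def oracle(pos, ref, alt):
            while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
                ref, alt = ref[:-1], alt[:-1]
            while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
                ref, alt, pos = ref[1:], alt[1:], pos + 1
            return pos, ref, alt
        mers = ["".join(t) for k in (1, 2, 3)
                for t in itertools.product("AC", repeat=k)]
        for ref in mers:
            for alt in mers:
                if ref == alt:
                    continue
                assert qc._trim_variant(50, ref, alt) == oracle(50, ref, alt)

    def test_duplicates_collapsed(self):
        gm = self._gm(["1", "1"], [100, 100], ["A", "A"], ["G", "G"])
        out, counts = qc.normalize_and_restrict(gm)
        assert counts["duplicate"] == 1 and out.n_sites == 1


class TestGenotypeFilters:
    def test_low_gq_het_set_missing(self):
        gm = make_gm([[1]], gq=19)
        out, counts = qc.filter_genotypes(gm)
        assert out.fully_missing().all() and counts["low_gq"] == 1

    def test_hom_alt_ab_zero_retained(self):
        gm = make_gm([[2]], gq=60, dp=30)
        gm.ad_alt[:] = 0  # AB = 0.0 but the rule applies to hets only
        gm.ad_ref[:] = 30
        out, _ = qc.filter_genotypes(gm)
        assert out.called().all()

    def test_dp_8_retained_dp_7_removed(self):
        gm = make_gm([[1, 1]])
        gm.dp[0] = [8, 7]
        gm.ad_alt[0] = [4, 3]
        gm.ad_ref[0] = [4, 4]
        out, counts = qc.filter_genotypes(gm)
        assert out.called()[0, 0] and not out.called()[0, 1]

    def test_het_ab_boundaries(self):
        gm = make_gm([[1, 1, 1, 1]], dp=100)
        gm.ad_alt[0] = [25, 24, 75, 76]
        gm.ad_ref[0] = [75, 76, 25, 24]
        out, _ = qc.filter_genotypes(gm)
        # 0.25 and 0.75 inclusive survive; outside strictly is removed
        assert list(out.called()[0]) == [True, False, True, False]

    def test_half_calls_removed(self):
        gm = make_gm([[1]])
        gm.a2[0, 0] = -1
        out, counts = qc.filter_genotypes(gm)
        assert counts["half_calls"] == 1 and out.fully_missing().all()

    def test_missing_field_passes_rule(self):
        gm = make_gm([[1]])
        gm.gq[:] = -1  # GQ absent: the GQ rule passes
        out, counts = qc.filter_genotypes(gm)
        assert out.called().all()
        assert counts["missing_quality_fields"] == 1


class TestMendel:
    def test_impossible_trio_masked(self):
        gm = make_gm([[0], [0], [1]], samples=["FATHER", "MOTHER", "CHILD"])
        out, rates, counts = qc.mendel_mask(gm, trio_pedigree())
        assert out.fully_missing().all()
        assert rates[0] == 1.0 and counts["trio_errors"] == 1

    def test_forced_het_retained(self):
        gm = make_gm([[0], [2], [1]], samples=["FATHER", "MOTHER", "CHILD"])
        out, rates, _ = qc.mendel_mask(gm, trio_pedigree())
        assert out.called().all() and rates[0] == 0.0

    def test_duo_inconsistency_masked(self):
        ped = Pedigree([Individual("P", None, None, 1),
                        Individual("C", "P", None, 2)])
        gm = make_gm([[2], [0]], samples=["P", "C"])
        out, _, counts = qc.mendel_mask(gm, ped)
        assert out.fully_missing().all() and counts["duo_errors"] == 1

    def test_full_trio_table_against_enumeration(self):
        # oracle: child must receive one allele from each parent
        def possible(f, m, c):
            fa = {0: {0}, 1: {0, 1}, 2: {1}}[f]
            ma = {0: {0}, 1: {0, 1}, 2: {1}}[m]
            return any(a + b == c for a in fa for b in ma)
        for f in range(3):
            for m in range(3):
                for c in range(3):
                    got = bool(qc.trio_inconsistent(
                        np.array([float(f)]), np.array([float(m)]),
                        np.array([float(c)]))[0])
                    assert got == (not possible(f, m, c)), (f, m, c)

    def test_full_duo_table_against_enumeration(self):
        def possible(p, c):
            pa = {0: {0}, 1: {0, 1}, 2: {1}}[p]
            return any(a + b == c for a in pa for b in (0, 1))
        for p in range(3):
            for c in range(3):
                got = bool(qc.duo_inconsistent(np.array([float(p)]),
                                               np.array([float(c)]))[0])
                assert got == (not possible(p, c)), (p, c)

    def test_missing_member_not_flagged(self):
        gm = make_gm([[-1], [0], [2]], samples=["FATHER", "MOTHER", "CHILD"])
        out, rates, _ = qc.mendel_mask(gm, trio_pedigree())
        assert out.called()[1:].all() and rates[0] == 0.0


class TestHwe:
    def test_monomorphic_p_one(self):
        assert qc.hwe_exact(50, 0, 0) == 1.0

    def test_25_50_25_matches_enumeration(self):
        assert qc.hwe_exact(25, 50, 25) == pytest.approx(
            qc.hwe_exact_oracle(25, 50, 25), abs=1e-12)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            qc.hwe_exact(0, 0, 0)

    def test_extreme_het_deficit_small_p(self):
        assert qc.hwe_exact(50, 0, 50) < 1e-20

    def test_oracle_equivalence_spot(self):
        for nAA, nAa, naa in [(1, 0, 0), (0, 1, 0), (3, 5, 2), (90, 5, 5),
                              (10, 80, 10), (40, 20, 40), (0, 100, 0)]:
            assert qc.hwe_exact(nAA, nAa, naa) == pytest.approx(
                qc.hwe_exact_oracle(nAA, nAa, naa), abs=1e-12)

    def test_uniformity_under_null(self):
        rng = np.random.default_rng(5)
        n, p_freq, reps = 100, 0.3, 500
        rejected = 0
        for _ in range(reps):
            g = rng.binomial(2, p_freq, size=n)
            if qc.hwe_exact(int((g == 0).sum()), int((g == 1).sum()),
                            int((g == 2).sum())) < 0.05:
                rejected += 1
        assert rejected / reps <= 0.06

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=200, deadline=None)
    def test_p_in_unit_interval(self, a, b, c):
        if a + b + c == 0:
            return
        p = qc.hwe_exact(a, b, c)
        assert 0.0 < p <= 1.0


class TestSiteFilters:
    def test_engineered_ten_site_fixture(self):
        from conftest import engineered_qc_fixture
        gm, ped = engineered_qc_fixture()
        hwe_p = qc.hwe_pvalues(gm)
        assert hwe_p[5] < 1e-6
        _, mendel_rates, _ = qc.mendel_mask(gm, ped)
        masked, _, _ = qc.mendel_mask(gm, ped)
        out, report = qc.filter_sites(masked, mendel_rates)
        assert report.site_filters["dropped"] == 7
        assert out.n_sites == 3
        assert [int(p) for p in out.sites.pos] == \
            [int(gm.sites.pos[j]) for j in (7, 8, 9)]

    def test_missing_rate_boundary(self):
        # 100 samples, 26 missing -> dropped; 25 missing -> kept
        d = np.ones((100, 2), dtype=int)
        d[:, 0] = [0, 1] * 50
        d[:, 1] = [0, 1] * 50
        d[:26, 0] = -1
        d[:25, 1] = -1
        gm = make_gm(d)
        out, report = qc.filter_sites(gm)
        assert out.n_sites == 1 and report.site_filters["missing_rate"] == 1

    def test_monomorphic_after_masking_dropped(self):
        d = np.zeros((10, 1), dtype=int)
        gm = make_gm(d)
        out, report = qc.filter_sites(gm)
        assert out.n_sites == 0 and report.site_filters["monomorphic"] == 1


class TestCascade:
    def test_idempotent(self, sim_bundle):
        from founderpanel import simpop as sp
        _, gm, ped, _ = sim_bundle
        noisy, _ = sp.inject_noise(gm, sp.NoiseConfig(
            frac_low_gq=0.02, frac_half_calls=0.01,
            frac_mendel_errors=0.005), seed=3, ped=ped)
        once, r1 = qc.run_qc(noisy, ped)
        twice, r2 = qc.run_qc(once, ped)
        assert np.array_equal(once.a1, twice.a1)
        assert np.array_equal(once.a2, twice.a2)
        assert once.n_sites == twice.n_sites

    def test_monotone_only_to_missing(self, sim_bundle):
        from founderpanel import simpop as sp
        _, gm, ped, _ = sim_bundle
        noisy, _ = sp.inject_noise(gm, sp.NoiseConfig(frac_low_gq=0.05),
                                   seed=4, ped=ped)
        clean, _ = qc.run_qc(noisy, ped)
        keys = {k: j for j, k in enumerate(noisy.sites.locus_keys())}
        cols = np.array([keys[k] for k in clean.sites.locus_keys()])
        before1, before2 = noisy.a1[:, cols], noisy.a2[:, cols]
        changed = (clean.a1 != before1) | (clean.a2 != before2)
        assert (clean.fully_missing() | ~changed).all()

    def test_clean_hwe_sim_survival(self, sim_bundle):
        # random-mating ancestral cohort, no noise: >=99% of segregating
        # sites survive default thresholds
        anc, _, _, _ = sim_bundle
        gm = anc.to_genotypes()
        gm.gq[:] = 60
        gm.dp[:] = 30
        gm.ad_alt = np.where(gm.a1 + gm.a2 == 1, 15,
                             np.where(gm.a1 + gm.a2 == 2, 30, 0)).astype(np.int16)
        gm.ad_ref = (30 - gm.ad_alt).astype(np.int16)
        gm.phased[:] = False
        seg = np.flatnonzero(gm.segregating())
        out, _ = qc.run_qc(gm.take_sites(seg))
        assert out.n_sites >= 0.99 * seg.size


class TestConcordance:
    def test_identical_duplicates(self, sim_bundle):
        _, gm, _, _ = sim_bundle
        dup = gm.take_samples(gm.samples[:2])
        dup.a1[1] = dup.a1[0]
        dup.a2[1] = dup.a2[0]
        res = qc.concordance(dup, [(dup.samples[0], dup.samples[1])])
        assert res["snv"]["rate"] == 1.0

    def test_one_disagreement_in_thousand(self):
        d = np.ones((2, 1000), dtype=int)
        d[1, 0] = 2
        gm = make_gm(d)
        res = qc.concordance(gm, [("S000", "S001")])
        assert res["snv"]["rate"] == pytest.approx(0.999)

    def test_missing_excluded_from_denominator(self):
        d = np.ones((2, 10), dtype=int)
        d[0, :5] = -1
        gm = make_gm(d)
        res = qc.concordance(gm, [("S000", "S001")])
        assert res["snv"]["n_compared"] == 5

    def test_unknown_sample_errors(self, sim_bundle):
        _, gm, _, _ = sim_bundle
        with pytest.raises(Exception):
            qc.concordance(gm, [("nope", gm.samples[0])])


class TestSensitivity:
    def _pair(self, sim_bundle, drop_frac=0.0, seed=0):
        anc, _, _, _ = sim_bundle
        wgs = anc.to_genotypes()
        seg = np.flatnonzero(wgs.segregating())
        wgs = wgs.take_sites(seg)
        array = wgs.copy()
        if drop_frac:
            rng = np.random.default_rng(seed)
            keep = rng.random(wgs.n_sites) > drop_frac
            wgs = wgs.take_sites(np.flatnonzero(keep))
        return wgs, array

    def test_superset_gives_full_sensitivity(self, sim_bundle):
        wgs, array = self._pair(sim_bundle)
        res = qc.sensitivity_by_maf(wgs, array, bins=[0.01, 0.05, 0.2, 0.5])
        for row in res:
            if row["n_sites"]:
                assert row["sensitivity"] == 1.0

    def test_high_missing_rate_excluded(self, sim_bundle):
        wgs, array = self._pair(sim_bundle)
        array = array.copy()
        array.a1[: int(0.06 * array.n_samples) + 1, 0] = -1
        array.a2[: int(0.06 * array.n_samples) + 1, 0] = -1
        res = qc.sensitivity_by_maf(wgs, array, bins=[0.5])
        assert res[0]["n_sites"] == array.n_sites - 1

    def test_two_percent_dropout_flat_profile(self, sim_bundle):
        wgs, array = self._pair(sim_bundle, drop_frac=0.02, seed=1)
        res = qc.sensitivity_by_maf(wgs, array, bins=[0.05, 0.2, 0.5])
        sens = [r["sensitivity"] for r in res if r["n_sites"] >= 30]
        assert all(0.93 <= s <= 1.0 for s in sens)
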