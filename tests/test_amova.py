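"""Nested AMOVA: distances, SSD partition, components, Phi, permutation tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pollenflow as pf
from pollenflow.amova import (DegenerateDesignError, design_coefficients,
                              pd_unique)

from conftest import make_haplotypes


def nested_anova_oracle(codes, sites, mothers):
    """Independent route: centroid-based nested ANOVA on one-hot allele
    indicators scaled by 1/sqrt(2), so squared Euclidean distance equals
    the locus-mismatch count (Gower identity).  Requires no missing data."""
    assert (codes >= 0).all()
    N, L = codes.shape
    cols = []
    for j in range(L):
        k = codes[:, j].max() + 1
        oh = np.zeros((N, k))
        oh[np.arange(N), codes[:, j]] = 1.0
        cols.append(oh / np.sqrt(2))
    X = np.hstack(cols)
    gm = X.mean(0)
    sst = ((X - gm) ** 2).sum()
    ssw = sum(
        ((X[mothers == m] - X[mothers == m].mean(0)) ** 2).sum()
        for m in set(mothers)
    )
    ss_sites = sum(
        (sites == g).sum() * ((X[sites == g].mean(0) - gm) ** 2).sum()
        for g in set(sites)
    )
    return ss_sites, sst - ssw - ss_sites, ssw, sst


def random_design(rng, n_sites=5, mothers_per_site=(2, 5), gametes=(2, 6),
                  n_loci=4, n_alleles=3, missing_rate=0.0):
    sites, mothers, rows = [], [], []
    for g in range(n_sites):
        for k in range(rng.integers(*mothers_per_site)):
            for _ in range(rng.integers(*gametes)):
                sites.append(f"s{g}")
                mothers.append(f"s{g}m{k}")
                row = rng.integers(0, n_alleles, n_loci)
                mask = rng.random(n_loci) < missing_rate
                rows.append(np.where(mask, -1, row))
    return np.array(rows), np.array(sites, dtype=object), np.array(mothers, dtype=object)


class TestDistance:
    def test_identical_and_counting(self, toy_haplotypes):
        h = toy_haplotypes
        assert pf.amova_distance(h[0], h[0], ["L"]) == 0
        assert pf.amova_distance(h[0], h[2], ["L"]) == 1

    def test_differing_at_3_of_11_loci(self):
        loci = [f"L{i}" for i in range(11)]
        a = pf.PollenHaplotype("s", "m", "f", "1",
                               {l: "1" for l in loci}, {l: "unambiguous" for l in loci})
        b_alleles = {l: ("2" if i < 3 else "1") for i, l in enumerate(loci)}
        b = pf.PollenHaplotype("s", "m", "f", "2", b_alleles,
                               {l: "unambiguous" for l in loci})
        assert pf.amova_distance(a, b, loci) == 3

    def test_matrix_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        codes, sites, mothers = random_design(rng, missing_rate=0.15)
        haps = make_haplotypes(codes, sites, mothers, codes.shape[1])
        loci = [f"L{j}" for j in range(codes.shape[1])]
        D = pf.distance_matrix(codes)
        for i in range(0, len(haps), 7):
            for j in range(0, len(haps), 5):
                expected = pf.amova_distance(haps[i], haps[j], loci)
                if np.isnan(expected):
                    expected = 0.0  # matrix counts non-shared pairs as 0
                assert D[i, j] == expected

    def test_zero_shared_loci_flagged_nan(self):
        loci = ["L0", "L1"]
        a = pf.PollenHaplotype("s", "m", "f", "1", {"L0": "1", "L1": None},
                               {"L0": "unambiguous", "L1": "missing"})
        b = pf.PollenHaplotype("s", "m", "f", "2", {"L0": None, "L1": "1"},
                               {"L0": "missing", "L1": "unambiguous"})
        assert np.isnan(pf.amova_distance(a, b, loci))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10**6))
def test_distance_matrix_is_a_semimetric(seed):
    """Symmetric, non-negative, zero diagonal, for any design incl. missing."""
    rng = np.random.default_rng(seed)
    codes, _, _ = random_design(rng, missing_rate=0.2)
    D = pf.distance_matrix(codes)
    assert (D >= 0).all()
    assert np.array_equal(D, D.T)
    assert np.all(np.diag(D) == 0)


class TestToyAmova:
    """Hand-computed 2x2x2 single-locus example."""

    def test_ssd_partition_and_df(self, toy_haplotypes):
        codes, sites, mothers = pf.encode_haplotypes(toy_haplotypes, ["L"])
        D = pf.distance_matrix(codes)
        ssd = pf.ssd_partition(D, sites, mothers)
        assert ssd["ssd_total"] == pytest.approx(2.0)
        assert ssd["ssd_within_mothers"] == pytest.approx(0.0)
        assert ssd["ssd_among_mothers"] == pytest.approx(2.0)
        assert ssd["ssd_among_sites"] == pytest.approx(0.0)
        assert (ssd["df_among_sites"], ssd["df_among_mothers"],
                ssd["df_within_mothers"]) == (1, 2, 4)

    def test_components_and_phi(self, toy_haplotypes):
        codes, sites, mothers = pf.encode_haplotypes(toy_haplotypes, ["L"])
        D = pf.distance_matrix(codes)
        res = pf.amova(D, sites, mothers)
        assert (res.n_prime, res.n_double_prime, res.n_triple_prime) == (2, 2, 4)
        assert res.sigma2_c == pytest.approx(0.0)
        assert res.sigma2_b == pytest.approx(0.5)
        assert res.sigma2_a == pytest.approx(-0.25)
        assert res.phi_sc == pytest.approx(1.0)
        assert res.phi_ct == pytest.approx(-1.0)  # negatives reported, not truncated
        assert res.negative_component

    def test_all_identical_haplotypes(self):
        codes = np.zeros((8, 2), dtype=np.int64)
        sites = np.repeat(["a", "b"], 4)
        mothers = np.repeat(["a1", "a2", "b1", "b2"], 2)
        D = pf.distance_matrix(codes)
        ssd = pf.ssd_partition(D, sites, mothers)
        assert ssd["ssd_total"] == 0.0
        res = pf.amova(D, sites, mothers)
        assert res.zero_total_variance
        assert np.isnan(res.phi_ct)


class TestAgainstOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_unbalanced_ssd_matches_centroid_route(self, seed):
        rng = np.random.default_rng(seed)
        codes, sites, mothers = random_design(rng)
        D = pf.distance_matrix(codes)
        ssd = pf.ssd_partition(D, sites, mothers)
        a, b, w, tot = nested_anova_oracle(codes, sites, mothers)
        assert ssd["ssd_among_sites"] == pytest.approx(a, abs=1e-9)
        assert ssd["ssd_among_mothers"] == pytest.approx(b, abs=1e-9)
        assert ssd["ssd_within_mothers"] == pytest.approx(w, abs=1e-9)
        assert ssd["ssd_total"] == pytest.approx(tot, abs=1e-9)

    def test_balanced_moment_identities(self):
        """E[MSD_w] = s_c, E[MSD_b] = s_c + n'*s_b, E[MSD_a] = s_c + n''*s_b
        + n'''*s_a: with haplotypes iid across mothers (no differentiation)
        mean estimated s_a, s_b should center on 0."""
        rng = np.random.default_rng(12)
        s_a_hat, s_b_hat = [], []
        for _ in range(300):
            codes, sites, mothers = random_design(
                rng, n_sites=4, mothers_per_site=(3, 4), gametes=(4, 5), n_loci=3
            )
            D = pf.distance_matrix(codes)
            res = pf.amova(D, sites, mothers)
            s_a_hat.append(res.sigma2_a)
            s_b_hat.append(res.sigma2_b)
        for vals in (s_a_hat, s_b_hat):
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals)) < 4 * se + 1e-3

    def test_single_site_degenerate(self):
        codes = np.zeros((4, 1), dtype=np.int64)
        sites = np.array(["s"] * 4, dtype=object)
        mothers = np.array(["m1", "m1", "m2", "m2"], dtype=object)
        with pytest.raises(DegenerateDesignError):
            pf.ssd_partition(pf.distance_matrix(codes), sites, mothers)


class TestInvariants:
    def test_ssd_conservation(self):
        rng = np.random.default_rng(8)
        codes, sites, mothers = random_design(rng, missing_rate=0.1)
        D = pf.distance_matrix(codes)
        ssd = pf.ssd_partition(D, sites, mothers)
        total = (ssd["ssd_among_sites"] + ssd["ssd_among_mothers"]
                 + ssd["ssd_within_mothers"])
        assert total == pytest.approx(ssd["ssd_total"], rel=1e-9)
        N = len(sites)
        assert (ssd["df_among_sites"] + ssd["df_among_mothers"]
                + ssd["df_within_mothers"]) == N - 1

    def test_phi_scale_invariance(self):
        rng = np.random.default_rng(9)
        codes, sites, mothers = random_design(rng)
        D = pf.distance_matrix(codes)
        r1 = pf.amova(D, sites, mothers)
        r2 = pf.amova(17.3 * D, sites, mothers)
        assert r2.phi_ct == pytest.approx(r1.phi_ct, rel=1e-12)
        assert r2.phi_sc == pytest.approx(r1.phi_sc, rel=1e-12)
        assert r2.phi_st == pytest.approx(r1.phi_st, rel=1e-12)

    def test_label_relabeling_equivariance(self):
        rng = np.random.default_rng(10)
        codes, sites, mothers = random_design(rng)
        D = pf.distance_matrix(codes)
        r1 = pf.amova(D, sites, mothers)
        relab_s = {s: f"site_{hash(s) % 97}_{s}" for s in set(sites)}
        relab_m = {m: f"mom_{m[::-1]}" for m in set(mothers)}
        r2 = pf.amova(D, np.array([relab_s[s] for s in sites], dtype=object),
                      np.array([relab_m[m] for m in mothers], dtype=object))
        assert r1.as_dict() == r2.as_dict()

    def test_study_design_df(self):
        """18 sites / 71 mothers: among-level df are 17 and 53."""
        rng = np.random.default_rng(11)
        sites, mothers = [], []
        per_site = [4] * 17 + [3]  # 71 mothers over 18 sites (uneven)
        assert sum(per_site) == 71
        for g, nm in enumerate(per_site):
            for k in range(nm):
                for _ in range(rng.integers(8, 12)):
                    sites.append(f"s{g}")
                    mothers.append(f"s{g}m{k}")
        codes = rng.integers(0, 5, (len(sites), 3))
        D = pf.distance_matrix(codes)
        ssd = pf.ssd_partition(D, np.array(sites, dtype=object),
                               np.array(mothers, dtype=object))
        assert ssd["df_among_sites"] == 17
        assert ssd["df_among_mothers"] == 53
        assert ssd["df_within_mothers"] == len(sites) - 71


@pytest.fixture(scope="module")
def structured():
    rng = np.random.default_rng(21)
    codes, sites, mothers = random_design(
        rng, n_sites=6, mothers_per_site=(3, 5), gametes=(3, 6), n_loci=6
    )
    return pf.distance_matrix(codes), sites, mothers


class TestPermutationTests:
    def test_nperm_zero_rejected(self, structured):
        D, sites, mothers = structured
        with pytest.raises(ValueError):
            pf.permutation_test_within(D, sites, mothers, 0, 1)
        with pytest.raises(ValueError):
            pf.permutation_test_among(D, sites, mothers, 0, 1)

    def test_fixed_seed_reproducible(self, structured):
        D, sites, mothers = structured
        assert (pf.permutation_test_within(D, sites, mothers, 99, 5)[0]
                == pf.permutation_test_within(D, sites, mothers, 99, 5)[0])
        assert (pf.permutation_test_among(D, sites, mothers, 99, 5)[0]
                == pf.permutation_test_among(D, sites, mothers, 99, 5)[0])

    def test_within_null_matches_direct_amova(self, structured):
        """The vectorized permutation statistic must equal a direct AMOVA
        recomputation under the same relabeling."""
        D, sites, mothers = structured
        n_perm = 30
        _, _, null = pf.permutation_test_within(D, sites, mothers, n_perm, 3,
                                                return_null=True)
        rng = np.random.default_rng(3)  # replay the same permutation stream
        site_orders = {}
        for g in pd_unique(sites):
            idx = np.flatnonzero(sites == g)
            if len(idx) < 2:
                continue
            site_orders[g] = np.argsort(rng.random((n_perm, len(idx))), axis=1)
        for b in range(5):
            perm = mothers.copy()
            for g, orders in site_orders.items():
                idx = np.flatnonzero(sites == g)
                perm[idx] = mothers[idx][orders[b]]
            direct = pf.amova(D, sites, perm)
            assert null[b] == pytest.approx(direct.phi_sc, rel=1e-9)

    def test_among_null_matches_direct_amova(self, structured):
        D, sites, mothers = structured
        _, _, null = pf.permutation_test_among(D, sites, mothers, 5, 7,
                                               return_null=True)
        rng = np.random.default_rng(7)
        mother_ids = pd_unique(mothers)
        site_of_mother = [sites[np.flatnonzero(mothers == m)[0]] for m in mother_ids]
        for b in range(5):
            assign = np.array(site_of_mother, dtype=object)[rng.permutation(len(mother_ids))]
            new_sites = np.empty(len(sites), dtype=object)
            for k, m in enumerate(mother_ids):
                new_sites[mothers == m] = assign[k]
            direct = pf.amova(D, new_sites, mothers)
            assert null[b] == pytest.approx(direct.phi_ct, rel=1e-9)

    def test_null_pvalues_uniform(self):
        """On null data both stratified tests produce uniform p-values:
        rejection at alpha=0.05 stays in the binomial band and the
        empirical CDF stays near the diagonal."""
        from scipy import stats

        sc = pf.SimulationScenario(
            n_sites=6, mothers_per_site=3, fruits_per_mother=2,
            seeds_per_fruit=2, n_loci=5, f_ct=0.0, f_sc=0.0, seed=0,
        )
        rep = pf.estimate_rejection_rates(
            sc, n_replicates=300, n_perm=59, alpha=0.05, seed=77
        )
        lo, hi = pf.binomial_ci(0.05, 300)
        assert lo <= rep.rejection_rate_sc <= hi
        assert lo <= rep.rejection_rate_ct <= hi
        for pvals in (rep.p_values_sc, rep.p_values_ct):
            # lattice spacing 1/60 inflates KS slightly; test at alpha=0.01
            assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPhiRatio:
    @pytest.mark.parametrize(
        "phi_sc, phi_ct, expected_within",
        [(0.0506, 0.0285, 0.639), (0.0635, 0.0273, 0.699), (0.0862, 0.0332, 0.721)],
    )
    def test_reported_fractions(self, phi_sc, phi_ct, expected_within):
        within, among = pf.phi_ratio(phi_sc, phi_ct)
        assert within == pytest.approx(expected_within, abs=1e-3)
        assert within + among == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_degenerate(self):
        assert pf.phi_ratio(0.04, 0.04) == (0.5, 0.5)
        assert all(np.isnan(v) for v in pf.phi_ratio(0.0, 0.0))
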