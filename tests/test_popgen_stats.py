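import math

import numpy as np
import pytest

from mothroutes.genotype_data import GenotypeDataset, LocusInfo
from mothroutes.popgen_stats import (
    DistanceMatrix,
    diversity_table,
    hwe_exact_test,
    ld_screen,
    locus_qc_filter,
    null_allele_em,
    pairwise_fst,
    rarefied_richness,
    wc_fis_population,
    wc_theta_pair,
)
from mothroutes.genotype_data import allele_counts
from mothroutes.synthetic_data import generate_hw_population

from .conftest import make_dataset


# ---------------------------------------------------------------------------
# Independent brute-force transcription of the Weir & Cockerham (1984)
# variance components, used as an oracle for the package implementation.


def wc_theta_oracle(pop_genos: list[list[tuple[int, int]]]) -> float:
    r = len(pop_genos)
    alleles = sorted({a for pop in pop_genos for g in pop for a in g})
    ns = np.array([len(pop) for pop in pop_genos], dtype=float)
    nbar = ns.mean()
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    num = den = 0.0
    for al in alleles:
        p = np.array(
            [sum(g.count(al) for g in pop) / (2 * len(pop)) for pop in pop_genos]
        )
        h = np.array(
            [
                sum(1 for g in pop if al in g and g[0] != g[1]) / len(pop)
                for pop in pop_genos
            ]
        )
        pbar = (ns * p).sum() / (r * nbar)
        s2 = (ns * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h).sum() / (r * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


class TestDiversity:
    def test_he_hand_value(self):
        ds = make_dataset({"a": [[(1, 2)], [(1, 2)]]})
        div = diversity_table(ds)
        row = div.per_locus.loc[("a", "L1")]
        assert row.ho == 1.0
        assert row.he == pytest.approx(4 / 3 * 0.5, abs=1e-12)

    def test_monomorphic_locus(self):
        ds = make_dataset({"a": [[(5, 5)], [(5, 5)], [(5, 5)]]})
        row = diversity_table(ds).per_locus.loc[("a", "L1")]
        assert (row.na, row.ho, row.he, row.ra) == (1, 0.0, 0.0, 1.0)
        assert np.isnan(row.fis)

    def test_rarefaction_hand_value(self):
        # gene counts {3,1}, N=4, g=2: 1 + (1 - C(3,2)/C(4,2)) = 1.5
        ds = make_dataset({"a": [[(1, 1)], [(1, 2)]]})
        ac = allele_counts(ds, "L1", "a")
        assert rarefied_richness(ac, 2) == pytest.approx(1.5, abs=1e-12)

    def test_rarefaction_at_full_sample_equals_na_and_monotone(self, rng):
        counts = {1: 7, 2: 4, 3: 1}
        from mothroutes.genotype_data import AlleleCounts

        ac = AlleleCounts("L", "p", counts, 12)
        assert rarefied_richness(ac, 12) == pytest.approx(3)
        vals = [rarefied_richness(ac, g) for g in range(1, 13)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_empty_cell_flagged_and_excluded_from_means(self):
        ds = make_dataset({"a": [[(1, 2), None], [(1, 1), None]]})
        div = diversity_table(ds)
        assert np.isnan(div.per_locus.loc[("a", "L2")].he)
        # freqs 3/4, 1/4: unbiased He = (4/3) * (1 - 10/16) = 0.5
        assert div.means.loc["a", "he"] == pytest.approx(0.5)


class TestPairwiseFst:
    def test_fixed_difference_gives_theta_one(self):
        ds = make_dataset(
            {
                "a": [[(1, 1)] * 2] * 6,
                "b": [[(2, 2)] * 2] * 6,
            }
        )
        m = pairwise_fst(ds)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_panmictic_pool_gives_theta_near_zero(self):
        freqs = {10: 0.4, 12: 0.35, 14: 0.25}
        a = generate_hw_population(freqs, 200, seed=1, n_loci=5, population="a")
        b = generate_hw_population(freqs, 200, seed=2, n_loci=5, population="b")
        ds = GenotypeDataset(a.loci, ["a", "b"], [a.individuals[0], b.individuals[0]])
        th = wc_theta_pair(ds, "a", "b")
        assert abs(th) < 0.02

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            pops = []
            for _ in range(2):
                pops.append(
                    [tuple(sorted(rng.integers(1, 5, size=2))) for _ in range(12)]
                )
            if len({a for p in pops for g in p for a in g}) < 2:
                continue
            ds = make_dataset({"a": [[g] for g in pops[0]], "b": [[g] for g in pops[1]]})
            assert wc_theta_pair(ds, "a", "b") == pytest.approx(
                wc_theta_oracle(pops), abs=1e-12
            )

    def test_negative_theta_retained(self):
        # nearly identical samples: small negative estimates must survive
        ds = make_dataset(
            {
                "a": [[(1, 2)], [(1, 2)], [(1, 1)], [(2, 2)]],
                "b": [[(1, 2)], [(1, 2)], [(1, 1)], [(2, 2)]],
            }
        )
        assert pairwise_fst(ds).values[0, 1] < 0


def test_theta_increases_with_divergence_time():
    """Weir-Cockerham theta grows with split time between two demes."""
    from mothroutes.abc_inference import (
        Deme,
        Founding,
        MutationModel,
        ScenarioSpec,
        simulate_dataset,
    )

    loci = [LocusInfo(f"L{i}", 100, 300, 2) for i in range(20)]
    mut = MutationModel(tuple([5e-4] * 20), 0.0, tuple(loci))
    means = []
    for T in (50.0, 400.0, 4000.0):
        spec = ScenarioSpec(
            8,
            "split",
            (Deme("A", 100), Deme("B", 100)),
            (Founding("B", "A", "T", "nbB", "dbB"),),
            root="A",
        )
        params = {"N_A": 500.0, "N_B": 500.0, "N_anc": 500.0, "T1": 1e8,
                  "T": T, "nbB": 500.0, "dbB": 1.0}
        thetas = [
            wc_theta_pair(simulate_dataset(spec, params, mut, 100 + rep), "A", "B")
            for rep in range(8)
        ]
        means.append(np.mean(thetas))
    assert means[0] < means[1] < means[2]


class TestHWE:
    def test_monomorphic_p_is_one(self):
        ds = make_dataset({"a": [[(3, 3)]] * 5})
        with pytest.warns(UserWarning, match="monomorphic"):
            assert hwe_exact_test(ds, "L1", "a") == 1.0

    def test_monte_carlo_matches_enumeration(self):
        # 2 alleles, n = 10, moderate heterozygote deficit
        genos = [[(1, 1)]] * 4 + [[(1, 2)]] * 2 + [[(2, 2)]] * 4
        ds = make_dataset({"a": genos})
        p_exact = hwe_exact_test(ds, "L1", "a")  # enumeration branch (n <= 20)
        big = make_dataset({"a": genos * 3})  # n = 30 forces Monte Carlo
        p_exact_big_ref = _hwe_enumeration_reference(big)
        p_mc = hwe_exact_test(big, "L1", "a", n_mc=20_000, seed=5)
        se = math.sqrt(p_exact_big_ref * (1 - p_exact_big_ref) / 20_000)
        assert abs(p_mc - p_exact_big_ref) < 3 * se + 1e-4
        assert 0 < p_exact <= 1

    def test_perfect_hw_sample_is_modal(self):
        # genotype counts exactly p^2, 2pq, q^2 with p = 0.5, n = 16
        genos = [[(1, 1)]] * 4 + [[(1, 2)]] * 8 + [[(2, 2)]] * 4
        ds = make_dataset({"a": genos})
        assert hwe_exact_test(ds, "L1", "a") > 0.5


def _hwe_enumeration_reference(ds) -> float:
    """Independent full enumeration for a 2-allele locus of any n."""
    from collections import Counter

    tab = Counter()
    for ind in ds.individuals[0]:
        tab[tuple(sorted(ind.genotypes[0]))] += 1
    n = sum(tab.values())
    a1 = 2 * tab[(1, 1)] + tab[(1, 2)]
    a2 = 2 * tab[(2, 2)] + tab[(1, 2)]

    def logprob(n12):
        n11, n22 = (a1 - n12) // 2, (a2 - n12) // 2
        return (
            math.lgamma(n + 1)
            - math.lgamma(n11 + 1)
            - math.lgamma(n12 + 1)
            - math.lgamma(n22 + 1)
            + n12 * math.log(2)
            + math.lgamma(a1 + 1)
            + math.lgamma(a2 + 1)
            - math.lgamma(2 * n + 1)
        )

    obs = logprob(tab[(1, 2)])
    ps = {
        n12: math.exp(logprob(n12))
        for n12 in range(a1 % 2, min(a1, a2) + 1, 2)
    }
    total = sum(ps.values())
    return sum(v for n12, v in ps.items() if logprob(n12) <= obs + 1e-9) / total


class TestNullAlleleEM:
    def test_no_signal_gives_near_zero(self):
        ds = generate_hw_population({10: 0.5, 12: 0.5}, 400, seed=3)
        r = null_allele_em(ds, "loc1", "pop1").frequency
        assert r < 0.03

    def test_recovers_planted_null_rate(self):
        ds = generate_hw_population({10: 0.4, 12: 0.6}, 500, null_rate=0.2, seed=4)
        r = null_allele_em(ds, "loc1", "pop1").frequency
        assert abs(r - 0.2) < 0.05

    def test_matches_grid_search_oracle(self):
        ds = generate_hw_population({10: 0.5, 12: 0.5}, 120, null_rate=0.15, seed=6)
        r_em = null_allele_em(ds, "loc1", "pop1", tol=1e-10).frequency
        r_grid = _null_grid_oracle(ds)
        assert abs(r_em - r_grid) < 0.002


def _null_grid_oracle(ds) -> float:
    """Profile-likelihood grid search (step 0.001) for a 2-visible-allele locus."""
    from collections import Counter

    het = hom1 = hom2 = miss = 0
    vis = sorted(
        {a for ind in ds.individuals[0] if ind.genotypes[0] for a in ind.genotypes[0]}
    )
    for ind in ds.individuals[0]:
        g = ind.genotypes[0]
        if g is None:
            miss += 1
        elif g[0] != g[1]:
            het += 1
        elif g[0] == vis[0]:
            hom1 += 1
        else:
            hom2 += 1
    best = (-np.inf, 0.0)
    for r in np.arange(0.0, 0.5, 0.001):
        for p1 in np.arange(0.001, 1.0 - r, 0.001):
            p2 = 1.0 - r - p1
            if p2 <= 0:
                continue
            probs = [
                p1 * p1 + 2 * p1 * r,
                p2 * p2 + 2 * p2 * r,
                2 * p1 * p2,
                r * r,
            ]
            if min(probs) <= 0:
                continue
            ll = (
                hom1 * math.log(probs[0])
                + hom2 * math.log(probs[1])
                + het * math.log(probs[2])
                + (miss * math.log(probs[3]) if miss else 0.0)
            )
            if ll > best[0]:
                best = (ll, r)
    return best[1]


class TestLdScreen:
    def test_duplicated_locus_hits_permutation_floor(self, rng):
        genos = {
            "a": [
                [g, g]
                for g in (tuple(sorted(rng.integers(1, 5, size=2))) for _ in range(30))
            ]
        }
        ds = make_dataset(genos)
        res = ld_screen(ds, n_perm=200, seed=1)
        assert res.p.iloc[0] == pytest.approx(1 / 201)

    def test_sparse_pair_skipped(self):
        ds = make_dataset({"a": [[(1, 2), (1, 2)], [(1, 1), None], [None, (2, 2)]]})
        res = ld_screen(ds, n_perm=100, seed=0)
        assert bool(res.skipped.iloc[0])

    def test_independent_loci_give_uniform_p(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(7)
        genos = []
        for _ in range(40):
            genos.append(
                [tuple(sorted(rng.integers(1, 6, size=2))) for _ in range(8)]
            )
        ds = make_dataset({"a": genos})
        res = ld_screen(ds, n_perm=200, seed=2)
        stat = kstest(res.p.values, "uniform")
        assert stat.pvalue > 0.01


class TestQcFilter:
    @staticmethod
    def _merged(n_pops=3, n=60, bad_null=0.0, seed=0):
        pops = {}
        for p in range(n_pops):
            clean = generate_hw_population(
                {10: 0.35, 12: 0.35, 14: 0.3}, n, n_loci=4, seed=seed + p
            )
            bad = generate_hw_population(
                {20: 0.5, 22: 0.5}, n, null_rate=bad_null, seed=seed + 50 + p
            )
            pops[f"p{p + 1}"] = [
                ci.genotypes + bi.genotypes
                for ci, bi in zip(clean.individuals[0], bad.individuals[0])
            ]
        return make_dataset(pops, locus_names=["A", "B", "C", "D", "bad"])

    def test_clean_loci_pass_unchanged(self):
        ds = self._merged(bad_null=0.0)
        assert locus_qc_filter(ds, seed=1) == ["A", "B", "C", "D", "bad"]

    def test_planted_bad_locus_dropped(self):
        ds = self._merged(bad_null=0.4, seed=3)
        assert locus_qc_filter(ds, seed=1) == ["A", "B", "C", "D"]

    def test_vacuous_thresholds_drop_nothing(self):
        ds = self._merged(bad_null=0.4, seed=3)
        retained = locus_qc_filter(ds, null_threshold=1.0, min_pop_fraction=1.0, seed=1)
        assert retained == ["A", "B", "C", "D", "bad"]


class TestFis:
    def test_recovers_planted_inbreeding(self):
        ds = generate_hw_population({10: 0.5, 12: 0.5}, 500, fis=0.3, seed=9, n_loci=5)
        assert wc_fis_population(ds, "pop1") == pytest.approx(0.3, abs=0.1)


class TestDistanceMatrix:
    def test_rejects_asymmetry_and_bad_diagonal(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))

    @pytest.mark.parametrize("form", ["square", "lower"])
    def test_file_round_trip(self, tmp_path, form):
        m = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 0.1, 0.2], [0.1, 0, -0.05], [0.2, -0.05, 0]]
        ))
        path = tmp_path / "m.csv"
        m.write(path, form=form)
        back = DistanceMatrix.read(path)
        assert back.labels == m.labels
        np.testing.assert_allclose(back.values, m.values)
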