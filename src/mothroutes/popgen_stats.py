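"""Per-population diversity statistics, Weir–Cockerham F-statistics, and
locus screening (Hardy–Weinberg exact tests, null-allele EM, linkage screen).

Estimator conventions follow the classical microsatellite toolchain:
unbiased expected heterozygosity (Nei), hypergeometric rarefaction of
allelic richness (Leberg/Hurlbert), and Weir & Cockerham (1984) variance
components for FIS/FST, with negative estimates retained.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_data import AlleleCounts, GenotypeDataset

__all__ = [
    "DistanceMatrix",
    "DiversityTable",
    "diversity_table",
    "pairwise_fst",
    "wc_theta_pair",
    "wc_fis_population",
    "fis_permutation_test",
    "hwe_exact_test",
    "null_allele_em",
    "NullAlleleResult",
    "ld_screen",
    "locus_qc_filter",
    "rarefied_richness",
    "unbiased_he",
]


# ---------------------------------------------------------------------------
# Distance matrices


@dataclass
class DistanceMatrix:
    """Labeled square symmetric matrix with a zero diagonal.

    FST matrices may legitimately carry small negative off-diagonal entries;
    no truncation is applied anywhere in the package.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        sym_ok = np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
            atol=1e-9,
        )
        if not sym_ok or not (finite == finite.T).all():
            raise ValueError("matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (label) order."""
        iu = np.triu_indices(self.n, 1)
        return self.values[iu]

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write(self, path, form: str = "square", sep: str = ",") -> None:
        """Write as a labeled table; ``form`` is 'square' or 'lower'."""
        df = self.to_dataframe()
        if form == "lower":
            mask = np.triu(np.ones_like(self.values, dtype=bool))
            df = df.mask(mask)
            df = df.iloc[1:, :-1]
        elif form != "square":
            raise ValueError("form must be 'square' or 'lower'")
        df.to_csv(path, sep=sep)

    @classmethod
    def read(cls, path, sep: str = ",") -> "DistanceMatrix":
        """Read a labeled square or lower-triangular matrix file."""
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str).str.strip()
        df.columns = [str(c).strip() for c in df.columns]
        rows, cols = list(df.index), list(df.columns)
        if rows == cols:
            return cls(rows, df.values.astype(float))
        # lower-triangular: rows are labels[1:], columns labels[:-1]
        labels = cols + [rows[-1]]
        if rows != labels[1:]:
            raise ValueError(
                f"labels do not form a square or lower-triangular layout: "
                f"rows={rows}, cols={cols}"
            )
        n = len(labels)
        m = np.zeros((n, n))
        for i in range(1, n):
            for j in range(i):
                m[i, j] = m[j, i] = float(df.iloc[i - 1, j])
        return cls(labels, m)


# ---------------------------------------------------------------------------
# Diversity statistics


def unbiased_he(counts: AlleleCounts) -> float:
    """Nei's unbiased gene diversity (2n/(2n-1)) * (1 - sum p^2)."""
    ng = counts.n_genes
    if ng < 2:
        return float("nan")
    p = np.array(list(counts.counts.values()), dtype=float) / ng
    return ng / (ng - 1) * (1.0 - float(np.sum(p**2)))


def rarefied_richness(counts: AlleleCounts, g: int) -> float:
    """Expected allele count in a random subsample of ``g`` gene copies.

    Hypergeometric rarefaction: sum over alleles of 1 - C(N - N_a, g)/C(N, g).
    """
    N = counts.n_genes
    if g < 1 or N == 0:
        return float("nan")
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds sample of {N} genes")
    total = 0.0
    lc_N_g = gammaln(N + 1) - gammaln(g + 1) - gammaln(N - g + 1)
    for na in counts.counts.values():
        if N - na < g:
            total += 1.0
        else:
            lc = gammaln(N - na + 1) - gammaln(g + 1) - gammaln(N - na - g + 1)
            total += 1.0 - math.exp(lc - lc_N_g)
    return total


def _locus_pop_stats(ds: GenotypeDataset, j: int, p: int):
    """(n, het count, Counter of allele copies, per-allele het counts) at locus j, pop p."""
    n = 0
    het = 0
    copies: Counter[int] = Counter()
    het_by_allele: Counter[int] = Counter()
    for ind in ds.individuals[p]:
        g = ind.genotypes[j]
        if g is None:
            continue
        n += 1
        copies[g[0]] += 1
        copies[g[1]] += 1
        if g[0] != g[1]:
            het += 1
            het_by_allele[g[0]] += 1
            het_by_allele[g[1]] += 1
    return n, het, copies, het_by_allele


def wc_fis_population(ds: GenotypeDataset, population: str) -> float:
    """Weir–Cockerham small-sample within-population fixation index f.

    Multilocus: f = 1 - sum(c) / sum(b + c) over loci and alleles, with the
    single-population variance components
    b = n/(n-1) * [p(1-p) - (2n-1)/(4n) * h],  c = h/2.
    """
    p_idx = ds.population_index(population)
    sum_b = 0.0
    sum_c = 0.0
    for j in range(ds.n_loci):
        n, _, copies, het_by_allele = _locus_pop_stats(ds, j, p_idx)
        if n < 2 or len(copies) < 2:
            continue
        for a, cnt in copies.items():
            pa = cnt / (2 * n)
            ha = het_by_allele.get(a, 0) / n
            b = n / (n - 1) * (pa * (1 - pa) - (2 * n - 1) / (4 * n) * ha)
            c = ha / 2.0
            sum_b += b
            sum_c += c
    denom = sum_b + sum_c
    if denom == 0:
        return float("nan")
    return 1.0 - sum_c / denom


def fis_permutation_test(
    ds: GenotypeDataset, population: str, n_perm: int = 10_000, seed: int = 0
) -> dict:
    """Randomization test of FIS: permute allele copies among individuals
    within the population (per locus), as FSTAT does.

    Returns observed f with one-tailed p-values for heterozygote deficit
    (f_perm >= f_obs) and excess, using the (b+1)/(m+1) estimator.
    """
    rng = np.random.default_rng(seed)
    p_idx = ds.population_index(population)
    f_obs = wc_fis_population(ds, population)
    if not np.isfinite(f_obs):
        return {"f": f_obs, "p_deficit": float("nan"), "p_excess": float("nan")}
    inds = ds.individuals[p_idx]
    per_locus_copies = []
    for j in range(ds.n_loci):
        copies = []
        for ind in inds:
            g = ind.genotypes[j]
            if g is not None:
                copies.extend(g)
        per_locus_copies.append(np.array(copies))
    ge_def = 0
    ge_exc = 0
    shadow = GenotypeDataset(
        ds.loci, [population], [[_copy_individual(ind) for ind in inds]]
    )
    for _ in range(n_perm):
        for j, copies in enumerate(per_locus_copies):
            perm = rng.permutation(copies)
            k = 0
            for orig, ind in zip(inds, shadow.individuals[0]):
                if orig.genotypes[j] is None:
                    ind.genotypes[j] = None
                else:
                    ind.genotypes[j] = (int(perm[k]), int(perm[k + 1]))
                    k += 2
        f_perm = wc_fis_population(shadow, population)
        if f_perm >= f_obs - 1e-12:
            ge_def += 1
        if f_perm <= f_obs + 1e-12:
            ge_exc += 1
    return {
        "f": f_obs,
        "p_deficit": (ge_def + 1) / (n_perm + 1),
        "p_excess": (ge_exc + 1) / (n_perm + 1),
    }


def _copy_individual(ind):
    from .genotype_data import Individual

    return Individual(ind.label, list(ind.genotypes))


@dataclass
class DiversityTable:
    """Per-population × locus diversity statistics plus per-population means."""

    per_locus: pd.DataFrame  # MultiIndex (population, locus) rows; columns na..fis
    means: pd.DataFrame  # population rows; columns na, ho, he, ra, fis

    def write(self, path, sep: str = ",") -> None:
        self.means.to_csv(path, sep=sep)


def diversity_table(ds: GenotypeDataset, rarefaction_g: int | None = None) -> DiversityTable:
    """NA, Ho, He (unbiased), rarefied allelic richness and FIS per population.

    ``rarefaction_g``: gene-copy count used for rarefaction; by default the
    smallest non-missing gene count observed at each locus across populations.
    """
    rows = []
    # per-locus default g = min gene count across populations with data
    g_per_locus: list[int] = []
    for j in range(ds.n_loci):
        gs = []
        for p in range(len(ds.populations)):
            n, _, copies, _ = _locus_pop_stats(ds, j, p)
            if n > 0:
                gs.append(2 * n)
        if rarefaction_g is not None:
            g_per_locus.append(int(rarefaction_g))
        else:
            g_per_locus.append(min(gs) if gs else 0)
        if g_per_locus[-1] == 1:
            g_per_locus[-1] = 2

    for p, pop in enumerate(ds.populations):
        for j, locus in enumerate(ds.locus_names):
            n, het, copies, het_by = _locus_pop_stats(ds, j, p)
            if n == 0:
                rows.append((pop, locus, np.nan, np.nan, np.nan, np.nan, np.nan))
                continue
            ac = AlleleCounts(locus, pop, dict(copies), 2 * n)
            na = len(copies)
            ho = het / n
            he = unbiased_he(ac) if na > 1 else 0.0
            g = min(g_per_locus[j], 2 * n)
            ra = rarefied_richness(ac, g) if g >= 1 else np.nan
            fis = _single_locus_fis(n, copies, het_by) if na > 1 and n >= 2 else np.nan
            rows.append((pop, locus, na, ho, he, ra, fis))

    per_locus = pd.DataFrame(
        rows, columns=["population", "locus", "na", "ho", "he", "ra", "fis"]
    ).set_index(["population", "locus"])

    means = per_locus.groupby(level="population", sort=False)[
        ["na", "ho", "he", "ra"]
    ].mean()
    means["fis"] = [wc_fis_population(ds, pop) for pop in means.index]
    return DiversityTable(per_locus, means)


def _single_locus_fis(n: int, copies: Counter, het_by: Counter) -> float:
    sum_b = sum_c = 0.0
    for a, cnt in copies.items():
        pa = cnt / (2 * n)
        ha = het_by.get(a, 0) / n
        sum_b += n / (n - 1) * (pa * (1 - pa) - (2 * n - 1) / (4 * n) * ha)
        sum_c += ha / 2.0
    d = sum_b + sum_c
    return float("nan") if d == 0 else 1.0 - sum_c / d


# ---------------------------------------------------------------------------
# Weir & Cockerham theta


def _wc_components_locus(ns, ps, hs):
    """Variance components (a, b, c) for one allele at one locus.

    ns: sample sizes per population; ps: allele frequencies; hs: observed
    heterozygote frequencies involving the allele.  Weir & Cockerham (1984).
    """
    ns = np.asarray(ns, float)
    ps = np.asarray(ps, float)
    hs = np.asarray(hs, float)
    r = len(ns)
    nbar = ns.mean()
    if nbar <= 1 or r < 2:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - np.sum(ns**2) / (r * nbar)) / (r - 1)
    pbar = np.sum(ns * ps) / (r * nbar)
    s2 = np.sum(ns * (ps - pbar) ** 2) / ((r - 1) * nbar)
    hbar = np.sum(ns * hs) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc_theta_pair(ds: GenotypeDataset, pop_a: str, pop_b: str) -> float:
    """Multilocus Weir–Cockerham theta between two populations."""
    ia, ib = ds.population_index(pop_a), ds.population_index(pop_b)
    sum_a = sum_abc = 0.0
    informative = False
    for j in range(ds.n_loci):
        stats = []
        for p in (ia, ib):
            n, _, copies, het_by = _locus_pop_stats(ds, j, p)
            stats.append((n, copies, het_by))
        if stats[0][0] == 0 or stats[1][0] == 0:
            continue
        alleles = set(stats[0][1]) | set(stats[1][1])
        if len(alleles) < 2:
            continue
        informative = True
        for al in alleles:
            ns = [s[0] for s in stats]
            ps = [s[1].get(al, 0) / (2 * s[0]) for s in stats]
            hs = [s[2].get(al, 0) / s[0] for s in stats]
            a, b, c = _wc_components_locus(ns, ps, hs)
            sum_a += a
            sum_abc += a + b + c
    if not informative or sum_abc == 0:
        return float("nan")
    return sum_a / sum_abc


def pairwise_fst(ds: GenotypeDataset) -> DistanceMatrix:
    """Pairwise multilocus Weir–Cockerham theta; negative values retained."""
    if len(ds.populations) < 2:
        raise ValueError("need at least two populations")
    n = len(ds.populations)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        th = wc_theta_pair(ds, ds.populations[i], ds.populations[j])
        if not np.isfinite(th):
            warnings.warn(
                f"theta undefined for pair ({ds.populations[i]}, {ds.populations[j]})"
            )
        m[i, j] = m[j, i] = th
    return DistanceMatrix(list(ds.populations), m)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test


def _table_logprob(n_ij: dict, allele_counts_: dict, n: int) -> float:
    """log conditional probability of a genotype table given allele counts."""
    H = sum(c for (a, b), c in n_ij.items() if a != b)
    lp = gammaln(n + 1) + H * math.log(2.0) - gammaln(2 * n + 1)
    for cnt in allele_counts_.values():
        lp += gammaln(cnt + 1)
    for cnt in n_ij.values():
        lp -= gammaln(cnt + 1)
    return lp


def _genotype_table(ds, locus, population):
    p = ds.population_index(population)
    j = ds.locus_index(locus)
    tab: Counter = Counter()
    for ind in ds.individuals[p]:
        g = ind.genotypes[j]
        if g is not None:
            tab[tuple(sorted(g))] += 1
    return dict(tab)


def _enumerate_tables(acounts: list[int]):
    """All genotype tables with the given (sorted-by-allele) gene-copy counts.

    Supports up to 3 alleles; yields dicts {(i,j): count} over allele indices.
    """
    k = len(acounts)
    if k == 2:
        a1, a2 = acounts
        for n12 in range(min(a1, a2), -1, -1):
            if (a1 - n12) % 2 or (a2 - n12) % 2:
                continue
            yield {(0, 0): (a1 - n12) // 2, (0, 1): n12, (1, 1): (a2 - n12) // 2}
    elif k == 3:
        a1, a2, a3 = acounts
        for n12 in range(min(a1, a2) + 1):
            for n13 in range(min(a1 - n12, a3) + 1):
                if (a1 - n12 - n13) % 2:
                    continue
                for n23 in range(min(a2 - n12, a3 - n13) + 1):
                    if (a2 - n12 - n23) % 2 or (a3 - n13 - n23) % 2:
                        continue
                    yield {
                        (0, 0): (a1 - n12 - n13) // 2,
                        (1, 1): (a2 - n12 - n23) // 2,
                        (2, 2): (a3 - n13 - n23) // 2,
                        (0, 1): n12,
                        (0, 2): n13,
                        (1, 2): n23,
                    }
    else:
        raise ValueError("enumeration supports at most 3 alleles")


def hwe_exact_test(
    ds: GenotypeDataset,
    locus: str,
    population: str,
    n_mc: int = 10_000,
    seed: int = 0,
) -> float:
    """Probability-based exact test of Hardy–Weinberg proportions.

    Full enumeration of genotype tables conditional on allele counts when the
    locus has <= 3 alleles and <= 20 typed individuals; otherwise Monte Carlo
    over tables generated by random pairing of the observed gene copies.
    The p-value is the total probability of tables no more probable than the
    observed one.
    """
    tab = _genotype_table(ds, locus, population)
    n = sum(tab.values())
    if n == 0:
        raise ValueError(f"no data at {locus} in {population}")
    acount: Counter = Counter()
    for (a, b), cnt in tab.items():
        acount[a] += cnt
        acount[b] += cnt
    alleles = sorted(acount)
    if len(alleles) < 2:
        warnings.warn(f"monomorphic locus {locus} in {population}; p = 1")
        return 1.0
    amap = {al: i for i, al in enumerate(alleles)}
    obs = {tuple(sorted((amap[a], amap[b]))): c for (a, b), c in tab.items()}
    counts = [acount[al] for al in alleles]
    acounts_idx = {i: c for i, c in enumerate(counts)}
    lp_obs = _table_logprob(obs, acounts_idx, n)

    if len(alleles) <= 3 and n <= 20:
        num = 0.0
        den = 0.0
        for t in _enumerate_tables(counts):
            lp = _table_logprob(t, acounts_idx, n)
            w = math.exp(lp)
            den += w
            if lp <= lp_obs + 1e-9:
                num += w
        return min(num / den, 1.0)

    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000 for the Monte Carlo mode")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(alleles)), counts)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(pool)
        t: Counter = Counter()
        for i in range(0, len(pool), 2):
            a, b = pool[i], pool[i + 1]
            t[(min(a, b), max(a, b))] += 1
        if _table_logprob(dict(t), acounts_idx, n) <= lp_obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_mc + 1)


# ---------------------------------------------------------------------------
# Null-allele EM (Dempster)


@dataclass
class NullAlleleResult:
    frequency: float
    converged: bool
    n_iter: int
    visible_freqs: dict[int, float] = field(default_factory=dict)


def null_allele_em(
    ds: GenotypeDataset,
    locus: str,
    population: str,
    tol: float = 1e-6,
    max_iter: int = 5000,
    include_missing: bool = True,
) -> NullAlleleResult:
    """EM estimate of the null-allele frequency at one locus in one population.

    Model: a non-amplifying allele of frequency r segregates with the visible
    alleles; null homozygotes appear as missing genotypes and null
    heterozygotes as visible homozygotes.  The E-step splits each observed
    homozygote class between true homozygotes and null carriers; blanks count
    as null homozygotes when ``include_missing``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    p_idx = ds.population_index(population)
    j = ds.locus_index(locus)
    het: Counter = Counter()
    hom: Counter = Counter()
    n_missing = 0
    for ind in ds.individuals[p_idx]:
        g = ind.genotypes[j]
        if g is None:
            n_missing += 1
        elif g[0] == g[1]:
            hom[g[0]] += 1
        else:
            het[g[0]] += 1
            het[g[1]] += 1
    if not include_missing:
        n_missing = 0
    alleles = sorted(set(het) | set(hom))
    n_total = sum(hom.values()) + sum(het.values()) // 2 + n_missing
    # het counter currently holds copies per allele from heterozygotes
    if n_total == 0 or not alleles:
        raise ValueError(f"no usable data at {locus} in {population}")

    two_n = 2 * n_total
    # initialize: visible freqs from observed copies, small r
    p = {a: (het.get(a, 0) + 2 * hom.get(a, 0)) / two_n for a in alleles}
    r = max(1e-3, n_missing / n_total if n_missing else 1e-3)
    scale = 1.0 - r
    tot = sum(p.values())
    p = {a: v / tot * scale for a, v in p.items()}

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: expected allele-copy counts
        copies = {a: float(het.get(a, 0)) for a in alleles}
        null_copies = 2.0 * n_missing
        for a, cnt in hom.items():
            pa = p[a]
            denom = pa * pa + 2 * pa * r
            if denom <= 0:
                frac_true = 1.0
            else:
                frac_true = pa * pa / denom
            copies[a] += cnt * (2 * frac_true + (1 - frac_true))
            null_copies += cnt * (1 - frac_true)
        # M-step
        r_new = null_copies / two_n
        tot_vis = sum(copies.values())
        p = {a: copies[a] / two_n for a in alleles}
        if abs(r_new - r) < tol:
            r = r_new
            converged = True
            break
        r = r_new
    if not converged:
        warnings.warn(f"null-allele EM did not converge at {locus}/{population}")
    return NullAlleleResult(float(r), converged, it, p)


# ---------------------------------------------------------------------------
# Linkage-disequilibrium screen


def _pair_g_statistic(ds: GenotypeDataset, j1: int, j2: int) -> tuple[float, int]:
    """Genotypic G (log-likelihood-ratio) statistic pooled over populations."""
    g_total = 0.0
    n_joint = 0
    for p in range(len(ds.populations)):
        tab: Counter = Counter()
        for ind in ds.individuals[p]:
            g1, g2 = ind.genotypes[j1], ind.genotypes[j2]
            if g1 is None or g2 is None:
                continue
            tab[(tuple(sorted(g1)), tuple(sorted(g2)))] += 1
        n = sum(tab.values())
        n_joint += n
        if n == 0:
            continue
        row: Counter = Counter()
        col: Counter = Counter()
        for (a, b), c in tab.items():
            row[a] += c
            col[b] += c
        for (a, b), c in tab.items():
            e = row[a] * col[b] / n
            g_total += 2 * c * math.log(c / e) if e > 0 else 0.0
    return g_total, n_joint


def ld_screen(
    ds: GenotypeDataset, n_perm: int = 1000, seed: int = 0, min_joint: int = 5
) -> pd.DataFrame:
    """Permutation screen for genotypic association between locus pairs.

    The statistic is the G (LLR) statistic of the genotype × genotype
    contingency table pooled over populations; the null distribution permutes
    one locus's genotype column among individuals within each population.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    rows = []
    for j1, j2 in itertools.combinations(range(ds.n_loci), 2):
        g_obs, n_joint = _pair_g_statistic(ds, j1, j2)
        if n_joint < min_joint:
            rows.append((ds.locus_names[j1], ds.locus_names[j2], np.nan, np.nan, True))
            continue
        hits = 0
        saved = [[ind.genotypes[j2] for ind in inds] for inds in ds.individuals]
        for _ in range(n_perm):
            for p, inds in enumerate(ds.individuals):
                order = rng.permutation(len(inds))
                for k, ind in enumerate(inds):
                    ind.genotypes[j2] = saved[p][order[k]]
            g_perm, _ = _pair_g_statistic(ds, j1, j2)
            if g_perm >= g_obs - 1e-12:
                hits += 1
        for p, inds in enumerate(ds.individuals):
            for k, ind in enumerate(inds):
                ind.genotypes[j2] = saved[p][k]
        rows.append(
            (
                ds.locus_names[j1],
                ds.locus_names[j2],
                g_obs,
                (hits + 1) / (n_perm + 1),
                False,
            )
        )
    return pd.DataFrame(rows, columns=["locus1", "locus2", "g", "p", "skipped"])


# ---------------------------------------------------------------------------
# Locus QC filter


def locus_qc_filter(
    ds: GenotypeDataset,
    null_threshold: float = 0.20,
    hwe_alpha: float = 0.05,
    min_pop_fraction: float = 0.5,
    n_mc: int = 2000,
    seed: int = 0,
) -> list[str]:
    """Drop loci with high null-allele load that also fail Hardy–Weinberg.

    A locus is removed when its mean EM null-allele frequency across
    populations exceeds ``null_threshold`` AND it is out of HW equilibrium
    (exact-test p < ``hwe_alpha``) in at least ``1 - min_pop_fraction`` of the
    populations with data.  Returns retained locus labels in original order.
    """
    for name, v in [
        ("null_threshold", null_threshold),
        ("hwe_alpha", hwe_alpha),
        ("min_pop_fraction", min_pop_fraction),
    ]:
        if not 0 < v <= 1:
            raise ValueError(f"{name} must be in (0, 1]")
    retained = []
    for j, locus in enumerate(ds.locus_names):
        null_freqs = []
        hwe_fail = 0
        n_tested = 0
        for p, pop in enumerate(ds.populations):
            n, _, copies, _ = _locus_pop_stats(ds, j, p)
            if n == 0:
                continue
            n_tested += 1
            if len(copies) < 2:
                null_freqs.append(0.0)
                continue
            res = null_allele_em(ds, locus, pop)
            null_freqs.append(res.frequency)
            pval = hwe_exact_test(ds, locus, pop, n_mc=max(n_mc, 1000), seed=seed + j)
            if pval < hwe_alpha:
                hwe_fail += 1
        mean_null = float(np.mean(null_freqs)) if null_freqs else 0.0
        bad = (
            n_tested > 0
            and mean_null > null_threshold
            and hwe_fail >= (1.0 - min_pop_fraction) * n_tested
        )
        if not bad:
            retained.append(locus)
    if not retained:
        raise ValueError("all loci removed by QC filter")
    return retained


def subset_loci(ds: GenotypeDataset, loci: list[str]) -> GenotypeDataset:
    """Restrict a dataset to the given loci (original order preserved)."""
    from .genotype_data import Individual

    keep = [j for j, name in enumerate(ds.locus_names) if name in set(loci)]
    new_inds = [
        [
            Individual(ind.label, [ind.genotypes[j] for j in keep])
            for ind in inds
        ]
        for inds in ds.individuals
    ]
    return GenotypeDataset([ds.loci[j] for j in keep], list(ds.populations), new_inds)
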