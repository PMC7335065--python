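"""Bayesian admixture clustering (STRUCTURE-style) and Evanno Delta-K.

The sampler implements the admixture model with *independent* Dirichlet
allele-frequency priors per cluster — deliberately simpler than the
correlated-frequencies and LOCPRIOR variants — which is sufficient to
resolve the native-vs-invaded split this package targets.  The number of
clusters is selected by the Evanno second-difference statistic over
replicate runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import _gibbs
from .genotype_data import GenotypeDataset

__all__ = [
    "StructureRun",
    "EvannoTable",
    "run_admixture_mcmc",
    "evanno_delta_k",
    "k1_log_marginal",
    "match_clusters",
]


@dataclass
class StructureRun:
    K: int
    Q: pd.DataFrame  # rows: individuals (label, population, q_1..q_K)
    P: np.ndarray  # (K, L, max alleles) posterior-mean frequencies
    loglik_trace: np.ndarray
    alpha_trace: np.ndarray
    mean_ln_p: float  # STRUCTURE's model log-evidence estimate: mean - var/2
    seed: int
    burn_in: int
    iters: int

    def q_matrix(self) -> np.ndarray:
        return self.Q[[c for c in self.Q.columns if c.startswith("q_")]].values


def _recode(ds: GenotypeDataset):
    """Allele sizes -> 0-based indices per locus; returns (geno, n_alleles, labels, pops)."""
    alleles, pop_idx = ds.to_arrays()
    n, L, _ = alleles.shape
    geno = np.full((n, L, 2), -1, dtype=np.int32)
    n_alleles = np.zeros(L, dtype=np.int64)
    for l in range(L):
        obs = alleles[:, l, :]
        vals = np.unique(obs[obs > 0])
        amap = {v: i for i, v in enumerate(vals)}
        n_alleles[l] = max(len(vals), 1)
        for i in range(n):
            for c in range(2):
                v = obs[i, c]
                if v > 0:
                    geno[i, l, c] = amap[v]
    labels = [ind.label for inds in ds.individuals for ind in inds]
    pops = [ds.populations[p] for p in pop_idx]
    return geno, n_alleles, labels, pops


def run_admixture_mcmc(
    ds: GenotypeDataset,
    K: int,
    burn_in: int = 10_000,
    iters: int = 50_000,
    thin: int = 10,
    alpha_init: float = 1.0,
    lambda_: float = 1.0,
    seed: int = 0,
    alpha_step: float = 0.025,
    alpha_max: float = 10.0,
) -> StructureRun:
    """Gibbs-sample the admixture model; returns posterior means and traces.

    ``iters`` is the total chain length; samples are recorded every ``thin``
    iterations after ``burn_in``.  Reproducible given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not iters > burn_in >= 0:
        raise ValueError("need iters > burn_in >= 0")
    geno, n_alleles, labels, pops = _recode(ds)
    n_distinct = len({tuple(row.ravel()) for row in geno})
    if K > n_distinct:
        warnings.warn(
            f"K={K} exceeds the {n_distinct} distinct multilocus genotypes; "
            "empty clusters likely"
        )
    Qm, Pm, ll, at, acc = _gibbs.run_chain(
        geno,
        n_alleles,
        K,
        lambda_,
        alpha_init,
        alpha_max,
        alpha_step,
        iters,
        burn_in,
        thin,
        seed & 0x7FFFFFFF,
    )
    if not np.isfinite(ll).all():
        raise RuntimeError("non-finite likelihood in MCMC trace")
    mean_ln_p = float(ll.mean() - ll.var() / 2.0) if len(ll) else float("nan")
    q = pd.DataFrame(Qm, columns=[f"q_{k + 1}" for k in range(K)])
    q.insert(0, "population", pops)
    q.insert(0, "individual", labels)
    return StructureRun(K, q, Pm, ll, at, mean_ln_p, seed, burn_in, iters)


def k1_log_marginal(ds: GenotypeDataset, lambda_: float = 1.0) -> float:
    """Exact log marginal likelihood at K=1 (multinomial-Dirichlet per locus).

    With a single cluster the latent structure integrates out analytically:
    ln m(X) = sum over loci of ln B(lambda + counts) - ln B(lambda).
    """
    from scipy.special import gammaln

    geno, n_alleles, _, _ = _recode(ds)
    total = 0.0
    for l in range(geno.shape[1]):
        obs = geno[:, l, :]
        counts = np.bincount(obs[obs >= 0], minlength=n_alleles[l]).astype(float)
        a = np.full(n_alleles[l], lambda_)
        total += float(
            gammaln(a + counts).sum()
            - gammaln((a + counts).sum())
            - (gammaln(a).sum() - gammaln(a.sum()))
        )
    return total


def match_clusters(q_ref: np.ndarray, q_other: np.ndarray) -> np.ndarray:
    """Best cluster permutation of ``q_other`` onto ``q_ref`` (label switching)."""
    if q_ref.shape != q_other.shape:
        raise ValueError("Q matrices must have identical shape")
    overlap = q_ref.T @ q_other
    _, perm = linear_sum_assignment(-overlap)
    return q_other[:, perm]


@dataclass
class EvannoTable:
    table: pd.DataFrame  # index K; columns mean_ln_p, sd_ln_p, n_runs, delta_k
    selected_k: int


def evanno_delta_k(runs: list[StructureRun]) -> EvannoTable:
    """Evanno second-difference statistic over replicate runs per K.

    Delta K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)), defined for interior K
    with positive replicate sd.  The selected K maximizes Delta K; ties break
    toward smaller K; if no Delta K is defined, falls back to the smallest K
    with a warning.
    """
    by_k: dict[int, list[float]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r.mean_ln_p)
    ks = sorted(by_k)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need at least 3 consecutive K values")
    if any(len(v) < 2 for v in by_k.values()):
        raise ValueError("need at least 2 replicate runs per K")
    mean = {k: float(np.mean(by_k[k])) for k in ks}
    sd = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    delta = {}
    for k in ks[1:-1]:
        if sd[k] > 0:
            delta[k] = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
        else:
            delta[k] = float("nan")
            warnings.warn(f"sd of ln P(X|K) is zero at K={k}; Delta K undefined")
    df = pd.DataFrame(
        {
            "mean_ln_p": [mean[k] for k in ks],
            "sd_ln_p": [sd[k] for k in ks],
            "n_runs": [len(by_k[k]) for k in ks],
            "delta_k": [delta.get(k, float("nan")) for k in ks],
        },
        index=pd.Index(ks, name="K"),
    )
    finite = {k: v for k, v in delta.items() if np.isfinite(v) and v > 0}
    if finite:
        best = max(finite.values())
        selected = min(k for k, v in finite.items() if v == best)
    else:
        warnings.warn("all Delta K undefined or zero; falling back to smallest K")
        selected = ks[0]
    return EvannoTable(df, selected)
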