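"""Numba kernel for the admixture-model Gibbs sampler.

Model: K clusters with independent Dirichlet(lambda) priors on per-locus
allele frequencies; each individual has admixture proportions Q with a
symmetric Dirichlet(alpha) prior; each allele copy carries a latent cluster
of origin.  alpha is updated by random-walk Metropolis under a uniform(0,10)
prior, shared across individuals.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def run_chain(
    geno,  # (n, L, 2) int32 allele indices, -1 missing
    n_alleles,  # (L,) int64
    K,
    lam,
    alpha_init,
    alpha_max,
    alpha_step,
    n_iter,
    burn_in,
    thin,
    seed,
):
    np.random.seed(seed)
    n, L, _ = geno.shape
    Amax = 0
    for l in range(L):
        if n_alleles[l] > Amax:
            Amax = n_alleles[l]

    P = np.zeros((K, L, Amax))
    for k in range(K):
        for l in range(L):
            tot = 0.0
            for a in range(n_alleles[l]):
                g = np.random.gamma(lam, 1.0)
                P[k, l, a] = g
                tot += g
            for a in range(n_alleles[l]):
                P[k, l, a] /= tot
    Q = np.full((n, K), 1.0 / K)
    alpha = alpha_init

    CP = np.zeros((K, L, Amax))
    CQ = np.zeros((n, K))
    w = np.zeros(K)

    n_rec = (n_iter - burn_in) // thin
    ll_trace = np.empty(n_rec)
    alpha_trace = np.empty(n_rec)
    Qm = np.zeros((n, K))
    Pm = np.zeros((K, L, Amax))
    rec = 0
    n_acc = 0.0

    for it in range(n_iter):
        CP[:, :, :] = 0.0
        CQ[:, :] = 0.0
        # latent origins
        for i in range(n):
            for l in range(L):
                for c in range(2):
                    a = geno[i, l, c]
                    if a < 0:
                        continue
                    tot = 0.0
                    for k in range(K):
                        w[k] = Q[i, k] * P[k, l, a]
                        tot += w[k]
                    u = np.random.random() * tot
                    acc = 0.0
                    kk = K - 1
                    for k in range(K):
                        acc += w[k]
                        if u <= acc:
                            kk = k
                            break
                    CP[kk, l, a] += 1.0
                    CQ[i, kk] += 1.0
        # allele frequencies
        for k in range(K):
            for l in range(L):
                tot = 0.0
                for a in range(n_alleles[l]):
                    g = np.random.gamma(lam + CP[k, l, a], 1.0)
                    P[k, l, a] = g
                    tot += g
                for a in range(n_alleles[l]):
                    P[k, l, a] /= tot
        # admixture proportions
        sum_ln_q = 0.0
        for i in range(n):
            tot = 0.0
            for k in range(K):
                g = np.random.gamma(alpha + CQ[i, k], 1.0)
                Q[i, k] = g
                tot += g
            for k in range(K):
                Q[i, k] /= tot
                if Q[i, k] < 1e-300:
                    Q[i, k] = 1e-300
                sum_ln_q += math.log(Q[i, k])
        # alpha Metropolis (only meaningful for K > 1)
        if K > 1:
            prop = alpha + np.random.normal() * alpha_step
            if 0.0 < prop < alpha_max:
                lr = n * (
                    math.lgamma(K * prop)
                    - K * math.lgamma(prop)
                    - math.lgamma(K * alpha)
                    + K * math.lgamma(alpha)
                ) + (prop - alpha) * sum_ln_q
                if lr >= 0.0 or np.random.random() < math.exp(lr):
                    alpha = prop
                    n_acc += 1.0
        # record
        if it >= burn_in and (it - burn_in) % thin == 0 and rec < n_rec:
            ll = 0.0
            for i in range(n):
                for l in range(L):
                    for c in range(2):
                        a = geno[i, l, c]
                        if a < 0:
                            continue
                        tot = 0.0
                        for k in range(K):
                            tot += Q[i, k] * P[k, l, a]
                        ll += math.log(tot)
            ll_trace[rec] = ll
            alpha_trace[rec] = alpha
            for i in range(n):
                for k in range(K):
                    Qm[i, k] += Q[i, k]
            for k in range(K):
                for l in range(L):
                    for a in range(Amax):
                        Pm[k, l, a] += P[k, l, a]
            rec += 1

    if rec > 0:
        Qm /= rec
        Pm /= rec
    return Qm, Pm, ll_trace[:rec], alpha_trace[:rec], n_acc / max(n_iter, 1)
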