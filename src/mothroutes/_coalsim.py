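"""Numba kernels: structured-coalescent genealogies, generalized stepwise
microsatellite mutation, and the ABC summary-statistic vector.

Time runs backward in generations.  Demes exchange lineages only through
discrete demographic events:

* MOVE  (kind 0): all lineages of deme ``a`` relocate to deme ``b``
  (the founding of ``a`` from ``b``, seen backward).
* ADMIX (kind 1): each lineage of deme ``a`` independently relocates to
  deme ``b`` with probability ``p``, else to deme ``c``.
* SIZE  (kind 2): deme ``a``'s diploid size becomes ``p``.

Between events, lineage pairs within a deme of diploid size N coalesce with
exponential waiting times at rate k(k-1)/2 / (2N) per generation.  Mutations
are Poisson on branches; a mutation moves the repeat count by +-1 with
probability 1-P and otherwise by a geometric number of steps, reflected at
the locus's allele-range bounds.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MOVE, ADMIX, SIZE = 0, 1, 2


@njit(cache=True)
def _sim_locus(copies_per_deme, sizes0, ev_time, ev_kind, ev_a, ev_b, ev_c, ev_p):
    D = copies_per_deme.shape[0]
    n = 0
    for d in range(D):
        n += copies_per_deme[d]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int32)
    times = np.zeros(n_nodes, dtype=np.float64)

    act = np.empty((D, n), dtype=np.int32)
    cnt = np.zeros(D, dtype=np.int64)
    nid = 0
    for d in range(D):
        for _ in range(copies_per_deme[d]):
            act[d, cnt[d]] = nid
            cnt[d] += 1
            nid += 1

    sizes = sizes0.copy()
    t = 0.0
    ei = 0
    n_ev = ev_time.shape[0]
    total = n
    next_id = n
    while total > 1:
        best_t = np.inf
        best_d = -1
        for d in range(D):
            k = cnt[d]
            if k >= 2 and sizes[d] > 0:
                rate = k * (k - 1) / 2.0 / (2.0 * sizes[d])
                td = t + np.random.exponential(1.0 / rate)
                if td < best_t:
                    best_t = td
                    best_d = d
        ev_t = ev_time[ei] if ei < n_ev else np.inf
        if best_d >= 0 and best_t < ev_t:
            d = best_d
            k = cnt[d]
            i1 = np.random.randint(k)
            i2 = np.random.randint(k - 1)
            if i2 >= i1:
                i2 += 1
            c1 = act[d, i1]
            c2 = act[d, i2]
            parent[c1] = next_id
            parent[c2] = next_id
            times[next_id] = best_t
            lo_i = i1 if i1 < i2 else i2
            hi_i = i2 if i1 < i2 else i1
            act[d, lo_i] = next_id
            act[d, hi_i] = act[d, k - 1]
            cnt[d] -= 1
            next_id += 1
            total -= 1
            t = best_t
        elif ei < n_ev:
            t = ev_t
            kind = ev_kind[ei]
            a = ev_a[ei]
            if kind == SIZE:
                sizes[a] = ev_p[ei]
            elif kind == MOVE:
                b = ev_b[ei]
                for i in range(cnt[a]):
                    act[b, cnt[b]] = act[a, i]
                    cnt[b] += 1
                cnt[a] = 0
            else:  # ADMIX
                b = ev_b[ei]
                c = ev_c[ei]
                p = ev_p[ei]
                for i in range(cnt[a]):
                    dest = b if np.random.random() < p else c
                    act[dest, cnt[dest]] = act[a, i]
                    cnt[dest] += 1
                cnt[a] = 0
            ei += 1
        else:
            # lineages stranded in disconnected demes: signal failure
            times[0] = -1.0
            return parent, times
    return parent, times


@njit(cache=True)
def _drop_mutations(parent, times, n_leaves, mu, p_geom, n_states):
    n_nodes = parent.shape[0]
    alleles = np.empty(n_nodes, dtype=np.int32)
    alleles[n_nodes - 1] = n_states // 2
    lo = 0
    hi = n_states - 1
    log_p = np.log(p_geom) if p_geom > 0.0 else 0.0
    for node in range(n_nodes - 2, -1, -1):
        pa = parent[node]
        a = alleles[pa]
        bl = times[pa] - times[node]
        nm = np.random.poisson(mu * bl)
        for _ in range(nm):
            if p_geom > 0.0:
                u = np.random.random()
                while u <= 0.0:
                    u = np.random.random()
                step = int(np.ceil(np.log(u) / log_p))
                if step < 1:
                    step = 1
            else:
                step = 1
            if np.random.random() < 0.5:
                step = -step
            a += step
            while a < lo or a > hi:
                if a < lo:
                    a = 2 * lo - a
                else:
                    a = 2 * hi - a
        alleles[node] = a
    return alleles


@njit(cache=True)
def sim_dataset_states(
    copies_per_deme,
    sizes0,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_c,
    ev_p,
    mu_per_locus,
    p_geom,
    n_states_per_locus,
    seed,
):
    """Simulate one multilocus dataset; returns (n_copies, L) allele-state ints.

    Returns an all -1 matrix if any locus genealogy fails to fully coalesce
    (mis-specified scenario wiring).
    """
    np.random.seed(seed)
    D = copies_per_deme.shape[0]
    n = 0
    for d in range(D):
        n += copies_per_deme[d]
    L = mu_per_locus.shape[0]
    out = np.empty((n, L), dtype=np.int32)
    for l in range(L):
        parent, times = _sim_locus(
            copies_per_deme, sizes0, ev_time, ev_kind, ev_a, ev_b, ev_c, ev_p
        )
        if times[0] < 0:
            out[:, :] = -1
            return out
        alleles = _drop_mutations(
            parent, times, n, mu_per_locus[l], p_geom, n_states_per_locus[l]
        )
        out[:, l] = alleles[:n]
    return out


# ---------------------------------------------------------------------------
# Summary statistics


@njit(cache=True)
def summary_stats(geno, ind_deme, n_demes, n_states_per_locus):
    """DIYABC-style summary vector from allele-state genotypes.

    ``geno``: (n_ind, L, 2) int32 allele states (0-based), -1 = missing.
    Layout: per deme [mean NA, mean He, mean allele-size variance,
    mean M-ratio], then per deme pair (i<j) [WC theta, mean (delta mu)^2].
    """
    n_ind, L, _ = geno.shape
    D = n_demes
    S = 0
    for l in range(L):
        if n_states_per_locus[l] > S:
            S = n_states_per_locus[l]

    # accumulators per deme x locus
    count = np.zeros((D, L, S), dtype=np.int64)  # gene copies per state
    hetc = np.zeros((D, L, S), dtype=np.int64)  # heterozygous individuals per state
    nind = np.zeros((D, L), dtype=np.int64)  # typed individuals

    for i in range(n_ind):
        d = ind_deme[i]
        for l in range(L):
            a = geno[i, l, 0]
            b = geno[i, l, 1]
            if a < 0 or b < 0:
                continue
            nind[d, l] += 1
            count[d, l, a] += 1
            count[d, l, b] += 1
            if a != b:
                hetc[d, l, a] += 1
                hetc[d, l, b] += 1

    n_pairs = D * (D - 1) // 2
    out = np.zeros(4 * D + 2 * n_pairs, dtype=np.float64)

    # one-sample statistics
    for d in range(D):
        s_na = 0.0
        s_he = 0.0
        s_var = 0.0
        s_m = 0.0
        nl = 0
        for l in range(L):
            ng = 2 * nind[d, l]
            if ng == 0:
                continue
            nl += 1
            na = 0
            sum_p2 = 0.0
            mean = 0.0
            amin = S
            amax = -1
            for s in range(n_states_per_locus[l]):
                c = count[d, l, s]
                if c > 0:
                    na += 1
                    p = c / ng
                    sum_p2 += p * p
                    mean += s * c
                    if s < amin:
                        amin = s
                    if s > amax:
                        amax = s
            mean /= ng
            var = 0.0
            if ng > 1:
                for s in range(n_states_per_locus[l]):
                    c = count[d, l, s]
                    if c > 0:
                        var += c * (s - mean) ** 2
                var /= ng - 1
            s_na += na
            if na > 1 and ng > 1:
                s_he += ng / (ng - 1.0) * (1.0 - sum_p2)
            s_var += var
            s_m += na / (amax - amin + 1.0)
        if nl > 0:
            out[4 * d] = s_na / nl
            out[4 * d + 1] = s_he / nl
            out[4 * d + 2] = s_var / nl
            out[4 * d + 3] = s_m / nl

    # two-sample statistics
    k = 0
    for d1 in range(D):
        for d2 in range(d1 + 1, D):
            sum_a = 0.0
            sum_abc = 0.0
            s_dmu = 0.0
            nl = 0
            for l in range(L):
                n1 = nind[d1, l]
                n2 = nind[d2, l]
                if n1 == 0 or n2 == 0:
                    continue
                nl += 1
                m1 = 0.0
                m2 = 0.0
                poly = 0
                for s in range(n_states_per_locus[l]):
                    if count[d1, l, s] > 0 or count[d2, l, s] > 0:
                        poly += 1
                    m1 += s * count[d1, l, s]
                    m2 += s * count[d2, l, s]
                m1 /= 2.0 * n1
                m2 /= 2.0 * n2
                s_dmu += (m1 - m2) ** 2
                if poly < 2:
                    continue
                nbar = (n1 + n2) / 2.0
                if nbar <= 1.0:
                    continue
                r = 2.0
                nc = (2.0 * nbar - (n1 * n1 + n2 * n2) / (2.0 * nbar)) / (r - 1.0)
                for s in range(n_states_per_locus[l]):
                    c1 = count[d1, l, s]
                    c2 = count[d2, l, s]
                    if c1 == 0 and c2 == 0:
                        continue
                    p1 = c1 / (2.0 * n1)
                    p2 = c2 / (2.0 * n2)
                    h1 = hetc[d1, l, s] / n1
                    h2 = hetc[d2, l, s] / n2
                    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
                    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (
                        (r - 1.0) * nbar
                    )
                    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
                    a_c = (nbar / nc) * (
                        s2
                        - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
                        / (nbar - 1.0)
                    )
                    b_c = (nbar / (nbar - 1.0)) * (
                        pbar * (1 - pbar)
                        - (r - 1) / r * s2
                        - (2 * nbar - 1) / (4 * nbar) * hbar
                    )
                    c_c = hbar / 2.0
                    sum_a += a_c
                    sum_abc += a_c + b_c + c_c
            theta = sum_a / sum_abc if sum_abc != 0.0 else 0.0
            out[4 * D + 2 * k] = theta
            out[4 * D + 2 * k + 1] = s_dmu / nl if nl > 0 else 0.0
            k += 1
    return out
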