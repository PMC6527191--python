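"""Independent oracles used by the tests.

Each function here recomputes a quantity by a route independent of the
package implementation it checks: EM point-fit of the admixture
likelihood, closed-form single-population marginal likelihood, hand-rank
Kruskal-Wallis, and a table-driven greedy family clustering.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, polygamma, psi


def em_admixture_fit(X, J, K, n_iter=500, seed=0):
    """EM point-fit of the admixture mixture likelihood.

    Maximizes sum_{i,l} 2 log sum_k q_ik p_klx over Q and P by plain EM
    (responsibilities over populations per site).  X is (N, L) dense
    allele indices with -1 missing; returns (Q, P) with P (K, L, Jmax).
    """
    rng = np.random.default_rng(seed)
    N, L = X.shape
    Jmax = int(max(J))
    Q = rng.dirichlet(np.ones(K), size=N)
    P = np.full((K, L, Jmax), 0.0)
    for l in range(L):
        P[:, l, : J[l]] = rng.dirichlet(np.ones(J[l]), size=K)
    for _ in range(n_iter):
        q_new = np.full((N, K), 1e-6)
        p_new = np.full((K, L, Jmax), 1e-6)
        for i in range(N):
            for l in range(L):
                x = X[i, l]
                if x < 0:
                    continue
                r = Q[i] * P[:, l, x]
                r = r / r.sum()
                q_new[i] += 2.0 * r
                p_new[:, l, x] += 2.0 * r
        Q = q_new / q_new.sum(axis=1, keepdims=True)
        for l in range(L):
            P[:, l, : J[l]] = (
                p_new[:, l, : J[l]]
                / p_new[:, l, : J[l]].sum(axis=1, keepdims=True)
            )
    return Q, P


def exact_k1_marginal(X, J, lam=1.0):
    """Closed-form ln Pr(X | K=1): product of Dirichlet-multinomials.

    Each locus contributes the marginal of its doubled allele counts under
    a symmetric Dirichlet(lam) prior over the observed allele set.
    """
    N, L = X.shape
    total = 0.0
    for l in range(L):
        col = X[:, l]
        obs = col[col >= 0]
        counts = np.bincount(obs, minlength=J[l]) * 2  # homozygous copies
        n = counts.sum()
        jl = J[l]
        total += (
            gammaln(jl * lam) - gammaln(jl * lam + n)
            + np.sum(gammaln(lam + counts)) - jl * gammaln(lam)
        )
    return float(total)


def analytic_k1_estimator(X, J, lam=1.0):
    """Exact expectation of the mean-var/2 estimator at K=1.

    With a single population the chain draws P iid from the posterior
    Dirichlet(lam + m) per locus, so D = sum m_lj ln p_lj has closed-form
    mean and variance through digamma / trigamma functions; the estimator
    converges (in trace length) to E[D] - V[D]/2.
    """
    N, L = X.shape
    ED = 0.0
    VD = 0.0
    for l in range(L):
        col = X[:, l]
        obs = col[col >= 0]
        m = np.bincount(obs, minlength=J[l]) * 2
        a = lam + m
        a0 = a.sum()
        ED += np.sum(m * (psi(a) - psi(a0)))
        VD += np.sum(m**2 * polygamma(1, a)) - polygamma(1, a0) * m.sum() ** 2
    return float(ED - VD / 2.0)


def kruskal_h_by_hand(groups):
    """Kruskal-Wallis H from first principles (mid-ranks, tie correction)."""
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    order = np.argsort(flat, kind="stable")
    ranks = np.empty(len(flat))
    sorted_vals = flat[order]
    i = 0
    while i < len(flat):
        j = i
        while j < len(flat) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mid-rank, 1-based
        i = j
    n_total = len(flat)
    h = 0.0
    pos = 0
    for g in groups:
        n = len(g)
        rbar = ranks[pos:pos + n].mean()
        h += n * (rbar - (n_total + 1) / 2.0) ** 2
        pos += n
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(flat, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / tie


def greedy_families_from_table(ids, lengths, match):
    """Greedy centroid clustering driven by a precomputed match table.

    ``match[(a, b)]`` says whether a and b satisfy the family rule.
    Mirrors the documented recursion: longest first (ties by id), join the
    first matching representative, else found a new family.
    """
    order = sorted(ids, key=lambda s: (-lengths[s], s))
    family_of, reps = {}, []
    for sid in order:
        for fam, rep in enumerate(reps):
            if match[(sid, rep)]:
                family_of[sid] = fam
                break
        else:
            family_of[sid] = len(reps)
            reps.append(sid)
    return family_of, reps
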