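"""Numba Gibbs-sweep kernel for the admixture model.

Hot loop of the sampler: kept free of Python objects, with an inline
xorshift128+ generator so every run is a pure function of its integer
seed.  The wrapper in :mod:`ltrpopgen.mcmc` owns validation, allele-code
mapping and posterior summaries.

Numerical notes: the two allele-copy draws at each site share one 64-bit
random word (26 bits of resolution each, ample for categorical sampling
over <= 21 states); the complete-data log-likelihood is accumulated as
sum(m * log p) over the nonzero assignment counts, which is exactly the
per-copy sum but touches only occupied (population, locus, allele) cells.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, literally

_U11 = np.uint64(11)
_U12 = np.uint64(12)
_U17 = np.uint64(17)
_U23 = np.uint64(23)
_U26 = np.uint64(26)
_U27 = np.uint64(27)
_U30 = np.uint64(30)
_U31 = np.uint64(31)
_U38 = np.uint64(38)
_M26 = np.uint64(0x3FFFFFF)
_SM1 = np.uint64(0x9E3779B97F4A7C15)
_SM2 = np.uint64(0xBF58476D1CE4E5B9)
_SM3 = np.uint64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0   # 2^-53
_INV26 = 1.0 / 67108864.0           # 2^-26


@njit(cache=True, inline="always")
def _u64(st):
    s1 = st[0]
    s0 = st[1]
    st[0] = s0
    s1 ^= s1 << _U23
    s1 ^= s1 >> _U17
    s1 ^= s0
    s1 ^= s0 >> _U26
    st[1] = s1
    return s0 + s1


@njit(cache=True, inline="always")
def _unif(st):
    # open interval (0, 1): safe under log()
    return ((_u64(st) >> _U11) + np.uint64(1)) * _INV53


@njit(cache=True)
def _seed_state(seed, st):
    z = seed
    for i in range(2):
        z = z + _SM1
        w = z
        w = (w ^ (w >> _U30)) * _SM2
        w = (w ^ (w >> _U27)) * _SM3
        st[i] = w ^ (w >> _U31)


@njit(cache=True, inline="always")
def _normal(st, spare):
    """Polar-method normal with the second variate cached in ``spare``."""
    if spare[0] != 0.0:
        v = spare[1]
        spare[0] = 0.0
        return v
    while True:
        u = 2.0 * _unif(st) - 1.0
        v = 2.0 * _unif(st) - 1.0
        s = u * u + v * v
        if 0.0 < s < 1.0:
            f = math.sqrt(-2.0 * math.log(s) / s)
            spare[0] = 1.0
            spare[1] = v * f
            return u * f


@njit(cache=True, inline="always")
def _gamma(st, spare, a):
    """Marsaglia-Tsang gamma variate; shape-1 fast path is an exponential."""
    boost = 1.0
    if a < 1.0:
        boost = math.pow(_unif(st), 1.0 / a)
        a = a + 1.0
    elif a == 1.0:
        return -math.log(_unif(st))
    d = a - 1.0 / 3.0
    c = 1.0 / math.sqrt(9.0 * d)
    while True:
        x = _normal(st, spare)
        t = 1.0 + c * x
        if t <= 0.0:
            continue
        v = t * t * t
        u = _unif(st)
        x2 = x * x
        if u < 1.0 - 0.0331 * x2 * x2:
            return boost * d * v
        if math.log(u) < 0.5 * x2 + d * (1.0 - v + math.log(v)):
            return boost * d * v


@njit(cache=True)
def gibbs_kernel(Xt, Jl, K, burnin, iters, lam,
                 alpha0, alpha_max, alpha_sd, infer_alpha,
                 correlated, f_shape, f_rate, f_prop_sd, pa_prop,
                 seed):
    """Run burnin+iters sweeps of the admixture Gibbs sampler.

    Xt : (L, N) int8, dense per-locus allele indices, -1 = missing.
    Jl : (L,) number of observed alleles per locus.
    Returns posterior means of Q (N,K), P (L,Jmax,K), the post-burn-in
    complete-data log-likelihood trace, the alpha trace, and mean F per
    population (prior mean under the independent model).

    K is specialized as a compile-time literal so the per-population
    inner loops unroll.
    """
    return _gibbs_impl(Xt, Jl, literally(K), burnin, iters, lam,
                       alpha0, alpha_max, alpha_sd, infer_alpha,
                       correlated, f_shape, f_rate, f_prop_sd, pa_prop,
                       seed)


@njit(cache=True, fastmath=True)
def _gibbs_impl(Xt, Jl, K, burnin, iters, lam,
                alpha0, alpha_max, alpha_sd, infer_alpha,
                correlated, f_shape, f_rate, f_prop_sd, pa_prop,
                seed):
    L, N = Xt.shape
    Jmax = 1
    for l in range(L):
        if Jl[l] > Jmax:
            Jmax = Jl[l]
    st = np.empty(2, dtype=np.uint64)
    _seed_state(np.uint64(seed), st)
    spare = np.zeros(2)

    Q = np.empty((N, K))
    P = np.zeros((L, Jmax, K))
    PA = np.zeros((L, Jmax))
    F = np.full(K, f_shape / f_rate)
    alpha = alpha0

    # draw the initial state from the priors
    for i in range(N):
        s = 0.0
        for k in range(K):
            g = _gamma(st, spare, alpha)
            if g < 1e-300:
                g = 1e-300
            Q[i, k] = g
            s += g
        for k in range(K):
            Q[i, k] /= s
    for l in range(L):
        for k in range(K):
            s = 0.0
            for j in range(Jl[l]):
                g = _gamma(st, spare, lam)
                P[l, j, k] = g
                s += g
            for j in range(Jl[l]):
                P[l, j, k] /= s
    if correlated:
        for l in range(L):
            s = 0.0
            for j in range(Jl[l]):
                g = _gamma(st, spare, lam)
                PA[l, j] = g
                s += g
            for j in range(Jl[l]):
                PA[l, j] /= s

    nik = np.zeros((N, K), dtype=np.int32)
    m = np.zeros((L, Jmax, K), dtype=np.int32)
    w = np.empty(K)

    Qsum = np.zeros((N, K))
    Psum = np.zeros((L, Jmax, K))
    Fsum = np.zeros(K)
    loglik_trace = np.empty(iters)
    alpha_trace = np.empty(iters)
    p_thin = 10  # accumulate the (large) P mean every 10th recorded sweep
    n_psum = 0

    total = burnin + iters

    if K == 1 and not correlated:
        # single population: all origins are fixed, counts never change,
        # so the chain reduces to iid P | X draws (exact fast path)
        for l in range(L):
            for i in range(N):
                x = Xt[l, i]
                if x >= 0:
                    m[l, x, 0] += 2
        for i in range(N):
            Q[i, 0] = 1.0
            Qsum[i, 0] = float(iters)
        for sweep in range(total):
            rec = sweep >= burnin
            if rec:
                ll = 0.0
                for l in range(L):
                    for j in range(Jl[l]):
                        mc = m[l, j, 0]
                        if mc > 0:
                            ll += mc * math.log(P[l, j, 0])
                t = sweep - burnin
                loglik_trace[t] = ll
                alpha_trace[t] = alpha
            for l in range(L):
                s = 0.0
                for j in range(Jl[l]):
                    g = _gamma(st, spare, lam + m[l, j, 0])
                    if g < 1e-300:
                        g = 1e-300
                    P[l, j, 0] = g
                    s += g
                inv = 1.0 / s
                for j in range(Jl[l]):
                    P[l, j, 0] *= inv
            if rec:
                t = sweep - burnin
                if t % p_thin == 0:
                    n_psum += 1
                    for l in range(L):
                        for j in range(Jl[l]):
                            Psum[l, j, 0] += P[l, j, 0]
                Fsum[0] += F[0]
        return (Qsum * (1.0 / iters), Psum * (1.0 / n_psum),
                loglik_trace, alpha_trace, Fsum * (1.0 / iters))

    for sweep in range(total):
        rec = sweep >= burnin
        # --- (1) Z | Q, P : two independent copies per non-missing site
        for i in range(N):
            for k in range(K):
                nik[i, k] = 0
        for l in range(L):
            for j in range(Jl[l]):
                for k in range(K):
                    m[l, j, k] = 0
        for l in range(L):
            for i in range(N):
                x = Xt[l, i]
                if x < 0:
                    continue
                tot = 0.0
                for k in range(K):
                    wk = Q[i, k] * P[l, x, k]
                    w[k] = wk
                    tot += wk
                r = _u64(st)
                u1 = ((r >> _U38) + np.uint64(1)) * _INV26 * tot
                u2 = (((r >> _U12) & _M26) + np.uint64(1)) * _INV26 * tot
                acc = 0.0
                k1 = K - 1
                for k in range(K - 1):
                    acc += w[k]
                    if u1 < acc:
                        k1 = k
                        break
                acc = 0.0
                k2 = K - 1
                for k in range(K - 1):
                    acc += w[k]
                    if u2 < acc:
                        k2 = k
                        break
                nik[i, k1] += 1
                nik[i, k2] += 1
                m[l, x, k1] += 1
                m[l, x, k2] += 1
        # complete-data log-likelihood of (Z, P) before P moves on:
        # sum over copies of log p equals sum over occupied cells of m*log p
        if rec:
            ll = 0.0
            for l in range(L):
                for j in range(Jl[l]):
                    for k in range(K):
                        mc = m[l, j, k]
                        if mc > 0:
                            ll += mc * math.log(P[l, j, k])
            loglik_trace[sweep - burnin] = ll

        # --- (2) P | Z (plus F and ancestral frequencies in the F-model)
        if not correlated:
            for l in range(L):
                for k in range(K):
                    s = 0.0
                    for j in range(Jl[l]):
                        g = _gamma(st, spare, lam + m[l, j, k])
                        if g < 1e-300:
                            g = 1e-300
                        P[l, j, k] = g
                        s += g
                    inv = 1.0 / s
                    for j in range(Jl[l]):
                        P[l, j, k] *= inv
        else:
            for k in range(K):
                ck = (1.0 - F[k]) / F[k]
                for l in range(L):
                    s = 0.0
                    for j in range(Jl[l]):
                        g = _gamma(st, spare, PA[l, j] * ck + m[l, j, k])
                        if g < 1e-300:
                            g = 1e-300
                        P[l, j, k] = g
                        s += g
                    inv = 1.0 / s
                    for j in range(Jl[l]):
                        P[l, j, k] *= inv
            # Metropolis step on each drift parameter F_k (gamma prior)
            for k in range(K):
                fp = F[k] + f_prop_sd * _normal(st, spare)
                if fp <= 0.0 or fp >= 1.0:
                    continue
                c_old = (1.0 - F[k]) / F[k]
                c_new = (1.0 - fp) / fp
                lr = ((f_shape - 1.0) * (math.log(fp) - math.log(F[k]))
                      - f_rate * (fp - F[k]))
                for l in range(L):
                    lr += math.lgamma(c_new) - math.lgamma(c_old)
                    for j in range(Jl[l]):
                        a_old = PA[l, j] * c_old
                        a_new = PA[l, j] * c_new
                        lr += (math.lgamma(a_old) - math.lgamma(a_new)
                               + (a_new - a_old) * math.log(P[l, j, k]))
                if math.log(_unif(st)) < lr:
                    F[k] = fp
            # Metropolis step on ancestral frequencies: shift mass between
            # a random allele pair at each locus
            for l in range(L):
                jn = Jl[l]
                if jn < 2:
                    continue
                j1 = int(_unif(st) * jn)
                j2 = int(_unif(st) * jn)
                if j1 == j2 or j1 >= jn or j2 >= jn:
                    continue
                d = (_unif(st) * 2.0 - 1.0) * pa_prop
                a1 = PA[l, j1] + d
                a2 = PA[l, j2] - d
                if a1 <= 0.0 or a2 <= 0.0:
                    continue
                lr = (lam - 1.0) * (math.log(a1) - math.log(PA[l, j1])
                                    + math.log(a2) - math.log(PA[l, j2]))
                for k in range(K):
                    ck = (1.0 - F[k]) / F[k]
                    lr += (math.lgamma(PA[l, j1] * ck) - math.lgamma(a1 * ck)
                           + math.lgamma(PA[l, j2] * ck) - math.lgamma(a2 * ck)
                           + (a1 - PA[l, j1]) * ck * math.log(P[l, j1, k])
                           + (a2 - PA[l, j2]) * ck * math.log(P[l, j2, k]))
                if math.log(_unif(st)) < lr:
                    PA[l, j1] = a1
                    PA[l, j2] = a2

        # --- (3) Q | Z
        sumlogq = 0.0
        for i in range(N):
            s = 0.0
            for k in range(K):
                g = _gamma(st, spare, alpha + nik[i, k])
                if g < 1e-300:
                    g = 1e-300
                Q[i, k] = g
                s += g
            inv = 1.0 / s
            for k in range(K):
                q = Q[i, k] * inv
                if q < 1e-300:
                    q = 1e-300
                Q[i, k] = q
                sumlogq += math.log(q)

        # --- (4) Metropolis step on alpha (uniform prior on (0, alpha_max))
        if infer_alpha and K > 1:
            ap = alpha + alpha_sd * _normal(st, spare)
            if 0.0 < ap < alpha_max:
                lr = (N * (math.lgamma(K * ap) - K * math.lgamma(ap)
                           - math.lgamma(K * alpha) + K * math.lgamma(alpha))
                      + (ap - alpha) * sumlogq)
                if math.log(_unif(st)) < lr:
                    alpha = ap

        if rec:
            t = sweep - burnin
            alpha_trace[t] = alpha
            for i in range(N):
                for k in range(K):
                    Qsum[i, k] += Q[i, k]
            if t % p_thin == 0:
                n_psum += 1
                for l in range(L):
                    for j in range(Jl[l]):
                        for k in range(K):
                            Psum[l, j, k] += P[l, j, k]
            for k in range(K):
                Fsum[k] += F[k]

    return (Qsum * (1.0 / iters), Psum * (1.0 / n_psum),
            loglik_trace, alpha_trace, Fsum * (1.0 / iters))
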