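"""Numba kernel for the mixture-prior (BayesR-style) Gibbs sampler.

The model, for a residualized phenotype y (scaled to unit variance) and
column-standardized predictors X:

    y = X beta + eps,   eps_i ~ N(0, sigma2_e)
    beta_j ~ pi_0 * delta_0 + sum_k pi_k * N(0, gamma_k)
    (pi_0, ..., pi_K) ~ Dirichlet(1, ..., 1)
    sigma2_e ~ scaled-inverse-chi2(nu0, s0sq)

gamma_k are the mixture variances (fractions of phenotypic variance, since y
has unit variance).  Each sweep visits CpGs in a pseudo-random order keyed on
(CpG identity hash, sweep, seed) — attached to identities rather than column
positions so that permuting the columns of X permutes the chain exactly —
and draws component membership and effect from the conjugate conditionals,
keeping the residual vector r = y - X beta up to date so each CpG update is
O(n).  Every update consumes a fixed number of random draws, which makes the
chain bit-reproducible and column-permutation-equivariant for a fixed seed.
"""

import numpy as np
from numba import njit

# Kernel algorithm version: bump if the update order or RNG stream changes,
# since stored chains are only comparable within a version.
KERNEL_VERSION = 2

_C1 = np.uint64(0x9E3779B97F4A7C15)
_C2 = np.uint64(0xD6E8FEB86659FD93)


@njit(cache=True)
def _mix64(z):
    # splitmix64 finalizer
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def _sample_dirichlet(alpha):
    out = np.empty(alpha.shape[0])
    total = 0.0
    for i in range(alpha.shape[0]):
        g = np.random.gamma(alpha[i], 1.0)
        out[i] = g
        total += g
    return out / total


@njit(cache=True)
def run_chain(
    Xt,            # (p, n) C-contiguous: predictors, transposed so rows are CpGs
    y,             # (n,)
    id_hash,       # (p,) uint64 stable hash of each CpG identifier
    gammas,        # (K,) mixture variances, increasing
    n_sweeps,      # burn_in + retained (pre-thinning)
    burn_in,
    thin,
    nu0,
    s0sq,
    seed,
    fixed_sigma2,  # > 0: hold sigma2_e at this value (conjugate-oracle mode)
    fixed_pi,      # (K+1,) sums to 1: hold mixture proportions; else size 0
):
    p, n = Xt.shape
    K = gammas.shape[0]
    np.random.seed(seed)
    seed_mix = _mix64(np.uint64(seed) * _C2 + _C1)

    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xtx[j] = s

    beta = np.zeros(p)
    comp = np.zeros(p, dtype=np.int8)  # 0 = null, 1..K = slab index
    r = y.copy()

    use_fixed_pi = fixed_pi.shape[0] == K + 1
    if use_fixed_pi:
        pi = fixed_pi.copy()
    else:
        # Sparse start: beta = 0 for every CpG, so begin with most of the
        # mixture mass on the null component (the BayesR-family convention);
        # starting uniform instead floods the smallest slab on sweep 1, which
        # a short burn-in cannot undo.
        pi = np.empty(K + 1)
        pi[0] = 0.95
        for k in range(K):
            pi[k + 1] = 0.05 / K
    sigma2 = fixed_sigma2 if fixed_sigma2 > 0.0 else np.var(y)

    n_stored = (n_sweeps - burn_in + thin - 1) // thin
    betas = np.zeros((n_stored, p))
    comps = np.zeros((n_stored, p), dtype=np.int8)
    sigma2s = np.zeros(n_stored)
    pis = np.zeros((n_stored, K + 1))
    fit_vars = np.zeros(n_stored)  # var(X beta) via the maintained residual

    logw = np.empty(K + 1)
    key = np.empty(p, dtype=np.uint64)
    store = 0
    for sweep in range(n_sweeps):
        sweep_mix = _mix64(np.uint64(sweep) * _C1 ^ seed_mix)
        for j in range(p):
            key[j] = _mix64(id_hash[j] ^ sweep_mix)
        order = np.argsort(key)

        for idx in range(p):
            j = order[idx]
            bj = beta[j]
            # rhs = X_j' (r + X_j * bj): residual with CpG j's effect put back
            rhs = bj * xtx[j]
            for i in range(n):
                rhs += Xt[j, i] * r[i]

            logw[0] = np.log(pi[0]) if pi[0] > 0.0 else -np.inf
            for k in range(K):
                v_k = 1.0 / (xtx[j] / sigma2 + 1.0 / gammas[k])
                m_k = v_k * rhs / sigma2
                if pi[k + 1] > 0.0:
                    logw[k + 1] = (
                        np.log(pi[k + 1])
                        + 0.5 * np.log(v_k / gammas[k])
                        + 0.5 * m_k * m_k / v_k
                    )
                else:
                    logw[k + 1] = -np.inf

            wmax = logw[0]
            for k in range(1, K + 1):
                if logw[k] > wmax:
                    wmax = logw[k]
            wsum = 0.0
            for k in range(K + 1):
                logw[k] = np.exp(logw[k] - wmax)
                wsum += logw[k]
            u = np.random.random() * wsum
            knew = K
            acc = 0.0
            for k in range(K + 1):
                acc += logw[k]
                if u <= acc:
                    knew = k
                    break

            # one normal per update regardless of the chosen component, so the
            # RNG stream position never depends on the sampled path
            zdraw = np.random.normal()
            if knew == 0:
                bnew = 0.0
            else:
                v_k = 1.0 / (xtx[j] / sigma2 + 1.0 / gammas[knew - 1])
                m_k = v_k * rhs / sigma2
                bnew = m_k + np.sqrt(v_k) * zdraw
            comp[j] = knew
            delta = bnew - bj
            if delta != 0.0:
                for i in range(n):
                    r[i] -= Xt[j, i] * delta
            beta[j] = bnew

        if fixed_sigma2 <= 0.0:
            sse = 0.0
            for i in range(n):
                sse += r[i] * r[i]
            # scaled-inv-chi2(nu0 + n, (nu0*s0sq + sse)/(nu0 + n))
            sigma2 = (nu0 * s0sq + sse) / np.random.chisquare(nu0 + n)

        if not use_fixed_pi:
            alpha = np.ones(K + 1)
            for j in range(p):
                alpha[comp[j]] += 1.0
            pi = _sample_dirichlet(alpha)

        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            betas[store] = beta
            comps[store] = comp
            sigma2s[store] = sigma2
            pis[store] = pi
            fmean = 0.0
            for i in range(n):
                fmean += y[i] - r[i]
            fmean /= n
            fss = 0.0
            for i in range(n):
                d = y[i] - r[i] - fmean
                fss += d * d
            fit_vars[store] = fss / n
            store += 1

    return betas, comps, sigma2s, pis, fit_vars
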