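"""Numba kernels shared by likelihood evaluation, MCMC and the mixture.

Everything that touches choice sequences trial-by-trial funnels through
``seq_loglik`` so the likelihood used by the samplers is byte-identical
to the one exercised by the unit tests. Parameters arrive on their
natural scale in each model's canonical order (see
``agent_models.MODELS``).

Model ids:
  0 m1a   RL, single learning rate
  1 m1b   RL, separate win/no-win learning rates
  2 m1c   RL, nonlinear utility
  3 m2a   Bayesian ideal observer (BIO), single update rate
  4 m2b   BIO, separate win/no-win update rates
  5 m2c   BIO, nonlinear utility
  6 m2d   BIO, uncertainty bonus/penalty
  7 gf_rl  gambler's-fallacy RL (negative learning rate, utility)
  8 gf_bio gambler's-fallacy BIO (negative update rates)
  9 eps   outcome-insensitive epsilon-risky
"""

import math

import numpy as np
from numba import njit

M1A, M1B, M1C, M2A, M2B, M2C, M2D, GF_RL, GF_BIO, EPS = range(10)

V_SURE = 10.0
BETA_FLOOR = 0.001  # pseudo-count floor keeping the Beta proper
C1 = 2.0            # fixed initial Beta concentration a1 + b1

_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _norm_cdf(z):
    return 0.5 * (1.0 + math.erf(z / _SQRT2))


@njit(cache=True)
def _log_sigmoid(x):
    # log(1/(1+exp(-x))), stable for large |x|
    if x >= 0.0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


@njit(cache=True)
def seq_loglik(mid, th, choices, outcomes, resets):
    """Log likelihood of one subject's choice sequence.

    choices: 1 = risky, 0 = sure; outcomes in cents {0, 10, 20};
    resets: 1 where the belief re-initializes (first trial of a block).
    """
    T = choices.shape[0]
    ll = 0.0

    if mid == EPS:
        eps = th[0]
        lp_r = math.log(eps)
        lp_s = math.log1p(-eps)
        for t in range(T):
            ll += lp_r if choices[t] == 1 else lp_s
        return ll

    # unpack to a common parameterization
    rl = mid == M1A or mid == M1B or mid == M1C or mid == GF_RL
    kappa = 1.0
    phi = 0.0
    if mid == M1A:
        rate_w, rate_l, beta, init = th[0], th[0], th[1], th[2]
    elif mid == M1B:
        rate_w, rate_l, beta, init = th[0], th[1], th[2], th[3]
    elif mid == M1C or mid == GF_RL:
        rate_w, rate_l, kappa, beta, init = th[0], th[0], th[1], th[2], th[3]
    elif mid == M2A:
        rate_w, rate_l, beta, init = th[0], th[0], th[1], th[2]
    elif mid == M2B or mid == GF_BIO:
        rate_w, rate_l, beta, init = th[0], th[1], th[2], th[3]
    elif mid == M2C:
        rate_w, rate_l, kappa, beta, init = th[0], th[0], th[1], th[2], th[3]
    else:  # M2D
        rate_w, rate_l, phi, beta, init = th[0], th[0], th[1], th[2], th[3]

    u20 = 10.0 * 2.0 ** kappa

    q = 0.0
    a = 1.0
    b = 1.0
    for t in range(T):
        if resets[t] == 1:
            if rl:
                q = init
            else:
                a = init
                b = C1 - init
        if rl:
            v = q
        else:
            mu = a / (a + b)
            v = u20 * mu
            if phi != 0.0:
                sd = math.sqrt(a * b / ((a + b) * (a + b) * (a + b + 1.0)))
                v += phi * 20.0 * sd
        x = beta * (v - V_SURE)
        if choices[t] == 1:
            ll += _log_sigmoid(x)
            won = outcomes[t] == 20
            if rl:
                u = u20 if won else 0.0
                r = rate_w if won else rate_l
                q = q + r * (u - q)
            else:
                if won:
                    a = max(a + rate_w, BETA_FLOOR)
                else:
                    b = max(b + rate_l, BETA_FLOOR)
        else:
            ll += _log_sigmoid(-x)
    return ll


@njit(cache=True)
def batch_loglik(mid, thetas, choices, outcomes, resets):
    """Log likelihood for B (theta, sequence) pairs; all arrays (B, ...)."""
    B = choices.shape[0]
    out = np.empty(B)
    for i in range(B):
        out[i] = seq_loglik(mid, thetas[i], choices[i], outcomes[i], resets[i])
    return out


@njit(cache=True)
def marginal_loglik(mid, lo, hi, choices, outcomes, resets, n_draws, seed):
    """log p(data | model) under a uniform prior over the parameter box.

    Plain Monte-Carlo integration: theta ~ U(box), logsumexp of the
    per-draw log likelihoods minus log n_draws.
    """
    np.random.seed(seed)
    P = lo.shape[0]
    lls = np.empty(n_draws)
    th = np.empty(P)
    for d in range(n_draws):
        for p in range(P):
            th[p] = lo[p] + (hi[p] - lo[p]) * np.random.rand()
        lls[d] = seq_loglik(mid, th, choices, outcomes, resets)
    m = lls.max()
    s = 0.0
    for d in range(n_draws):
        s += math.exp(lls[d] - m)
    return m + math.log(s / n_draws)


@njit(cache=True)
def _map_box(z, lo, hi, out):
    for p in range(z.shape[0]):
        out[p] = lo[p] + (hi[p] - lo[p]) * _norm_cdf(z[p])


@njit(cache=True)
def run_chain(mid, lo, hi, choices, outcomes, resets,
              n_warmup, n_keep, seed, prior_m_sd, prior_s_scale):
    """One MCMC chain for the two-level hierarchical model.

    Unconstrained subject scores z[s, p] ~ Normal(M[p], S[p]) are mapped
    through the scaled probit to each parameter's box. Priors:
    M ~ Normal(0, prior_m_sd), S ~ half-Normal(prior_s_scale).

    Sampler, per sweep:
      * subject blocks (conditionally independent given M, S):
        coordinate-wise random-walk Metropolis during the first third of
        warmup, then joint adaptive-Metropolis proposals whose covariance
        is the running empirical posterior covariance of each subject's
        scores (subject parameters are strongly correlated a posteriori);
      * conjugate Gibbs for each group mean M;
      * log-scale Metropolis for each group sd S;
      * two parameter-expansion moves that cut through the hierarchical
        funnel: joint rescale (z, S) -> (M + c (z - M), c S) and joint
        translation (z, M) -> (z + d, M + d).
    All proposal scales adapt during warmup only.

    Returns (z draws, M draws, S draws, deviance draws).
    """
    np.random.seed(seed)
    n, T = choices.shape
    P = lo.shape[0]

    z = np.random.randn(n, P) * 0.1
    M = np.zeros(P)
    S = np.ones(P)

    step_z = np.full((n, P), 0.5)
    scale_j = np.full(n, 1.0)
    step_s = np.full(P, 0.4)
    step_c = np.full(P, 0.3)
    scale_t = 1.0
    acc_z = np.zeros((n, P))
    acc_j = np.zeros(n)
    acc_s = np.zeros(P)
    acc_c = np.zeros(P)
    acc_t = 0.0
    dvec = np.empty(P)

    th = np.empty(P)
    zs_new = np.empty(P)
    prop_ll = np.empty(n)
    cur_ll = np.empty(n)
    for s in range(n):
        _map_box(z[s], lo, hi, th)
        cur_ll[s] = seq_loglik(mid, th, choices[s], outcomes[s], resets[s])

    # running moments for the per-subject proposal covariance
    zsum = np.zeros((n, P))
    zouter = np.zeros((n, P, P))
    n_acc = 0
    L = np.zeros((n, P, P))       # Cholesky factors of proposal covariance
    switch = max(100, n_warmup // 3)
    have_l = False
    # running moments of the group means for the translation move
    msum = np.zeros(P)
    mouter = np.zeros((P, P))
    L_m = np.zeros((P, P))
    have_lm = False

    out_z = np.empty((n_keep, n, P))
    out_m = np.empty((n_keep, P))
    out_s = np.empty((n_keep, P))
    out_dev = np.empty(n_keep)

    total = n_warmup + n_keep
    window = 25
    for it in range(total):
        if not have_l:
            # coordinate-wise subject updates (early warmup)
            for p in range(P):
                for s in range(n):
                    old = z[s, p]
                    z[s, p] = old + step_z[s, p] * np.random.randn()
                    _map_box(z[s], lo, hi, th)
                    ll = seq_loglik(mid, th, choices[s], outcomes[s],
                                    resets[s])
                    dpri = (-0.5 * ((z[s, p] - M[p]) / S[p]) ** 2
                            + 0.5 * ((old - M[p]) / S[p]) ** 2)
                    if math.log(np.random.rand()) < ll - cur_ll[s] + dpri:
                        cur_ll[s] = ll
                        acc_z[s, p] += 1.0
                    else:
                        z[s, p] = old
        else:
          # joint adaptive-Metropolis subject updates, several per sweep
          # so the subject blocks decorrelate as fast as the group level
          for _rep in range(4):
            for s in range(n):
                dpri = 0.0
                eps = np.random.randn(P)
                for p in range(P):
                    step = 0.0
                    for q in range(p + 1):
                        step += L[s, p, q] * eps[q]
                    zs_new[p] = z[s, p] + scale_j[s] * step
                _map_box(zs_new, lo, hi, th)
                ll = seq_loglik(mid, th, choices[s], outcomes[s], resets[s])
                for p in range(P):
                    dpri += (-0.5 * ((zs_new[p] - M[p]) / S[p]) ** 2
                             + 0.5 * ((z[s, p] - M[p]) / S[p]) ** 2)
                if math.log(np.random.rand()) < ll - cur_ll[s] + dpri:
                    cur_ll[s] = ll
                    for p in range(P):
                        z[s, p] = zs_new[p]
                    acc_j[s] += 1.0

        # group mean: Normal prior x Normal likelihood, exact Gibbs
        for p in range(P):
            prec = 1.0 / prior_m_sd ** 2 + n / S[p] ** 2
            mean = (z[:, p].sum() / S[p] ** 2) / prec
            M[p] = mean + math.sqrt(1.0 / prec) * np.random.randn()

        # group sd: Metropolis on log S with half-Normal prior
        for p in range(P):
            rss = 0.0
            for s in range(n):
                rss += (z[s, p] - M[p]) ** 2
            old = S[p]
            new = old * math.exp(step_s[p] * np.random.randn())
            lt_old = (-n * math.log(old) - rss / (2.0 * old ** 2)
                      - old ** 2 / (2.0 * prior_s_scale ** 2) + math.log(old))
            lt_new = (-n * math.log(new) - rss / (2.0 * new ** 2)
                      - new ** 2 / (2.0 * prior_s_scale ** 2) + math.log(new))
            if math.log(np.random.rand()) < lt_new - lt_old:
                S[p] = new
                acc_s[p] += 1.0

        # joint rescale: (z, S) -> (M + c (z - M), c S); the z prior and
        # the Jacobian cancel up to a factor log c
        for p in range(P):
            c = math.exp(step_c[p] * np.random.randn())
            new_s = c * S[p]
            delta = 0.0
            for s in range(n):
                old = z[s, p]
                z[s, p] = M[p] + c * (old - M[p])
                _map_box(z[s], lo, hi, th)
                prop_ll[s] = seq_loglik(mid, th, choices[s], outcomes[s],
                                        resets[s])
                delta += prop_ll[s] - cur_ll[s]
                z[s, p] = old
            delta += (-(new_s ** 2 - S[p] ** 2)
                      / (2.0 * prior_s_scale ** 2) + math.log(c))
            if math.log(np.random.rand()) < delta:
                for s in range(n):
                    z[s, p] = M[p] + c * (z[s, p] - M[p])
                    cur_ll[s] = prop_ll[s]
                S[p] = new_s
                acc_c[p] += 1.0

        # joint translation: (z, M) -> (z + d, M + d) for a random vector
        # d; the z prior is invariant, only the likelihood and the M
        # prior change. Early on d is axis-aligned; once the running
        # covariance of M is available d follows it, so the group level
        # can slide along likelihood ridges (e.g. the near-trade-off
        # between the two update rates and the inverse temperature).
        for _rep in range(4):
            if have_lm:
                eps = np.random.randn(P)
                for p in range(P):
                    acc = 0.0
                    for q in range(p + 1):
                        acc += L_m[p, q] * eps[q]
                    dvec[p] = scale_t * acc
            else:
                for p in range(P):
                    dvec[p] = 0.0
                dvec[it % P] = 0.1 * np.random.randn()
            delta = 0.0
            for p in range(P):
                new_m = M[p] + dvec[p]
                delta += -(new_m ** 2 - M[p] ** 2) / (2.0 * prior_m_sd ** 2)
            for s in range(n):
                for p in range(P):
                    zs_new[p] = z[s, p] + dvec[p]
                _map_box(zs_new, lo, hi, th)
                prop_ll[s] = seq_loglik(mid, th, choices[s], outcomes[s],
                                        resets[s])
                delta += prop_ll[s] - cur_ll[s]
            if math.log(np.random.rand()) < delta:
                for s in range(n):
                    for p in range(P):
                        z[s, p] += dvec[p]
                    cur_ll[s] = prop_ll[s]
                for p in range(P):
                    M[p] += dvec[p]
                acc_t += 1.0

        # accumulate moments and refresh proposal covariances (warmup)
        if it < n_warmup:
            n_acc += 1
            for s in range(n):
                for p in range(P):
                    zsum[s, p] += z[s, p]
                    for q in range(P):
                        zouter[s, p, q] += z[s, p] * z[s, q]
            for p in range(P):
                msum[p] += M[p]
                for q in range(P):
                    mouter[p, q] += M[p] * M[q]
            if it + 1 >= switch and (it + 1 - switch) % 100 == 0:
                cov = np.empty((P, P))
                for s in range(n):
                    for p in range(P):
                        for q in range(P):
                            cov[p, q] = (zouter[s, p, q] / n_acc
                                         - (zsum[s, p] / n_acc)
                                         * (zsum[s, q] / n_acc))
                        cov[p, p] += 1e-5
                    L[s] = np.linalg.cholesky(
                        cov * (2.38 ** 2 / P))
                have_l = True
                for p in range(P):
                    for q in range(P):
                        cov[p, q] = (mouter[p, q] / n_acc
                                     - (msum[p] / n_acc) * (msum[q] / n_acc))
                    cov[p, p] += 1e-6
                L_m = np.linalg.cholesky(cov * (2.38 ** 2 / P))
                have_lm = True

        # proposal step-size adaptation, warmup only
        if it < n_warmup and (it + 1) % window == 0:
            for s in range(n):
                rate = acc_j[s] / window
                if rate < 0.2:
                    scale_j[s] *= 0.7
                elif rate > 0.4:
                    scale_j[s] *= 1.4
                acc_j[s] = 0.0
            for p in range(P):
                for s in range(n):
                    rate = acc_z[s, p] / window
                    if rate < 0.25:
                        step_z[s, p] *= 0.7
                    elif rate > 0.5:
                        step_z[s, p] *= 1.4
                    acc_z[s, p] = 0.0
                rate = acc_s[p] / window
                if rate < 0.25:
                    step_s[p] *= 0.7
                elif rate > 0.5:
                    step_s[p] *= 1.4
                acc_s[p] = 0.0
                rate = acc_c[p] / window
                if rate < 0.25:
                    step_c[p] *= 0.7
                elif rate > 0.5:
                    step_c[p] *= 1.4
                acc_c[p] = 0.0
            rate = acc_t / (4 * window)
            if rate < 0.2:
                scale_t *= 0.7
            elif rate > 0.4:
                scale_t *= 1.4
            acc_t = 0.0

        if it >= n_warmup:
            k = it - n_warmup
            for s in range(n):
                for p in range(P):
                    out_z[k, s, p] = z[s, p]
            out_m[k] = M
            out_s[k] = S
            out_dev[k] = -2.0 * cur_ll.sum()

    return out_z, out_m, out_s, out_dev
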