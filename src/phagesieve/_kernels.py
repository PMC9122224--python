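"""Numba-compiled inner loops of the stochastic phage-bacteria engine.

The simulation state lives in flat arrays sized by the bacterial census B0,
one slot per host cell, plus a length-2 vector of free-phage counts (slot 0
is the resident strain, slot 1 the mutant/second allele).  Per cell we keep
an infection flag, the founder strain, the infection age, the founder's
lysis age, the two intracellular pseudo-population masses and the number of
phage that have entered (V_n).  This layout is distribution-identical to the
per-agent description in :mod:`phagesieve.engine` (tested against it) but
runs a few hundred times faster, which is what makes millions of fixation
trials tractable on one core.

Strategy codes: 0 = S (superinfecting), 1 = SX (superinfection-excluding).
A cell's behaviour is always governed by its *founder's* strategy: SX-founded
cells absorb and destroy any later phage, S-founded cells accept entry from
any strain.

All kernels draw from numba's internal Mersenne-Twister stream; call
:func:`seed_rng` (or pass an explicit ``seed >= 0`` where a kernel accepts
one) before use for reproducible trajectories.
"""

import numpy as np
from numba import njit

#: strategy codes
S = 0
SX = 1

#: fixation-trial outcomes
EXTINCT = 0
FIXED = 1
CENSORED = 2
ALL_EXTINCT = 3


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def step(free, infected, founder, age, lysage, p, vn,
         alpha, beta, tau, strat, delta, B0):
    """Advance the population by one timestep, in place.

    Phase order: adsorption (start-of-step counts) -> intracellular growth
    -> lysis -> decay of free phage -> release of this step's progeny
    (so new progeny neither adsorb nor decay until the next step) ->
    replacement of lysed hosts (implicit: clearing the cell slot).

    Returns ``(n0, n1, i_mid)``: phage of each strain leaving the free pool
    this step, and the mid-step infected-cell count (after adsorption,
    before lysis), which is the census convention used for reported
    steady-state population sizes.
    """
    # --- adsorption -------------------------------------------------------
    n0 = np.random.poisson(alpha[0] * free[0] * B0)
    if n0 > free[0]:
        n0 = free[0]
    n1 = np.random.poisson(alpha[1] * free[1] * B0)
    if n1 > free[1]:
        n1 = free[1]
    free[0] -= n0
    free[1] -= n1
    rem0 = n0
    rem1 = n1
    for _ in range(n0 + n1):
        # interleave the two strains' adsorption events in uniform order so
        # that, when several phage hit the same uninfected cell in one step,
        # the founder is uniform among them
        if np.random.random() * (rem0 + rem1) < rem0:
            s = 0
            rem0 -= 1
        else:
            s = 1
            rem1 -= 1
        t = np.random.randint(0, B0)
        if infected[t] == 0:
            infected[t] = 1
            founder[t] = s
            age[t] = -1  # founded this step: first growth happens next step
            lysage[t] = tau[s]
            p[t, 0] = 0.0
            p[t, 1] = 0.0
            p[t, s] = 1.0
            vn[t] = 1
        else:
            f = founder[t]
            if strat[f] == S:
                p[t, s] += 1.0
                vn[t] += 1
            # SX founder: the phage is adsorbed and lost, cell unchanged
    i_mid = 0
    for c in range(B0):
        i_mid += infected[c]
    # --- intracellular growth --------------------------------------------
    for c in range(B0):
        if infected[c] == 1:
            a = age[c]
            if a >= 0:
                pa = p[c, 0]
                pb = p[c, 1]
                if pa > 0.0 and pb > 0.0:
                    tot = pa + pb
                    p[c, 0] = pa + beta[0] / tau[0] * pa / tot
                    p[c, 1] = pb + beta[1] / tau[1] * pb / tot
                elif pa > 0.0:
                    p[c, 0] = pa + beta[0] / tau[0]
                else:
                    p[c, 1] = pb + beta[1] / tau[1]
            age[c] = a + 1
    # --- lysis ------------------------------------------------------------
    y0 = 0
    y1 = 0
    for c in range(B0):
        if infected[c] == 1 and age[c] == lysage[c]:
            f = founder[c]
            if strat[f] == SX:
                y = np.random.poisson(beta[f])
                if f == 0:
                    y0 += y
                else:
                    y1 += y
            else:
                tot = p[c, 0] + p[c, 1]
                lam = tot - vn[c]
                if lam < 0.0:
                    lam = 0.0
                y = np.random.poisson(lam)
                if p[c, 1] == 0.0:
                    ya = y
                elif p[c, 0] == 0.0:
                    ya = 0
                else:
                    ya = np.random.binomial(y, p[c, 0] / tot)
                y0 += ya
                y1 += y - ya
            infected[c] = 0  # lysed host immediately replaced, uninfected
    # --- decay, then release of new progeny -------------------------------
    if delta > 0.0:
        if free[0] > 0:
            free[0] = np.random.binomial(free[0], 1.0 - delta)
        if free[1] > 0:
            free[1] = np.random.binomial(free[1], 1.0 - delta)
    free[0] += y0
    free[1] += y1
    return n0, n1, i_mid


@njit(cache=True)
def run_steps(free, infected, founder, age, lysage, p, vn,
              alpha, beta, tau, strat, delta, B0, n_steps):
    for _ in range(n_steps):
        step(free, infected, founder, age, lysage, p, vn,
             alpha, beta, tau, strat, delta, B0)


@njit(cache=True)
def run_average(free, infected, founder, age, lysage, p, vn,
                alpha, beta, tau, strat, delta, B0, n_steps):
    """Average the mid-step census (V, B, I) over ``n_steps`` steps."""
    sv = 0.0
    sb = 0.0
    si = 0.0
    for _ in range(n_steps):
        v_start = free[0] + free[1]
        n0, n1, i_mid = step(free, infected, founder, age, lysage, p, vn,
                             alpha, beta, tau, strat, delta, B0)
        sv += v_start - n0 - n1
        si += i_mid
        sb += B0 - i_mid
    return sv / n_steps, sb / n_steps, si / n_steps


@njit(cache=True)
def run_to_steady(free, infected, founder, age, lysage, p, vn,
                  alpha, beta, tau, strat, delta, B0,
                  burnin, window, rtol, max_steps):
    """Step until windowed running means of V, B and I settle.

    Returns ``(status, t, V, B, I)`` where status is 1 converged,
    0 max_steps reached, -1 phage extinct.  Means use the mid-step census.
    """
    t = 0
    for _ in range(burnin):
        step(free, infected, founder, age, lysage, p, vn,
             alpha, beta, tau, strat, delta, B0)
        t += 1
    prev_v = -1.0
    prev_b = -1.0
    prev_i = -1.0
    while t < max_steps:
        sv = 0.0
        sb = 0.0
        si = 0.0
        last_i = 0
        for _ in range(window):
            v_start = free[0] + free[1]
            n0, n1, i_mid = step(free, infected, founder, age, lysage, p, vn,
                                 alpha, beta, tau, strat, delta, B0)
            sv += v_start - n0 - n1
            si += i_mid
            sb += B0 - i_mid
            last_i = i_mid
            t += 1
        mv = sv / window
        mb = sb / window
        mi = si / window
        if free[0] + free[1] == 0 and last_i == 0:
            return -1, t, mv, mb, mi
        if prev_v >= 0.0:
            ok_v = abs(mv - prev_v) <= rtol * abs(prev_v)
            ok_b = abs(mb - prev_b) <= rtol * abs(prev_b)
            ok_i = abs(mi - prev_i) <= rtol * abs(prev_i)
            if ok_v and ok_b and ok_i:
                return 1, t, mv, mb, mi
        prev_v = mv
        prev_b = mb
        prev_i = mi
    return 0, t, prev_v, prev_b, prev_i


@njit(cache=True)
def run_record(free, infected, founder, age, lysage, p, vn,
               alpha, beta, tau, strat, delta, B0, n_steps,
               out_v0, out_v1, out_i):
    """Record end-of-step free counts per strain and infected count."""
    for k in range(n_steps):
        step(free, infected, founder, age, lysage, p, vn,
             alpha, beta, tau, strat, delta, B0)
        out_v0[k] = free[0]
        out_v1[k] = free[1]
        ni = 0
        for c in range(B0):
            ni += infected[c]
        out_i[k] = ni


@njit(cache=True)
def _ownership(infected, p, B0):
    """Per-strain pseudo-population ownership, in units of cells."""
    own0 = 0.0
    own1 = 0.0
    for c in range(B0):
        if infected[c] == 1:
            tot = p[c, 0] + p[c, 1]
            own0 += p[c, 0] / tot
            own1 += p[c, 1] / tot
    return own0, own1


@njit(cache=True)
def run_freq(free, infected, founder, age, lysage, p, vn,
             alpha, beta, tau, strat, delta, B0, beta_res, n_steps, out_f):
    """Record the census-weighted mutant allele frequency each step.

    f = (V_mut + beta_res * ownership_mut) / (V_tot + beta_res * I).
    On absorption the remaining entries are filled with 0 (mutant lost) or
    1 (mutant fixed).  Returns ``(status, t_abs)`` with status 1 polymorphic
    at the end, 0 lost, 2 fixed, -1 whole population extinct.
    """
    for k in range(n_steps):
        step(free, infected, founder, age, lysage, p, vn,
             alpha, beta, tau, strat, delta, B0)
        own0, own1 = _ownership(infected, p, B0)
        num = free[1] + beta_res * own1
        den = free[0] + free[1] + beta_res * (own0 + own1)
        if den == 0.0:
            for j in range(k, n_steps):
                out_f[j] = 0.0
            return -1, k
        f = num / den
        out_f[k] = f
        if free[1] == 0 and own1 == 0.0:
            for j in range(k + 1, n_steps):
                out_f[j] = 0.0
            return 0, k
        if free[0] == 0 and own0 == 0.0:
            for j in range(k + 1, n_steps):
                out_f[j] = 1.0
            return 2, k
    return 1, n_steps


@njit(cache=True)
def run_fixation(free, infected, founder, age, lysage, p, vn,
                 alpha, beta, tau, strat, delta, B0, max_steps):
    """Step until the mutant (strain 1) fixes or goes extinct.

    A strain counts as alive while it has free phage or any intracellular
    pseudo-population mass.  Returns ``(outcome, steps)``.
    """
    for k in range(max_steps):
        step(free, infected, founder, age, lysage, p, vn,
             alpha, beta, tau, strat, delta, B0)
        m_alive = free[1] > 0
        r_alive = free[0] > 0
        if not (m_alive and r_alive):
            for c in range(B0):
                if infected[c] == 1:
                    if p[c, 1] > 0.0:
                        m_alive = True
                    if p[c, 0] > 0.0:
                        r_alive = True
                    if m_alive and r_alive:
                        break
            if not m_alive and not r_alive:
                return ALL_EXTINCT, k + 1
            if not m_alive:
                return EXTINCT, k + 1
            if not r_alive:
                return FIXED, k + 1
    return CENSORED, max_steps
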