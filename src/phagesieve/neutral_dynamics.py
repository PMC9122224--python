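"""Neutral dynamics: heterozygosity decay, effective population size and
generation time.

Genetic drift in the phage population is quantified by splitting a
steady-state population into two parameter-identical alleles and tracking
the heterozygosity ``H(t) = 2 <f (1 - f)>`` across an ensemble of
independent trajectories.  At long times ``H`` decays exponentially at rate
``Lambda = 2 / N_e`` per generation (Moran model), so a linear fit to
``log H`` against time, converted from timesteps to generations with the
generation time ``T``, yields the effective population size.

The generation time itself follows from the age-structured demography of a
free phage: it can die (decay at rate ``delta``, or adsorb to an infected
host at rate ``alpha * I_ss``) or reproduce by infecting an uninfected host
(rate ``alpha * B_ss``, yielding ``beta - 1`` net new phage ``tau`` steps
later).  In the continuum limit the net reproduction rate is

    R0 = alpha * B_ss * (beta - 1) / (delta + alpha * I_ss)
         * exp(-(delta + alpha * I_ss) * tau)

and the mean birth-to-offspring interval is ``T = tau + 1/(delta +
alpha*I_ss)``.  The same ``T`` applies to superinfecting and
superinfection-excluding populations with equal parameters, because a lone
strain's demography is strategy-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import _kernels
from .engine import (EnvConfig, PopulationState, SimState, StrainParams,
                     SteadyState, run_to_steady_state)

__all__ = [
    "HeterozygositySeries", "NeEstimate", "GenerationStats",
    "label_split", "allele_frequency", "heterozygosity_series",
    "estimate_Ne", "net_reproduction_rate", "generation_time",
    "generation_stats",
]

MUTANT_LABEL = "allele_b"


@dataclass
class HeterozygositySeries:
    """Ensemble heterozygosity on a timestep grid."""

    t: np.ndarray
    H: np.ndarray
    n_reps: int
    n_polymorphic: np.ndarray  # reps still segregating at each t

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "H": self.H,
                             "n_polymorphic": self.n_polymorphic})


@dataclass
class NeEstimate:
    """Exponential-decay fit of heterozygosity.

    ``Lambda`` is the decay rate of H per timestep; ``Ne = 2 / (Lambda*T)``
    converts it to a Moran-equivalent census using the generation time.
    """

    Lambda: float
    T: float
    Ne: float
    fit_range: Tuple[int, int]
    stderr: float


@dataclass
class GenerationStats:
    """Net reproduction rate and generation time of a free phage."""

    R0: float
    T: float


def label_split(state: PopulationState, rng: np.random.Generator,
                strains: Dict[str, StrainParams],
                mutant_label: str = MUTANT_LABEL
                ) -> Tuple[PopulationState, Dict[str, StrainParams]]:
    """Relabel ~50% of a single-strain population as a second neutral allele.

    Free phage are split binomially; each infected cell is relabelled whole
    (founder and pseudo mass) with probability 1/2, preserving every count.
    Returns the relabelled state and the two-strain parameter table.
    """
    if len(state.free) != 1:
        raise ValueError("label_split needs a single-strain state")
    (res_label, v), = state.free.items()
    res = strains[res_label]
    mut = res.with_(label=mutant_label)
    n_mut = int(rng.binomial(v, 0.5)) if v > 0 else 0
    new = state.copy()
    new.free = {res_label: v - n_mut, mutant_label: n_mut}
    for cell in new.cells:
        if rng.random() < 0.5:
            cell.founder = mutant_label
            cell.pseudo = {mutant_label: sum(cell.pseudo.values())}
    return new, {res_label: res, mutant_label: mut}


def allele_frequency(state: PopulationState, beta_res: float,
                     mutant_label: str = MUTANT_LABEL) -> float:
    """Census-weighted frequency of the mutant allele.

    Each infected cell contributes ``beta_res`` phage-equivalents, split
    between alleles by intracellular pseudo-population ownership (entirely
    the founder's for SX cells).
    """
    free_mut = state.free.get(mutant_label, 0)
    free_tot = state.total_free()
    own = 0.0
    for cell in state.cells:
        tot = sum(cell.pseudo.values())
        own += cell.pseudo.get(mutant_label, 0.0) / tot
    den = free_tot + beta_res * state.I
    if den == 0:
        raise ZeroDivisionError("allele frequency undefined: empty system")
    return (free_mut + beta_res * own) / den


def _array_label_split(sim: SimState, rng: np.random.Generator) -> None:
    """In-place 50/50 relabel of a resident-only SimState to strain 1."""
    v = int(sim.free[0])
    n_mut = int(rng.binomial(v, 0.5)) if v > 0 else 0
    sim.free[0] = v - n_mut
    sim.free[1] = n_mut
    idx = np.flatnonzero(sim.infected == 1)
    flip = idx[rng.random(idx.size) < 0.5]
    sim.founder[flip] = 1
    sim.p[flip, 1] = sim.p[flip, 0] + sim.p[flip, 1]
    sim.p[flip, 0] = 0.0


def heterozygosity_series(strain: StrainParams, env: EnvConfig,
                          n_reps: int, n_steps: int,
                          *, seed: Optional[int] = None,
                          decorrelate: int = 50,
                          steady: Optional[SteadyState] = None
                          ) -> HeterozygositySeries:
    """Ensemble heterozygosity of two neutral alleles from steady state.

    One resident burn-in supplies the starting condition; before each
    replicate the base population is advanced ``decorrelate`` further steps,
    then split 50/50 into two labels and run for ``n_steps`` while recording
    the census-weighted allele frequency.  ``H(t) = 2 <f(1-f)>`` over the
    ensemble; absorbed replicates contribute 0 from their absorption time.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    master = np.random.SeedSequence(env.seed if seed is None else seed)
    py_rng = np.random.default_rng(master.spawn(1)[0])
    kernel_seeds = master.generate_state(2 * n_reps + 1) >> 1
    if steady is None:
        steady = run_to_steady_state(strain, env, seed=int(kernel_seeds[-1]))
    mut = strain.with_(label=MUTANT_LABEL)
    base = SimState.from_population(steady.snapshot, [strain, mut], env)
    h_acc = np.zeros(n_steps)
    n_poly = np.zeros(n_steps, dtype=int)
    f_buf = np.empty(n_steps)
    used = 0
    for rep in range(n_reps):
        base.seed(int(kernel_seeds[2 * rep]))
        base.run(decorrelate)
        sim = base.copy()
        _array_label_split(sim, py_rng)
        sim.seed(int(kernel_seeds[2 * rep + 1]))
        status, t_abs = _kernels.run_freq(
            *sim.arrays, *sim.params, float(strain.beta),
            int(n_steps), f_buf)
        if status == -1:
            continue  # whole-population extinction: discard replicate
        h_acc += 2.0 * f_buf * (1.0 - f_buf)
        seg = np.zeros(n_steps, dtype=int)
        upto = n_steps if status == 1 else t_abs
        seg[:upto] = (f_buf[:upto] > 0.0) & (f_buf[:upto] < 1.0)
        n_poly += seg
        used += 1
    if used < 2:
        raise RuntimeError("fewer than two surviving replicates")
    return HeterozygositySeries(t=np.arange(1, n_steps + 1),
                                H=h_acc / used, n_reps=used,
                                n_polymorphic=n_poly)


def estimate_Ne(series: HeterozygositySeries, T: float,
                *, fit_range: Optional[Tuple[int, int]] = None,
                start_frac: float = 0.45,
                min_poly_frac: float = 0.2) -> NeEstimate:
    """Least-squares fit of ``log H`` against time in the drift regime.

    The default window opens once H has dropped below ``start_frac`` of its
    initial value (clear of the relaxation transient) and closes when fewer
    than ``min_poly_frac`` of the replicates remain polymorphic (beyond
    which H is dominated by a handful of trajectories).
    """
    H, t = series.H, series.t
    h0 = H[0]
    if fit_range is None:
        below = np.flatnonzero(H < start_frac * h0)
        start = int(below[0]) if below.size else 0
        thin = np.flatnonzero(series.n_polymorphic
                              < min_poly_frac * series.n_reps)
        stop = int(thin[0]) if thin.size else len(H)
    else:
        start, stop = fit_range
    mask = np.zeros(len(H), dtype=bool)
    mask[start:stop] = True
    mask &= H > 0
    if mask.sum() < 3:
        raise ValueError("fit window too short to estimate a decay rate")
    fit = stats.linregress(t[mask], np.log(H[mask]))
    lam = -fit.slope
    if lam <= 0:
        raise ValueError("non-positive decay rate: no drift signal")
    ne = 2.0 / (lam * T)
    return NeEstimate(Lambda=lam, T=T, Ne=ne,
                      fit_range=(int(t[mask][0]), int(t[mask][-1])),
                      stderr=float(fit.stderr))


def net_reproduction_rate(params: StrainParams, env: EnvConfig,
                          steady: SteadyState) -> float:
    """Continuum-limit net reproduction rate R0 of a free phage."""
    loss = env.delta + params.alpha * steady.I_ss
    if loss <= 0:
        return math.inf if params.beta > 1 else 0.0
    return (params.alpha * steady.B_ss * (params.beta - 1.0) / loss
            * math.exp(-loss * params.tau))


def generation_time(params: StrainParams, env: EnvConfig,
                    I_ss: float) -> float:
    """Mean birth-to-offspring interval: ``tau + 1/(delta + alpha*I_ss)``."""
    loss = env.delta + params.alpha * I_ss
    if loss <= 0:
        raise ZeroDivisionError("generation time undefined at zero loss rate")
    return params.tau + 1.0 / loss


def generation_stats(params: StrainParams, env: EnvConfig,
                     steady: SteadyState) -> GenerationStats:
    return GenerationStats(R0=net_reproduction_rate(params, env, steady),
                           T=generation_time(params, env, steady.I_ss))
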