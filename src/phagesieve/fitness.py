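"""Growth-rate and competitive selection coefficients, and their relation.

Two fitness measures are defined for a mutant relative to a resident:

* ``s_growth = r_mut / r_res - 1``, from the exponential growth rates of
  each strain alone invading a fully uninfected culture;
* ``s_comp``, from 50/50 competition at the resident's steady state, where
  ``V_mut / V_res = exp(r_res * s_comp * t)`` so that ``s_comp`` is the
  fitted slope of the mean log-ratio divided by ``r_res``.

In an interaction-free world the two would coincide.  Here they do not:
the turbidostat steady state and (for superinfecting strains) intracellular
competition reshape the competitive advantage, summarised by the gradient
``sigma`` of the origin-constrained fit ``s_comp = sigma * s_growth``
across a grid of single-parameter mutants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import _kernels
from .engine import (EnvConfig, SimState, SteadySampler, SteadyState,
                     StrainParams, run_to_steady_state)
from .meanfield import meanfield_steady_state
from .neutral_dynamics import _array_label_split

__all__ = [
    "GrowthRateEstimate", "CompetitionResult", "SigmaFit",
    "measure_growth_rate", "s_growth", "run_competition", "fit_sigma",
    "mutant_grid", "sigma_experiment",
]


@dataclass
class GrowthRateEstimate:
    """Exponential growth rate fitted from isolated-growth simulations."""

    r: float
    stderr: float
    window: Tuple[int, int]
    n_reps: int
    n_extinct: int = 0


@dataclass
class CompetitionResult:
    """Competitive selection coefficient from 50/50 steady-state contests."""

    s_comp: float
    stderr: float
    slope: float
    r_res: float
    n_reps: int
    n_flagged: int
    log_ratio: np.ndarray = field(repr=False)  # ensemble-mean ln(Vmut/Vres)
    t: np.ndarray = field(repr=False)


@dataclass
class SigmaFit:
    """Origin-constrained gradient of s_comp against s_growth."""

    sigma: float
    stderr: float
    points: List[Tuple[float, float]]


def measure_growth_rate(params: StrainParams, env: EnvConfig,
                        n_reps: int = 500, *, seed: int = 0,
                        v0_frac: float = 0.01, cap_frac: float = 0.25,
                        v_lo: Optional[float] = None,
                        max_steps: int = 1200) -> GrowthRateEstimate:
    """Exponential growth rate of one strain invading uninfected hosts.

    Each replicate inoculates ``v0_frac * B0`` free phage into ``B0``
    uninfected bacteria and fits a line to log free-phage count inside the
    exponential phase: from the first time (after the first lysis burst,
    t > tau) the free count clears ``v_lo`` -- past the decay of the
    unadsorbed inoculum and the large relative sawtooth of the first few
    bursts -- until it reaches ``cap_frac`` of the strain's projected
    steady-state free count (from the mean field).  Replicates that die
    out or never produce a usable window are discarded and counted.
    """
    v_ss = meanfield_steady_state(params, env)[0]
    cap = cap_frac * v_ss
    v0 = max(1, round(v0_frac * env.B0))
    if v_lo is None:
        v_lo = min(max(50.0, 10.0 * v0), cap / 4.0)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) >> 1
    v_buf = np.empty(max_steps)
    v1_buf = np.empty(max_steps)
    i_buf = np.empty(max_steps)
    t_axis = np.arange(1, max_steps + 1)
    rates = []
    n_extinct = 0
    lo_used, hi_used = max_steps, 0
    for rep in range(n_reps):
        sim = SimState([params], env)
        sim.free[0] = v0
        sim.seed(int(seeds[rep]))
        _kernels.run_record(*sim.arrays, *sim.params, max_steps,
                            v_buf, v1_buf, i_buf)
        est = np.flatnonzero((t_axis > params.tau) & (v_buf >= v_lo))
        if est.size == 0:
            n_extinct += 1
            continue
        i0 = int(est[0])
        over = np.flatnonzero(v_buf[i0:] >= cap)
        i1 = i0 + int(over[0]) if over.size else max_steps
        seg = v_buf[i0:i1]
        if i1 - i0 < 10 or (seg <= 0).any():
            n_extinct += 1
            continue
        fit = stats.linregress(t_axis[i0:i1], np.log(seg))
        rates.append(fit.slope)
        lo_used = min(lo_used, int(t_axis[i0]))
        hi_used = max(hi_used, int(t_axis[i1 - 1]))
    if not rates:
        raise RuntimeError("all growth replicates went extinct")
    rates = np.asarray(rates)
    sem = rates.std(ddof=1) / math.sqrt(len(rates)) if len(rates) > 1 else 0.0
    return GrowthRateEstimate(r=float(rates.mean()), stderr=float(sem),
                              window=(lo_used, hi_used),
                              n_reps=len(rates), n_extinct=n_extinct)


def s_growth(r_mut: float, r_res: float) -> float:
    """Relative growth-rate advantage ``r_mut / r_res - 1``."""
    if r_res == 0:
        raise ZeroDivisionError("resident growth rate is zero")
    return r_mut / r_res - 1.0


def run_competition(res: StrainParams, mut: StrainParams, env: EnvConfig,
                    n_reps: int = 200, *, r_res: float,
                    seed: int = 0, fit_start: Optional[int] = None,
                    fit_len: int = 600, max_excursion: float = 2.0,
                    min_fit: int = 100,
                    sampler: Optional[SteadySampler] = None,
                    steady: Optional[SteadyState] = None
                    ) -> CompetitionResult:
    """Selection coefficient from 50/50 competition at steady state.

    Each replicate starts from a decorrelated resident steady-state
    snapshot in which half the free phage (binomially) and each infected
    cell with probability 1/2 (whole cell: founder and pseudo mass) are
    relabelled as the mutant.  The ensemble-mean ``ln(V_mut / V_res)`` is
    fitted from ``fit_start`` (default ``2*tau``, excluding the relaxation
    of the relabelled cell generation) over at most ``fit_len`` steps, and
    ``s_comp = slope / r_res``.

    For strong selection the window is shortened so that the mean
    log-ratio moves at most ``max_excursion`` (but no fewer than
    ``min_fit`` steps): past that point the losing strain's free count is
    small enough for discreteness and extinction-conditioning to bend the
    trajectory.  Replicates in which either strain's free count hits zero
    before the end of the fit window are flagged and excluded.
    """
    if fit_start is None:
        fit_start = 2 * res.tau
    n_steps = fit_start + fit_len
    master = np.random.SeedSequence(seed)
    py_rng = np.random.default_rng(master.spawn(1)[0])
    seeds = master.generate_state(2 * n_reps) >> 1
    if sampler is None:
        if steady is None:
            steady = run_to_steady_state(res, env, seed=int(seeds[0]))
        sampler = SteadySampler(steady, [res, mut], env)
    v0 = np.empty(n_steps)
    v1 = np.empty(n_steps)
    ib = np.empty(n_steps)
    traj = np.full((n_reps, n_steps), np.nan)
    for rep in range(n_reps):
        sim = sampler.next(int(seeds[2 * rep]))
        sim = sim.with_strains([res, mut])
        _array_label_split(sim, py_rng)
        sim.seed(int(seeds[2 * rep + 1]))
        _kernels.run_record(*sim.arrays, *sim.params, n_steps, v0, v1, ib)
        ok = (v0 > 0) & (v1 > 0)
        dead = np.flatnonzero(~ok)
        upto = int(dead[0]) if dead.size else n_steps
        traj[rep, :upto] = np.log(v1[:upto] / v0[:upto])
    # provisional ensemble mean over whatever survives at each t sets the
    # excursion-limited window; the final mean uses only replicates intact
    # through the whole window
    n_valid = (~np.isnan(traj)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        prov = np.nansum(traj, axis=0) / np.maximum(n_valid, 1)
    prov[n_valid == 0] = np.inf  # nobody left: certainly past the window
    rel = np.abs(prov - prov[fit_start])
    beyond = np.flatnonzero(rel[fit_start:] > max_excursion)
    fit_end = fit_start + int(beyond[0]) if beyond.size else n_steps
    fit_end = min(max(fit_end, fit_start + min_fit), n_steps)
    intact = ~np.isnan(traj[:, fit_end - 1])
    used = int(intact.sum())
    flagged = n_reps - used
    if used == 0:
        raise RuntimeError("every competition replicate lost one strain")
    log_ratio = traj[intact].mean(axis=0)
    t = np.arange(1, n_steps + 1)
    win = slice(fit_start, fit_end)
    fit = stats.linregress(t[win], log_ratio[win])
    s_comp = fit.slope / r_res
    return CompetitionResult(s_comp=float(s_comp),
                             stderr=float(fit.stderr / abs(r_res)),
                             slope=float(fit.slope), r_res=r_res,
                             n_reps=used, n_flagged=flagged,
                             log_ratio=log_ratio[:fit_end], t=t[:fit_end])


def fit_sigma(pairs: Sequence[Tuple[float, float]]) -> SigmaFit:
    """Least-squares gradient through the origin of (s_growth, s_comp)."""
    pts = [(float(x), float(y)) for x, y in pairs]
    if not pts:
        raise ValueError("need at least one (s_growth, s_comp) pair")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ZeroDivisionError("all s_growth values are zero")
    sigma = float(np.dot(x, y) / sxx)
    if len(pts) > 1:
        resid = y - sigma * x
        stderr = math.sqrt(float(np.dot(resid, resid))
                           / ((len(pts) - 1) * sxx))
    else:
        stderr = 0.0
    return SigmaFit(sigma=sigma, stderr=stderr, points=pts)


def mutant_grid(res: StrainParams, param: str,
                fractions: Sequence[float] = (-0.30, -0.15, 0.15, 0.30)
                ) -> List[StrainParams]:
    """Single-parameter mutant grid around the resident value.

    ``tau`` perturbations are rounded to the nearest admissible integer
    timestep (the +/-15% and +/-30% grid around tau=15 is {11, 13, 17, 19}).
    """
    if param not in ("alpha", "beta", "tau"):
        raise ValueError("param must be alpha, beta or tau")
    muts = []
    for frac in fractions:
        value = getattr(res, param) * (1.0 + frac)
        if param == "tau":
            # truncate the perturbation toward the resident so the grid
            # stays symmetric in integer steps (15 +/- 15/30% -> 13,17/11,19)
            value = max(1, res.tau + math.trunc(res.tau * frac))
            if value == res.tau:
                value += 1 if frac > 0 else -1
        label = f"mut_{param}{'+' if frac > 0 else ''}{frac:.2f}"
        muts.append(res.with_(label=label, **{param: value}))
    return muts


def sigma_experiment(res: StrainParams, env: EnvConfig, param: str,
                     *, seed: int = 0,
                     fractions: Sequence[float] = (-0.30, -0.15, 0.15, 0.30),
                     growth_reps: int = 200, comp_reps: int = 200,
                     fit_len: int = 600,
                     r_res: Optional[GrowthRateEstimate] = None,
                     steady: Optional[SteadyState] = None) -> Dict:
    """Measure sigma for one perturbed life-history parameter.

    Runs the isolated-growth assay for the resident and each mutant on the
    grid, the steady-state competition for each mutant against the
    resident (both carrying the resident's strategy), and returns the
    origin-constrained :class:`SigmaFit` together with the per-mutant
    table.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * len(fractions) + 2) >> 1
    if r_res is None:
        r_res = measure_growth_rate(res, env, growth_reps,
                                    seed=int(seeds[-1]))
    if steady is None:
        steady = run_to_steady_state(res, env, seed=int(seeds[-2]))
    muts = mutant_grid(res, param, fractions)
    rows = []
    pairs = []
    for k, mut in enumerate(muts):
        g = measure_growth_rate(mut, env, growth_reps,
                                seed=int(seeds[2 * k]))
        sg = s_growth(g.r, r_res.r)
        comp = run_competition(res, mut, env, comp_reps, r_res=r_res.r,
                               seed=int(seeds[2 * k + 1]), fit_len=fit_len,
                               steady=steady)
        pairs.append((sg, comp.s_comp))
        rows.append({"label": mut.label, "param": param,
                     "value": getattr(mut, param),
                     "r_mut": g.r, "r_mut_err": g.stderr,
                     "s_growth": sg, "s_comp": comp.s_comp,
                     "s_comp_err": comp.stderr,
                     "comp_reps": comp.n_reps, "flagged": comp.n_flagged})
    fit = fit_sigma(pairs)
    return {"sigma": fit, "rows": rows, "r_res": r_res, "steady": steady,
            "strategy": res.strategy, "param": param}
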