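"""Single-mutant invasion experiments and Moran-model predictions.

A fixation trial introduces one mutant phage into a resident population at
steady state and runs until one lineage owns the whole population.  A
strain is alive while it has free phage or intracellular pseudo-population
mass, so a mutant surviving only inside a cell is not declared extinct
before its progeny had a chance to be released.

The Moran benchmark uses the classic diffusion result

    P_fix = (1 - exp(-Ne * s * f0)) / (1 - exp(-Ne * s)),

parameterised without free constants by quantities measured upstream: the
effective population size from heterozygosity decay, ``s = sigma *
s_growth`` from the fitness module, and the initial frequency ``f0 =
1 / N_T`` of a single mutant in the steady-state phage census.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import _kernels
from .engine import (EnvConfig, SimState, SteadySampler, SteadyState,
                     StrainParams, run_to_steady_state)

__all__ = [
    "FixationResult", "MoranPrediction", "estimate_pfix", "moran_pfix",
    "run_fixation_trial", "fixation_experiment", "predict_vs_simulate",
    "strategy_switch_experiment",
]

_OUTCOMES = {_kernels.EXTINCT: "extinct", _kernels.FIXED: "fixed",
             _kernels.CENSORED: "censored", _kernels.ALL_EXTINCT: "extinct"}


@dataclass
class FixationResult:
    """Trial counts and the binomially-estimated fixation probability."""

    n: int
    n_fix: int
    P_fix: float
    dP_fix: float
    censored: int = 0
    f0_star: Optional[float] = None
    N_T: Optional[float] = None

    @property
    def scaled(self) -> Optional[float]:
        """P_fix divided by the single-mutant initial frequency f0*."""
        if self.f0_star in (None, 0.0):
            return None
        return self.P_fix / self.f0_star


@dataclass
class MoranPrediction:
    Ne: float
    s: float
    f0: float
    P_fix_pred: float


def estimate_pfix(n: int, n_fix: int, censored: int = 0,
                  **extra) -> FixationResult:
    """Binomial estimate ``P_fix = n_fix / n`` with its standard error."""
    if n < 1:
        raise ValueError("need at least one trial")
    if not 0 <= n_fix <= n:
        raise ValueError("n_fix must lie in [0, n]")
    p = n_fix / n
    return FixationResult(n=n, n_fix=n_fix, P_fix=p,
                          dP_fix=math.sqrt(p * (1.0 - p) / n),
                          censored=censored, **extra)


def moran_pfix(Ne: float, s: float, f0: float) -> float:
    """Moran fixation probability for small selection coefficient s.

    Continuous at ``s = 0`` where the neutral limit ``f0`` applies.
    """
    if Ne <= 0:
        raise ValueError("Ne must be > 0")
    if not 0.0 <= f0 <= 1.0:
        raise ValueError("f0 must lie in [0, 1]")
    x = Ne * s
    if abs(x) < 1e-8:
        return f0
    if x > 500.0:  # denominator is 1 to machine precision
        return float(-math.expm1(-x * f0))
    if x < -500.0:  # both terms huge: ratio reduces to exp(x * (1 - f0))
        expo = x * (1.0 - f0)
        return math.exp(expo) if expo > -745.0 else 0.0
    return float(-math.expm1(-x * f0) / -math.expm1(-x))


def moran_prediction(Ne: float, s: float, f0: float) -> MoranPrediction:
    return MoranPrediction(Ne=Ne, s=s, f0=f0,
                           P_fix_pred=moran_pfix(Ne, s, f0))


def run_fixation_trial(res: StrainParams, mut: StrainParams,
                       snapshot: SteadyState, env: EnvConfig,
                       seed: int, *,
                       max_steps: int = 1_000_000) -> str:
    """One invasion trial from a steady-state snapshot.

    Adds a single free mutant phage and steps until the mutant census
    (free + intracellular pseudo-ownership) or the resident census reaches
    zero.  Returns ``"fixed"``, ``"extinct"`` or ``"censored"``.
    """
    sim = SimState.from_population(snapshot.snapshot, [res, mut], env)
    sim.free[1] += 1
    sim.seed(seed)
    outcome, _ = _kernels.run_fixation(*sim.arrays, *sim.params,
                                       int(max_steps))
    return _OUTCOMES[outcome]


def fixation_experiment(res: StrainParams, mut: StrainParams,
                        env: EnvConfig, n_trials: int, *, seed: int = 0,
                        max_steps: int = 1_000_000,
                        decorrelate: int = 50, reuse: int = 10,
                        steady: Optional[SteadyState] = None
                        ) -> FixationResult:
    """Estimate P_fix of a single mutant phage over ``n_trials`` invasions.

    Snapshots come from one resident burn-in, advanced ``decorrelate``
    steps between (reused) snapshots.  ``f0* = 1 / N_T`` is measured from
    the same steady state.  Censored trials (``max_steps`` reached without
    absorption) are reported separately and not counted as fixations.
    """
    master = np.random.SeedSequence(seed)
    seeds = master.generate_state(2 * n_trials + 1) >> 1
    if steady is None:
        steady = run_to_steady_state(res, env, seed=int(seeds[-1]))
    sampler = SteadySampler(steady, [res, mut], env,
                            decorrelate=decorrelate, reuse=reuse)
    n_fix = 0
    censored = 0
    for k in range(n_trials):
        sim = sampler.next(int(seeds[2 * k]))
        sim.free[1] += 1
        sim.seed(int(seeds[2 * k + 1]))
        outcome, _ = _kernels.run_fixation(*sim.arrays, *sim.params,
                                           int(max_steps))
        if outcome == _kernels.FIXED:
            n_fix += 1
        elif outcome == _kernels.CENSORED:
            censored += 1
    return estimate_pfix(n_trials, n_fix, censored,
                         f0_star=1.0 / steady.N_T, N_T=steady.N_T)


def predict_vs_simulate(res: StrainParams, mut_grid: Sequence[StrainParams],
                        env: EnvConfig, *, Ne: float, sigma: float,
                        s_growths: Sequence[float], n_trials: int,
                        seed: int = 0,
                        steady: Optional[SteadyState] = None,
                        max_steps: int = 1_000_000) -> "pd.DataFrame":
    """Simulated P_fix against the parameter-free Moran prediction.

    ``s_growths`` are the measured growth advantages of ``mut_grid`` (same
    order); the Moran column uses ``moran_pfix(Ne, sigma * s_growth,
    1/N_T)`` with no fitted constants.
    """
    import pandas as pd

    if len(mut_grid) != len(s_growths):
        raise ValueError("mut_grid and s_growths must align")
    seeds = np.random.SeedSequence(seed).generate_state(len(mut_grid) + 1)
    if steady is None:
        steady = run_to_steady_state(res, env, seed=int(seeds[-1] >> 1))
    rows = []
    for mut, sg, s_i in zip(mut_grid, s_growths, seeds):
        result = fixation_experiment(res, mut, env, n_trials,
                                     seed=int(s_i >> 1), steady=steady,
                                     max_steps=max_steps)
        pred = moran_pfix(Ne, sigma * sg, 1.0 / steady.N_T)
        rows.append({"label": mut.label, "s_growth": sg,
                     "P_fix": result.P_fix, "dP_fix": result.dP_fix,
                     "n": result.n, "n_fix": result.n_fix,
                     "censored": result.censored,
                     "P_fix_moran": pred})
    return pd.DataFrame(rows)


def strategy_switch_experiment(resident_strategy: str, beta_mut: float,
                               env: EnvConfig, n_trials: int, *,
                               resident: Optional[StrainParams] = None,
                               seed: int = 0,
                               max_steps: int = 1_000_000
                               ) -> FixationResult:
    """Invasion of a mutant differing in strategy (and optionally burst size).

    With an S resident, the SX mutant's cells cannot be entered by resident
    phage while the mutant itself can still exploit resident-founded cells;
    with an SX resident the superinfecting mutant gains nothing (resident
    cells exclude it) yet its own cells are open to resident phage.  Cell
    behaviour always follows the founder's strategy, so no extra machinery
    is needed beyond the two-strain engine.
    """
    if resident is None:
        resident = StrainParams(label="resident",
                                strategy=resident_strategy)
    else:
        resident = resident.with_(strategy=resident_strategy)
    other = "SX" if resident_strategy == "S" else "S"
    mut = resident.with_(label="switch_mut", strategy=other, beta=beta_mut)
    return fixation_experiment(resident, mut, env, n_trials, seed=seed,
                               max_steps=max_steps)
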