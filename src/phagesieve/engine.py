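"""Stochastic agent-based model of lytic phage growth at constant host census.

The model is a discrete-time turbidostat: ``B0`` bacteria are held at
constant density, each either uninfected or infected, and a well-mixed pool
of free phage adsorbs to them.  Each phage genotype ("strain") carries three
life-history parameters -- adsorption rate ``alpha``, burst size ``beta``
and a deterministic lysis time ``tau`` -- plus an infection strategy:

* ``"S"`` (superinfecting): later phage may enter an already-infected cell
  and claim part of its burst through intracellular pseudo-populations;
* ``"SX"`` (superinfection-excluding): later phage adsorb but are destroyed
  without entering, so a cell only ever produces its founder's progeny.

Each timestep runs adsorption, intracellular replication, lysis, free-phage
decay and host replacement, in that order.  One timestep corresponds to one
minute of a typical coliphage culture.

Two state representations are provided.  :class:`PopulationState` is an
explicit per-cell object model used by the operation functions in this
module; it is the reference semantics.  :class:`SimState` packs the same
information into flat arrays driven by the numba kernels in
:mod:`phagesieve._kernels`; all expensive experiment drivers use it.  The
two are distribution-identical (this is covered by the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "StrainParams",
    "EnvConfig",
    "InfectedCell",
    "PopulationState",
    "SteadyState",
    "SimState",
    "PhageExtinctionError",
    "ConvergenceError",
    "DEFAULT_RESIDENT",
    "DEFAULT_ENV",
    "draw_infections",
    "assign_targets",
    "grow_intracellular",
    "lyse",
    "decay_free",
    "replace_lysed",
    "step",
    "initial_state",
    "run_to_steady_state",
    "scaled_census",
]

STRATEGIES = ("S", "SX")


class PhageExtinctionError(RuntimeError):
    """Raised when the phage population dies out before steady state."""


class ConvergenceError(RuntimeError):
    """Raised when steady state is not detected within ``max_steps``."""


@dataclass(frozen=True)
class StrainParams:
    """Life-history parameters and infection strategy of one phage strain.

    Parameters
    ----------
    label:
        Identifier used in outputs and state maps.
    alpha:
        Adsorption rate per free phage per bacterium per timestep.
    beta:
        Mean burst size (progeny phage per lysis).
    tau:
        Lysis time in integer timesteps; set by the *first* phage to infect
        a cell.
    strategy:
        ``"S"`` or ``"SX"``.
    """

    label: str
    alpha: float = 3e-6
    beta: float = 100.0
    tau: int = 15
    strategy: str = "SX"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError("tau must be an integer >= 1")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")

    def with_(self, **kw) -> "StrainParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class EnvConfig:
    """Environment: host census, phage decay and run control.

    ``delta`` is the per-timestep removal probability of each free phage
    (natural decay plus turbidostat outflow).  ``dt`` is the timestep in
    simulation units and is 1 throughout (1 timestep = 1 min); it is kept
    explicit because ``delta * dt`` must stay within [0, 1].
    """

    B0: int = 1000
    delta: float = 0.1
    dt: float = 1.0
    seed: int = 0
    max_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if self.B0 < 1:
            raise ValueError("B0 must be >= 1")
        if not 0.0 <= self.delta * self.dt <= 1.0:
            raise ValueError("delta * dt must lie in [0, 1]")

    def with_(self, **kw) -> "EnvConfig":
        return replace(self, **kw)


DEFAULT_RESIDENT = StrainParams(label="resident")
DEFAULT_ENV = EnvConfig()


def scaled_census(strain: StrainParams, env: EnvConfig, scale: float):
    """Rescale the bacterial census keeping ``alpha * B0`` (and therefore
    all per-phage rates and the steady-state densities per host) fixed."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    b0 = max(1, round(env.B0 * scale))
    return (strain.with_(alpha=strain.alpha * env.B0 / b0),
            env.with_(B0=b0))


@dataclass
class InfectedCell:
    """Infection record of one host cell.

    ``pseudo`` maps strain label to intracellular pseudo-population mass;
    ``n_entered`` counts every phage that entered (V_n).  The founder's
    strategy governs whether later phage may enter.
    """

    founder: str
    lysis_age: int
    age: int = 0
    pseudo: Dict[str, float] = field(default_factory=dict)
    n_entered: int = 1

    def copy(self) -> "InfectedCell":
        return InfectedCell(self.founder, self.lysis_age, self.age,
                            dict(self.pseudo), self.n_entered)


@dataclass
class PopulationState:
    """Full system state: free phage per strain, uninfected count, cells."""

    t: int
    free: Dict[str, int]
    B: int
    cells: List[InfectedCell]

    @property
    def I(self) -> int:
        return len(self.cells)

    def total_free(self) -> int:
        return sum(self.free.values())

    def copy(self) -> "PopulationState":
        return PopulationState(self.t, dict(self.free), self.B,
                               [c.copy() for c in self.cells])


@dataclass
class SteadyState:
    """Running-average steady state of a single-strain resident population.

    ``N_T = V_ss + beta * I_ss`` is the total phage census (free phage plus
    the phage-equivalents bound to lyse out of infected cells); the inverse
    of ``N_T`` is the initial frequency of a single inoculated mutant.
    Averages use the mid-step census (after adsorption, before lysis).
    """

    V_ss: float
    B_ss: float
    I_ss: float
    N_T: float
    snapshot: PopulationState
    converged: bool = True
    steps: int = 0


# ---------------------------------------------------------------------------
# reference (per-agent) operations
# ---------------------------------------------------------------------------

def draw_infections(state: PopulationState, strain: StrainParams,
                    rng: np.random.Generator, B0: int) -> int:
    """Number of ``strain`` phage leaving the free pool this step.

    Poisson with mean ``alpha * V * (B + I)``, capped at the available free
    count.  The caller debits the free pool.
    """
    v = state.free.get(strain.label, 0)
    if v == 0 or strain.alpha == 0.0:
        return 0
    n = rng.poisson(strain.alpha * v * B0)
    return min(int(n), v)


def assign_targets(n_infecting: Dict[str, int], state: PopulationState,
                   strains: Dict[str, StrainParams],
                   rng: np.random.Generator, B0: int) -> Dict[str, int]:
    """Deliver this step's infecting phage to uniformly chosen bacteria.

    Every infecting phage is removed from the free pool whether or not it
    enters a cell.  Targets are uniform with replacement among all ``B0``
    hosts.  An uninfected target becomes a new :class:`InfectedCell` whose
    founder -- chosen uniformly among same-step arrivals -- sets the lysis
    clock.  On an infected target the founder's strategy decides: S-founded
    cells accept the phage into its strain's pseudo-population, SX-founded
    cells absorb and destroy it.

    Returns a per-strain count of phage absorbed without entry (SX losses).
    """
    for label, n in n_infecting.items():
        if n > state.free.get(label, 0):
            raise ValueError("cannot infect with more phage than are free")
        state.free[label] -= n
    events: List[str] = []
    for label, n in n_infecting.items():
        events.extend([label] * n)
    rng.shuffle(events)
    targets = rng.integers(0, B0, size=len(events))
    i_start = state.I
    new_cells: Dict[int, InfectedCell] = {}
    excluded = {label: 0 for label in n_infecting}
    for label, t in zip(events, targets):
        if t < i_start:
            cell: Optional[InfectedCell] = state.cells[t]
        else:
            cell = new_cells.get(t)
        if cell is None:
            params = strains[label]
            new_cells[int(t)] = InfectedCell(
                founder=label, lysis_age=params.tau, age=0,
                pseudo={label: 1.0}, n_entered=1)
        elif strains[cell.founder].strategy == "S":
            cell.pseudo[label] = cell.pseudo.get(label, 0.0) + 1.0
            cell.n_entered += 1
        else:
            excluded[label] += 1
    state.cells.extend(new_cells.values())
    state.B = B0 - state.I
    return excluded


def grow_intracellular(cell: InfectedCell,
                       strains: Dict[str, StrainParams]) -> InfectedCell:
    """One step of intracellular replication; advances the cell's age.

    A lone strain grows at its constant rate ``beta/tau``.  When two strains
    share a (superinfecting) cell each receives only the fraction of its
    rate given by its current share of the total pseudo-population --
    intracellular competition for host resources.
    """
    if cell.age >= cell.lysis_age:
        raise ValueError("cell is past its lysis age")
    present = [s for s, mass in cell.pseudo.items() if mass > 0.0]
    if len(present) == 1:
        s = present[0]
        cell.pseudo[s] += strains[s].beta / strains[s].tau
    else:
        total = sum(cell.pseudo.values())
        for s in present:
            rate = strains[s].beta / strains[s].tau
            cell.pseudo[s] = cell.pseudo[s] * (1.0 + rate / total)
    cell.age += 1
    return cell


def lyse(cell: InfectedCell, strains: Dict[str, StrainParams],
         rng: np.random.Generator) -> Dict[str, int]:
    """Progeny released when the cell bursts.

    SX-founded cells yield ``Poisson(beta_founder)`` copies of the founder.
    S-founded cells yield ``Poisson(sum(p) - V_n)`` phage -- subtracting the
    entered phage keeps the mean burst at ``beta`` however many same-strain
    phage re-entered -- partitioned binomially by pseudo-population share.
    """
    if cell.age != cell.lysis_age:
        raise ValueError("cell lysed away from its lysis age")
    founder = strains[cell.founder]
    if founder.strategy == "SX":
        return {cell.founder: int(rng.poisson(founder.beta))}
    total = sum(cell.pseudo.values())
    lam = max(total - cell.n_entered, 0.0)
    y = int(rng.poisson(lam))
    labels = sorted(cell.pseudo)
    if len(labels) == 1:
        return {labels[0]: y}
    a, b = labels
    ya = int(rng.binomial(y, cell.pseudo[a] / total)) if y > 0 else 0
    return {a: ya, b: y - ya}


def decay_free(state: PopulationState, env: EnvConfig,
               rng: np.random.Generator) -> PopulationState:
    """Remove each free phage independently with probability ``delta*dt``."""
    q = env.delta * env.dt
    if q <= 0.0:
        return state
    for label, v in state.free.items():
        if v > 0:
            state.free[label] = int(rng.binomial(v, 1.0 - q)) if q < 1.0 else 0
    return state


def replace_lysed(state: PopulationState, n_lysed: int) -> PopulationState:
    """Replace lysed hosts with uninfected ones (turbidostat constraint)."""
    state.B += n_lysed
    return state


def step(state: PopulationState, strains: Dict[str, StrainParams],
         env: EnvConfig, rng: np.random.Generator) -> PopulationState:
    """One full timestep on the reference per-agent representation."""
    pre_existing = state.I
    n_inf = {label: draw_infections(state, sp, rng, env.B0)
             for label, sp in strains.items()}
    assign_targets(n_inf, state, strains, rng, env.B0)
    for cell in state.cells[:pre_existing]:
        grow_intracellular(cell, strains)
    survivors: List[InfectedCell] = []
    yields: Dict[str, int] = {label: 0 for label in strains}
    n_lysed = 0
    for cell in state.cells:
        if cell.age == cell.lysis_age:
            for label, y in lyse(cell, strains, rng).items():
                yields[label] += y
            n_lysed += 1
        else:
            survivors.append(cell)
    state.cells = survivors
    decay_free(state, env, rng)
    for label, y in yields.items():
        state.free[label] = state.free.get(label, 0) + y
    replace_lysed(state, n_lysed)
    state.t += 1
    return state


def initial_state(strains: Sequence[StrainParams], env: EnvConfig,
                  v0: Optional[Dict[str, int]] = None) -> PopulationState:
    """All-uninfected start; default inoculum is ``2 * B0`` resident phage."""
    free = {sp.label: 0 for sp in strains}
    if v0 is None:
        free[strains[0].label] = 2 * env.B0
    else:
        free.update(v0)
    return PopulationState(t=0, free=free, B=env.B0, cells=[])


# ---------------------------------------------------------------------------
# flat-array fast path
# ---------------------------------------------------------------------------

class SimState:
    """Array-backed population state driven by the numba kernels.

    Strain slot 0 is the resident, slot 1 the mutant (absent strains keep
    empty slots).  Conversion to and from :class:`PopulationState` is exact.
    """

    def __init__(self, strains: Sequence[StrainParams], env: EnvConfig):
        if not 1 <= len(strains) <= 2:
            raise ValueError("SimState supports 1 or 2 strains")
        self.strains = list(strains)
        if len(self.strains) == 1:
            # dead second slot: zero adsorption, harmless placeholders
            ghost = self.strains[0].with_(label="__ghost__", alpha=0.0)
            self.strains.append(ghost)
        self.env = env
        self.labels = [sp.label for sp in self.strains]
        self.alpha = np.array([sp.alpha for sp in self.strains])
        self.beta = np.array([sp.beta for sp in self.strains])
        self.tau = np.array([sp.tau for sp in self.strains], dtype=np.int64)
        self.strat = np.array(
            [0 if sp.strategy == "S" else 1 for sp in self.strains],
            dtype=np.int64)
        B0 = env.B0
        self.free = np.zeros(2, dtype=np.int64)
        self.infected = np.zeros(B0, dtype=np.int8)
        self.founder = np.zeros(B0, dtype=np.int8)
        self.age = np.zeros(B0, dtype=np.int64)
        self.lysage = np.zeros(B0, dtype=np.int64)
        self.p = np.zeros((B0, 2), dtype=np.float64)
        self.vn = np.zeros(B0, dtype=np.int64)
        self.t = 0

    # -- plumbing ----------------------------------------------------------
    @property
    def arrays(self):
        return (self.free, self.infected, self.founder, self.age,
                self.lysage, self.p, self.vn)

    @property
    def params(self):
        return (self.alpha, self.beta, self.tau, self.strat,
                self.env.delta * self.env.dt, self.env.B0)

    def copy(self) -> "SimState":
        new = SimState.__new__(SimState)
        new.strains = self.strains
        new.env = self.env
        new.labels = self.labels
        new.alpha, new.beta = self.alpha, self.beta
        new.tau, new.strat = self.tau, self.strat
        new.free = self.free.copy()
        new.infected = self.infected.copy()
        new.founder = self.founder.copy()
        new.age = self.age.copy()
        new.lysage = self.lysage.copy()
        new.p = self.p.copy()
        new.vn = self.vn.copy()
        new.t = self.t
        return new

    def with_strains(self, strains: Sequence[StrainParams]) -> "SimState":
        """Same cell/free state, different strain parameter table."""
        new = self.copy()
        tmp = SimState(strains, self.env)
        new.strains = tmp.strains
        new.labels = tmp.labels
        new.alpha, new.beta = tmp.alpha, tmp.beta
        new.tau, new.strat = tmp.tau, tmp.strat
        return new

    @property
    def I(self) -> int:
        return int(self.infected.sum())

    @property
    def B(self) -> int:
        return self.env.B0 - self.I

    def ownership(self):
        """Per-strain intracellular pseudo-ownership, in cell units."""
        return _kernels._ownership(self.infected, self.p, self.env.B0)

    def strain_alive(self, slot: int) -> bool:
        if self.free[slot] > 0:
            return True
        mask = self.infected == 1
        return bool((self.p[mask, slot] > 0.0).any())

    # -- stepping ----------------------------------------------------------
    def seed(self, seed: int) -> None:
        _kernels.seed_rng(int(seed) & 0x7FFFFFFF)

    def run(self, n_steps: int) -> None:
        _kernels.run_steps(*self.arrays, *self.params, int(n_steps))
        self.t += int(n_steps)

    # -- conversion --------------------------------------------------------
    @classmethod
    def from_population(cls, state: PopulationState,
                        strains: Sequence[StrainParams],
                        env: EnvConfig) -> "SimState":
        sim = cls(strains, env)
        sim.t = state.t
        for slot, label in enumerate(sim.labels):
            sim.free[slot] = state.free.get(label, 0)
        if state.I > env.B0:
            raise ValueError("more infected cells than bacteria")
        for c, cell in enumerate(state.cells):
            sim.infected[c] = 1
            sim.founder[c] = sim.labels.index(cell.founder)
            sim.age[c] = cell.age
            sim.lysage[c] = cell.lysis_age
            for label, mass in cell.pseudo.items():
                sim.p[c, sim.labels.index(label)] = mass
            sim.vn[c] = cell.n_entered
        return sim

    def to_population(self) -> PopulationState:
        free = {label: int(v) for label, v in zip(self.labels, self.free)
                if not label.startswith("__")}
        cells = []
        for c in np.flatnonzero(self.infected == 1):
            pseudo = {self.labels[s]: float(self.p[c, s])
                      for s in range(2) if self.p[c, s] > 0.0}
            cells.append(InfectedCell(
                founder=self.labels[int(self.founder[c])],
                lysis_age=int(self.lysage[c]), age=int(self.age[c]),
                pseudo=pseudo, n_entered=int(self.vn[c])))
        return PopulationState(t=self.t, free=free,
                               B=self.env.B0 - len(cells), cells=cells)


class SteadySampler:
    """Serves decorrelated steady-state snapshots from one resident burn-in.

    A fresh burn-in per trial would dominate the cost of large trial
    batches, so a single base population is kept at steady state and
    advanced ``decorrelate`` steps between snapshots; each snapshot may be
    reused ``reuse`` times before the base is advanced again.
    """

    def __init__(self, steady: "SteadyState", strains: Sequence[StrainParams],
                 env: EnvConfig, *, decorrelate: int = 50, reuse: int = 1):
        self.steady = steady
        self.base = SimState.from_population(steady.snapshot, strains, env)
        self.decorrelate = decorrelate
        self.reuse = max(1, reuse)
        self._served = 0

    def next(self, seed: int) -> SimState:
        if self._served % self.reuse == 0:
            self.base.seed(seed)
            self.base.run(self.decorrelate)
        self._served += 1
        return self.base.copy()


def run_to_steady_state(strain: StrainParams, env: EnvConfig,
                        *, window: int = 500, rtol: float = 1e-2,
                        burnin: Optional[int] = None, n_avg: int = 5000,
                        max_steps: Optional[int] = None,
                        seed: Optional[int] = None) -> SteadyState:
    """Run a single resident strain from the standard inoculum to steady state.

    Convergence is declared when the running means of V, B and I over
    consecutive windows of ``window`` steps each change by less than
    ``rtol`` (after a burn-in of at least ``10 * tau`` steps); the reported
    values are then averaged over a further ``n_avg`` steps.  All averages
    use the mid-step census: free phage counted after adsorption, infected
    cells counted through their lysis step.
    """
    sim = SimState([strain], env)
    sim.free[0] = 2 * env.B0
    sim.seed(env.seed if seed is None else seed)
    if burnin is None:
        burnin = max(10 * strain.tau, 2 * window)
    if max_steps is None:
        max_steps = env.max_steps
    status, t, _, _, _ = _kernels.run_to_steady(
        *sim.arrays, *sim.params, int(burnin), int(window), float(rtol),
        int(max_steps))
    if status == -1:
        raise PhageExtinctionError(
            f"phage went extinct after {t} steps (beta below persistence?)")
    if status == 0:
        raise ConvergenceError(f"no steady state within {max_steps} steps")
    v, b, i = _kernels.run_average(*sim.arrays, *sim.params, int(n_avg))
    sim.t = t + n_avg
    return SteadyState(V_ss=v, B_ss=b, I_ss=i,
                       N_T=v + strain.beta * i,
                       snapshot=sim.to_population(),
                       converged=True, steps=sim.t)
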