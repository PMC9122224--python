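"""Deterministic ensemble-mean companion of the stochastic engine.

Instead of integrating a continuous-time ODE system, this module applies
the expectation of every stochastic rule of :mod:`phagesieve.engine` in the
same phase order and in the same discrete time, keeping the infected hosts
age-structured.  Cells are grouped into cohorts by (infection age, founder
strain); each cohort carries its expected per-strain pseudo-population
masses, entered-phage count and the lysis age fixed at founding.  The only
closure is that the nonlinear per-cell rules (the shared-growth weights
p_s / sum(p) and the founding probability of a multiply-hit cell) are
evaluated on cohort aggregates -- exact for single-strain cohorts and
accurate to second order in the fluctuations otherwise.

The mean field is fully deterministic (no RNG anywhere), conserves hosts
exactly, and its steady state matches the stochastic running averages; the
test suite checks it against stochastic ensemble means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .engine import EnvConfig, StrainParams

__all__ = ["MeanFieldState", "initial_meanfield", "meanfield_step",
           "meanfield_run", "meanfield_steady_state",
           "meanfield_competition"]


@dataclass
class MeanFieldState:
    """Deterministic state: real-valued free phage, hosts and age cohorts.

    ``C[a, f]`` is the expected number of cells of infection age ``a``
    founded by strain ``f``; ``P[a, f, s]`` the total pseudo-population mass
    of strain ``s`` inside them; ``VN[a, f]`` the total entered-phage count;
    ``LY[a, f]`` the lysis age the founder stamped on the cohort.  Age ``a``
    is the end-of-step age (0 = founded this step); the cohort lyses in the
    step its age would reach ``LY[a, f]``.
    """

    V: np.ndarray          # (2,) free phage per strain
    B: float               # uninfected hosts
    C: np.ndarray          # (A, 2)
    P: np.ndarray          # (A, 2, 2)
    VN: np.ndarray         # (A, 2)
    LY: np.ndarray         # (A, 2) int
    t: int = 0
    # mid-step census of the last executed step (reported steady state)
    V_mid: float = 0.0
    I_mid: float = 0.0

    @property
    def I(self) -> float:
        return float(self.C.sum())

    def copy(self) -> "MeanFieldState":
        return MeanFieldState(self.V.copy(), self.B, self.C.copy(),
                              self.P.copy(), self.VN.copy(), self.LY.copy(),
                              self.t, self.V_mid, self.I_mid)


def _strain_arrays(strains: Sequence[StrainParams]):
    strains = list(strains)
    if len(strains) == 1:
        strains = strains + [strains[0].with_(label="__ghost__", alpha=0.0)]
    alpha = np.array([s.alpha for s in strains])
    beta = np.array([s.beta for s in strains])
    tau = np.array([s.tau for s in strains], dtype=int)
    is_s = np.array([s.strategy == "S" for s in strains])
    return alpha, beta, tau, is_s


def initial_meanfield(strains: Sequence[StrainParams], env: EnvConfig,
                      v0: Sequence[float] | None = None) -> MeanFieldState:
    _, _, tau, _ = _strain_arrays(strains)
    A = int(tau.max())
    V = np.zeros(2)
    if v0 is None:
        V[0] = 2.0 * env.B0
    else:
        V[: len(v0)] = v0
    return MeanFieldState(V=V, B=float(env.B0), C=np.zeros((A, 2)),
                          P=np.zeros((A, 2, 2)), VN=np.zeros((A, 2)),
                          LY=np.zeros((A, 2), dtype=int))


def meanfield_step(state: MeanFieldState, strains: Sequence[StrainParams],
                   env: EnvConfig) -> MeanFieldState:
    """Advance the expected state by one timestep (in place)."""
    alpha, beta, tau, is_s = _strain_arrays(strains)
    B0 = float(env.B0)
    delta = env.delta * env.dt
    C, P, VN, LY = state.C, state.P, state.VN, state.LY
    A = C.shape[0]
    V_pre = state.V.copy()

    # --- adsorption -------------------------------------------------------
    n = alpha * V_pre * B0                 # expected adsorptions per strain
    lam = float((alpha * V_pre).sum())     # hit rate per host cell
    state.V = V = V_pre - n
    state.V_mid = float(V.sum())
    I_before = float(C.sum())
    found_total = state.B * (1.0 - np.exp(-lam)) if lam > 0 else 0.0
    if lam > 0:
        w = alpha * V_pre / lam            # founder strain shares
    else:
        w = np.zeros(2)
    newC = found_total * w
    newP = np.zeros((2, 2))
    newVN = newC.copy()
    for f in range(2):
        newP[f, f] = newC[f]
    # hits to uninfected beyond the founders: same-step co-entrants
    hits_uninf = n * (state.B / B0)
    extra = max(float(hits_uninf.sum() - found_total), 0.0)
    if extra > 0 and found_total > 0:
        share_s = hits_uninf / hits_uninf.sum()
        for f in range(2):
            if newC[f] == 0:
                continue
            cell_frac = newC[f] / found_total
            if is_s[f]:
                for s in range(2):
                    amt = extra * cell_frac * share_s[s]
                    newP[f, s] += amt
                    newVN[f] += amt
            # SX founder: co-entrants are absorbed and lost
    # hits to already-infected cells, spread uniformly over cohorts
    if I_before > 0:
        hits_inf = n * (I_before / B0)
        for s in range(2):
            if hits_inf[s] == 0:
                continue
            per_cell = hits_inf[s] / I_before
            for f in range(2):
                if not is_s[f]:
                    continue  # SX-founded cells absorb and destroy
                amt = per_cell * C[:, f]
                P[:, f, s] += amt
                VN[:, f] += amt
    state.I_mid = I_before + found_total

    # --- intracellular growth (new cohort does not grow this step) -------
    rate = beta / tau
    for a in range(A):
        for f in range(2):
            if C[a, f] <= 0:
                continue
            if is_s[f]:
                tot = P[a, f, :].sum()
                if P[a, f, 0] > 0 and P[a, f, 1] > 0:
                    P[a, f, :] += rate * C[a, f] * P[a, f, :] / tot
                else:
                    s = 0 if P[a, f, 0] > 0 else 1
                    P[a, f, s] += rate[s] * C[a, f]
            else:
                P[a, f, f] += rate[f] * C[a, f]

    # --- age advance and lysis -------------------------------------------
    yields = np.zeros(2)
    C2 = np.zeros_like(C)
    P2 = np.zeros_like(P)
    VN2 = np.zeros_like(VN)
    LY2 = np.zeros_like(LY)
    for a in range(A):
        for f in range(2):
            if C[a, f] <= 0:
                continue
            new_age = a + 1
            if new_age >= LY[a, f]:
                if is_s[f]:
                    tot = P[a, f, :].sum()
                    y = max(tot - VN[a, f], 0.0)
                    if tot > 0:
                        yields += y * P[a, f, :] / tot
                else:
                    yields[f] += beta[f] * C[a, f]
            else:
                C2[new_age, f] = C[a, f]
                P2[new_age, f, :] = P[a, f, :]
                VN2[new_age, f] = VN[a, f]
                LY2[new_age, f] = LY[a, f]
    C2[0, :] = newC
    P2[0, :, :] = newP
    VN2[0, :] = newVN
    LY2[0, :] = tau
    state.C, state.P, state.VN, state.LY = C2, P2, VN2, LY2

    # --- decay, release, replacement -------------------------------------
    state.V = V * (1.0 - delta) + yields
    state.B = B0 - float(C2.sum())
    state.t += 1
    return state


def meanfield_run(strains: Sequence[StrainParams], env: EnvConfig,
                  n_steps: int,
                  state: MeanFieldState | None = None
                  ) -> Tuple[MeanFieldState, np.ndarray]:
    """Run and record (t, V0, V1, B, I) per step (end-of-step census)."""
    if state is None:
        state = initial_meanfield(strains, env)
    rec = np.empty((n_steps, 5))
    for k in range(n_steps):
        meanfield_step(state, strains, env)
        rec[k] = (state.t, state.V[0], state.V[1], state.B, state.I)
    return state, rec


def meanfield_steady_state(strain: StrainParams, env: EnvConfig,
                           *, rtol: float = 1e-10,
                           max_steps: int = 200_000):
    """Iterate the single-strain mean field to its fixed point.

    Returns ``(V_ss, B_ss, I_ss, N_T)`` in the mid-step census used by the
    stochastic steady-state report.
    """
    state = initial_meanfield([strain], env)
    prev = -1.0
    check = max(10 * strain.tau, 200)
    for k in range(max_steps):
        meanfield_step(state, [strain], env)
        if (k + 1) % check == 0:
            v = float(state.V.sum())
            if prev >= 0 and abs(v - prev) <= rtol * max(prev, 1.0):
                break
            prev = v
    v, i = state.V_mid, state.I_mid
    return v, env.B0 - i, i, v + strain.beta * i


def meanfield_competition(res: StrainParams, mut: StrainParams,
                          env: EnvConfig, n_steps: int) -> np.ndarray:
    """Deterministic 50/50 competition started from the resident steady state.

    The resident mean field is run to its fixed point, then every
    compartment is split equally between resident and mutant labels.
    Relabelled cells keep the lysis clock stamped at founding; only cells
    founded after the split use the mutant's own tau and strategy.  Returns
    an array of shape (n_steps, 3) with columns (t, V_res, V_mut).
    """
    state = initial_meanfield([res], env)
    prev = -1.0
    for k in range(200_000):
        meanfield_step(state, [res], env)
        if (k + 1) % 200 == 0:
            v = float(state.V.sum())
            if prev >= 0 and abs(v - prev) <= 1e-12 * max(prev, 1.0):
                break
            prev = v
    pair = [res, mut]
    if mut.tau > state.C.shape[0]:
        A2 = mut.tau
        for name in ("C", "VN", "LY"):
            old = getattr(state, name)
            new = np.zeros((A2, 2), dtype=old.dtype)
            new[: old.shape[0]] = old
            setattr(state, name, new)
        P2 = np.zeros((A2, 2, 2))
        P2[: state.P.shape[0]] = state.P
        state.P = P2
    state.V = np.array([state.V[0] / 2.0, state.V[0] / 2.0])
    C, P, VN, LY = state.C, state.P, state.VN, state.LY
    C[:, 1] = C[:, 0] / 2.0
    C[:, 0] /= 2.0
    P[:, 1, 1] = P[:, 0, 0] / 2.0
    P[:, 0, 0] /= 2.0
    VN[:, 1] = VN[:, 0] / 2.0
    VN[:, 0] /= 2.0
    LY[:, 1] = LY[:, 0]
    rec = np.empty((n_steps, 3))
    for k in range(n_steps):
        meanfield_step(state, pair, env)
        rec[k] = (state.t, state.V[0], state.V[1])
    return rec
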