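"""Unit and property tests of the per-agent engine and its fast kernels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phagesieve as pg
from phagesieve import _kernels
from phagesieve.engine import (EnvConfig, InfectedCell, PopulationState,
                               SimState, StrainParams, assign_targets,
                               decay_free, draw_infections, grow_intracellular,
                               initial_state, lyse, replace_lysed, step)


def make_state(free, cells=None, B0=1000):
    cells = cells or []
    return PopulationState(t=0, free=dict(free), B=B0 - len(cells),
                           cells=cells)


# ---------------------------------------------------------------- parameters

@pytest.mark.parametrize("kw", [
    {"alpha": -1e-6}, {"beta": 0.0}, {"beta": -5.0}, {"tau": 0},
    {"strategy": "XX"},
])
def test_strain_params_rejects_invalid(kw):
    with pytest.raises(ValueError):
        StrainParams(label="x", **kw)


@pytest.mark.parametrize("kw", [{"B0": 0}, {"delta": 1.5}, {"delta": -0.1}])
def test_env_config_rejects_invalid(kw):
    with pytest.raises(ValueError):
        EnvConfig(**kw)


# ------------------------------------------------------------- draw/adsorb

def test_no_free_phage_means_no_infections(rng):
    strain = StrainParams(label="r", alpha=1e-3)
    state = make_state({"r": 0})
    assert draw_infections(state, strain, rng, 1000) == 0


def test_infection_draw_capped_at_free_count(rng):
    strain = StrainParams(label="r", alpha=1.0)  # huge Poisson mean
    state = make_state({"r": 5})
    for _ in range(20):
        assert draw_infections(state, strain, rng, 1000) <= 5


def test_infection_draw_mean_matches_poisson_rate(rng):
    # mean of Poisson(alpha*V*(B+I)) = 3e-6 * 40000 * 1000 = 120
    strain = StrainParams(label="r", alpha=3e-6)
    state = make_state({"r": 40000})
    n = 100_000
    draws = [draw_infections(state, strain, rng, 1000) for _ in range(n)]
    mean = np.mean(draws)
    sem = np.std(draws) / math.sqrt(n)
    assert abs(mean - 120.0) < 4 * sem


def test_single_phage_founds_cell_with_its_tau(rng):
    strain = StrainParams(label="r", tau=9)
    state = make_state({"r": 1})
    assign_targets({"r": 1}, state, {"r": strain}, rng, 1000)
    assert state.free["r"] == 0
    (cell,) = state.cells
    assert cell.founder == "r" and cell.lysis_age == 9
    assert cell.pseudo == {"r": 1.0} and cell.n_entered == 1


def test_same_step_founder_chosen_uniformly(rng):
    # two phage of different strains hit the one available cell in one step
    strains = {"a": StrainParams(label="a"), "b": StrainParams(label="b")}
    counts = {"a": 0, "b": 0}
    reps = 10_000
    for _ in range(reps):
        state = make_state({"a": 1, "b": 1}, B0=1)
        state.B = 1
        assign_targets({"a": 1, "b": 1}, state, strains, rng, 1)
        counts[state.cells[0].founder] += 1
    frac = counts["a"] / reps
    assert abs(frac - 0.5) < 4 * math.sqrt(0.25 / reps)


def test_sx_founded_cell_absorbs_later_phage_unchanged(rng):
    strains = {"r": StrainParams(label="r", strategy="SX"),
               "m": StrainParams(label="m", strategy="S")}
    cell = InfectedCell(founder="r", lysis_age=15, age=3,
                        pseudo={"r": 1.0}, n_entered=1)
    state = make_state({"r": 0, "m": 4}, cells=[cell], B0=1)
    excluded = assign_targets({"m": 4}, state, strains, rng, 1)
    assert state.free["m"] == 0          # phage debited regardless
    assert excluded["m"] == 4            # absorbed and lost
    assert cell.pseudo == {"r": 1.0} and cell.n_entered == 1


def test_s_founded_cell_accepts_entry(rng):
    strains = {"r": StrainParams(label="r", strategy="S"),
               "m": StrainParams(label="m", strategy="S")}
    cell = InfectedCell(founder="r", lysis_age=15, age=3,
                        pseudo={"r": 5.0}, n_entered=1)
    state = make_state({"m": 1}, cells=[cell], B0=1)
    assign_targets({"m": 1}, state, strains, rng, 1)
    assert cell.pseudo == {"r": 5.0, "m": 1.0} and cell.n_entered == 2


# ---------------------------------------------------------------- growth

def test_single_infection_grows_to_one_plus_beta():
    strains = {"r": StrainParams(label="r", beta=100.0, tau=15)}
    cell = InfectedCell(founder="r", lysis_age=15, pseudo={"r": 1.0})
    for _ in range(15):
        grow_intracellular(cell, strains)
    assert cell.age == 15
    assert cell.pseudo["r"] == pytest.approx(1.0 + 15 * (100.0 / 15))


def test_absent_second_strain_reduces_to_constant_rate():
    strains = {"r": StrainParams(label="r", beta=60.0, tau=10),
               "m": StrainParams(label="m", beta=90.0, tau=10)}
    solo = InfectedCell(founder="r", lysis_age=10, pseudo={"r": 2.0})
    with_zero = InfectedCell(founder="r", lysis_age=10,
                             pseudo={"r": 2.0, "m": 0.0})
    grow_intracellular(solo, strains)
    grow_intracellular(with_zero, strains)
    assert with_zero.pseudo["r"] == pytest.approx(solo.pseudo["r"])
    assert with_zero.pseudo["m"] == 0.0


def test_equal_strains_share_growth_symmetrically():
    strains = {"a": StrainParams(label="a", beta=100.0, tau=15),
               "b": StrainParams(label="b", beta=100.0, tau=15)}
    cell = InfectedCell(founder="a", lysis_age=15,
                        pseudo={"a": 3.0, "b": 3.0}, n_entered=2)
    grow_intracellular(cell, strains)
    solo_rate = 100.0 / 15
    assert cell.pseudo["a"] == pytest.approx(3.0 + solo_rate / 2)
    assert cell.pseudo["b"] == pytest.approx(3.0 + solo_rate / 2)


def test_growth_past_lysis_age_is_a_contract_violation():
    strains = {"r": StrainParams(label="r")}
    cell = InfectedCell(founder="r", lysis_age=2, age=2, pseudo={"r": 1.0})
    with pytest.raises(ValueError):
        grow_intracellular(cell, strains)


# ------------------------------------------------------------------ lysis

def test_mean_burst_is_beta_regardless_of_reentries(rng):
    """A cell entered only by one strain yields beta on average (S and SX)."""
    beta, tau = 80.0, 10
    for strategy in ("S", "SX"):
        strains = {"r": StrainParams(label="r", beta=beta, tau=tau,
                                     strategy=strategy)}
        totals = []
        for k in range(100_000):
            # founder plus k%4 same-strain re-entries at random ages
            extra = k % 4
            cell = InfectedCell(founder="r", lysis_age=tau,
                                pseudo={"r": 1.0}, n_entered=1)
            entry_ages = sorted(rng.integers(0, tau, size=extra))
            for a in range(tau):
                for ea in entry_ages:
                    if ea == a:
                        cell.pseudo["r"] += 1.0
                        cell.n_entered += 1
                grow_intracellular(cell, strains)
            totals.append(lyse(cell, strains, rng)["r"])
        totals = np.asarray(totals)
        sem = totals.std() / math.sqrt(len(totals))
        assert abs(totals.mean() - beta) < 3 * sem, strategy


def test_mixed_cell_partition_is_exhaustive(rng):
    strains = {"a": StrainParams(label="a", strategy="S"),
               "b": StrainParams(label="b", strategy="S")}
    for _ in range(2000):
        pa, pb = rng.uniform(1, 120, size=2)
        vn = int(rng.integers(1, 5))
        cell = InfectedCell(founder="a", lysis_age=4, age=4,
                            pseudo={"a": pa, "b": pb}, n_entered=vn)
        y = lyse(cell, strains, rng)
        assert y["a"] >= 0 and y["b"] >= 0


def test_sx_lysis_yields_founder_only(rng):
    strains = {"r": StrainParams(label="r", beta=50.0, strategy="SX",
                                 tau=15),
               "m": StrainParams(label="m", beta=50.0, strategy="S",
                                 tau=15)}
    cell = InfectedCell(founder="r", lysis_age=15, age=15,
                        pseudo={"r": 30.0}, n_entered=1)
    y = lyse(cell, strains, rng)
    assert set(y) == {"r"}


def test_lysis_away_from_lysis_age_is_a_contract_violation(rng):
    strains = {"r": StrainParams(label="r")}
    cell = InfectedCell(founder="r", lysis_age=15, age=3,
                        pseudo={"r": 1.0})
    with pytest.raises(ValueError):
        lyse(cell, strains, rng)


# ---------------------------------------------------------------- decay

def test_decay_edge_cases(rng):
    state = make_state({"r": 10_000})
    decay_free(state, EnvConfig(delta=0.0), rng)
    assert state.free["r"] == 10_000
    decay_free(state, EnvConfig(delta=1.0), rng)
    assert state.free["r"] == 0


def test_decay_removes_binomial_fraction(rng):
    removed = []
    for _ in range(10_000):
        state = make_state({"r": 10_000})
        decay_free(state, EnvConfig(delta=0.1), rng)
        removed.append(10_000 - state.free["r"])
    mean = np.mean(removed)
    sem = np.std(removed) / 100.0
    assert abs(mean - 1000.0) < 4 * sem


# ------------------------------------------------------------ full steps

def test_empty_population_is_absorbing(rng):
    strains = {"r": StrainParams(label="r")}
    state = make_state({"r": 0})
    for _ in range(50):
        step(state, strains, EnvConfig(), rng)
    assert state.total_free() == 0 and state.I == 0 and state.B == 1000


def test_host_census_conserved_every_step(rng):
    env = EnvConfig(B0=200, delta=0.1)
    strains = {"r": StrainParams(label="r", alpha=1.5e-5, beta=40, tau=6,
                                 strategy="S"),
               "m": StrainParams(label="m", alpha=2e-5, beta=60, tau=9,
                                 strategy="SX")}
    state = initial_state(list(strains.values()), env,
                          v0={"r": 300, "m": 200})
    for _ in range(120):
        step(state, strains, env, rng)
        assert state.B + state.I == env.B0
        assert state.B >= 0 and all(v >= 0 for v in state.free.values())
    # replace_lysed restores conservation by construction
    before = state.B
    replace_lysed(state, 0)
    assert state.B == before


def test_seed_determinism_bitwise():
    res = StrainParams(label="r", alpha=3e-5, strategy="S")
    mut = res.with_(label="m", strategy="SX")
    env = EnvConfig(B0=100)
    runs = []
    for _ in range(2):
        sim = SimState([res, mut], env)
        sim.free[0], sim.free[1] = 150, 60
        sim.seed(987)
        sim.run(300)
        runs.append((sim.free.copy(), sim.infected.copy(), sim.p.copy(),
                     sim.age.copy(), sim.vn.copy()))
    for a, b in zip(*runs):
        np.testing.assert_array_equal(a, b)


def test_reference_engine_and_kernels_agree_distributionally(rng):
    """Dual-route check: per-agent reference vs flat-array kernels.

    Both implementations of the same stochastic rules must produce the
    same ensemble means of (V_res, V_mut, I) on a small mixed-strategy
    system within Monte-Carlo error.
    """
    env = EnvConfig(B0=100)
    res = StrainParams(label="r", alpha=3e-5, beta=40.0, tau=8,
                       strategy="S")
    mut = res.with_(label="m", beta=60.0, tau=6, strategy="SX")
    strains = {"r": res, "m": mut}
    n_reps, n_steps = 300, 40
    ref = np.empty((n_reps, 3))
    for k in range(n_reps):
        state = initial_state([res, mut], env, v0={"r": 150, "m": 100})
        for _ in range(n_steps):
            step(state, strains, env, rng)
        ref[k] = (state.free["r"], state.free["m"], state.I)
    fast = np.empty((n_reps, 3))
    for k in range(n_reps):
        sim = SimState([res, mut], env)
        sim.free[0], sim.free[1] = 150, 100
        sim.seed(40_000 + k)
        sim.run(n_steps)
        fast[k] = (sim.free[0], sim.free[1], sim.I)
    for j in range(3):
        d = ref[:, j].mean() - fast[:, j].mean()
        se = math.sqrt(ref[:, j].var(ddof=1) / n_reps
                       + fast[:, j].var(ddof=1) / n_reps)
        assert abs(d) < 4 * se, f"component {j}: {d} vs {se}"


def test_adsorption_bookkeeping_balances_free_pool():
    """Phage leaving the free pool = infections drawn, SX losses included."""
    res = StrainParams(label="r", alpha=5e-5, strategy="SX")
    env = EnvConfig(B0=100, delta=0.0)  # no decay: only adsorption removes
    sim = SimState([res], env)
    sim.free[0] = 2000
    sim.seed(7)
    before = int(sim.free[0])
    n0, n1, _ = _kernels.step(*sim.arrays, *sim.params)
    released = int(sim.free[0]) - (before - n0 - n1)
    assert released >= 0  # any increase is lysis yield, not phantom phage


def test_sx_purity_in_full_simulation():
    """SX-founded cells never accumulate non-founder pseudo mass."""
    res = StrainParams(label="r", alpha=3e-5, strategy="SX")
    mut = res.with_(label="m")
    env = EnvConfig(B0=100)
    sim = SimState([res, mut], env)
    sim.free[0] = sim.free[1] = 1000
    sim.seed(99)
    for _ in range(50):
        sim.run(1)
        inf = sim.infected == 1
        f = sim.founder[inf]
        assert (sim.p[inf, 1][f == 0] == 0).all()
        assert (sim.p[inf, 0][f == 1] == 0).all()


# -------------------------------------------------------- steady state

def test_extinction_flagged_below_persistence_threshold():
    # beta far below the persistence threshold: production cannot match loss
    res = StrainParams(label="r", beta=2.0)
    with pytest.raises(pg.PhageExtinctionError):
        pg.run_to_steady_state(res, EnvConfig(B0=200), seed=3)


def test_steady_state_independent_of_inoculum(small_setup):
    res, env_s, ss = small_setup("SX")
    base = ss.V_ss
    for v0_mult, seed in ((1, 5), (10, 6)):
        sim = SimState([res], env_s)
        sim.free[0] = v0_mult * env_s.B0
        sim.seed(seed)
        status, _, v, b, i = _kernels.run_to_steady(
            *sim.arrays, *sim.params, 300, 500, 1e-2, 100_000)
        assert status == 1
        v_avg, _, _ = _kernels.run_average(*sim.arrays, *sim.params, 4000)
        assert abs(v_avg - base) / base < 0.05  # fluctuation band


@settings(deadline=None, derandomize=True, max_examples=20)
@given(v=st.integers(0, 3000), seed=st.integers(0, 2**20))
def test_population_counts_stay_nonnegative(v, seed):
    res = StrainParams(label="r", alpha=5e-5, beta=30, tau=4, strategy="S")
    env = EnvConfig(B0=50)
    sim = SimState([res], env)
    sim.free[0] = v
    sim.seed(seed)
    sim.run(30)
    assert sim.free.min() >= 0
    assert 0 <= sim.I <= env.B0
    assert (sim.p >= 0).all()
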