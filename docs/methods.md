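# Methods

## The stochastic engine

The simulation is a discrete-time agent-based model of lytic phage on a
bacterial population held at constant census `B0` (a turbidostat: every
lysed host is replaced by an uninfected one in the same step). State is
the free-phage count per strain, plus one record per infected cell:
founder strain, infection age, the founder's lysis age, per-strain
intracellular pseudo-population masses `p`, and the count `V_n` of phage
that have entered.

Each step executes, in order, using start-of-step counts for adsorption:

1. **Adsorption.** Per strain, the number of infecting phage is
   `Poisson(alpha * V * (B + I))`, capped at the available free count
   (count conservation); all of them leave the free pool whatever happens
   next. Targets are uniform with replacement among all `B0` hosts. A
   previously uninfected target becomes an infected cell; when several
   phage hit it in the same step the founder is uniform among them. An
   infected target admits the phage (`p += 1`, `V_n += 1`) if its founder
   superinfects, and absorbs and destroys it if its founder excludes.
   Same-step co-arrivals behind an excluding founder are likewise lost,
   which keeps exclusion airtight from the moment of founding.
2. **Replication.** Cells founded in an earlier step grow: a lone strain
   adds `beta/tau` to its mass; two strains sharing a cell each add
   `(beta_s/tau_s) * p_s / sum(p)` — intracellular competition for host
   resources. A cell founded this step starts growing next step, so a solo
   founder reaches `p = 1 + beta` after exactly `tau` growth steps.
3. **Lysis.** A cell bursts `tau` steps after founding. Excluding cells
   release `Poisson(beta_founder)` copies of the founder. Superinfecting
   cells release `Poisson(max(sum(p) - V_n, 0))`, binomially partitioned
   by pseudo-population share; subtracting `V_n` makes every same-strain
   entry burst-neutral, so a cell entered by a single strain averages
   exactly `beta` progeny no matter how many phage entered.
4. **Decay.** Each free phage present before this step's releases is
   removed with probability `delta * dt`; progeny released this step join
   the pool afterwards and can neither adsorb nor decay until the next
   step.
5. **Replacement.** Lysed hosts return as uninfected cells, so
   `B + I = B0` at the end of every step.

Lysis time is deterministic; at most two concurrent strains are supported;
there is no recombination, reassortment, complementation or spatial
structure.

**Census convention.** Reported population sizes (`V_ss`, `B_ss`, `I_ss`,
and `N_T = V_ss + beta * I_ss`) are running averages of the *mid-step*
census: free phage counted after adsorption, infected cells counted
through the step in which they lyse. Counting instead at the end of the
step gives an infected census smaller by one lysis cohort,
`I_ss * (1 + 1/tau) ≈ I_mid`; the mid-step convention is the one under
which the default parameters give `I_ss ≈ 680` and a generation time of
24.8 steps.

Two equivalent implementations exist: a per-agent reference
(`engine.py`), kept readable and used to define semantics, and flat-array
numba kernels (`_kernels.py`) used by every driver; the test suite checks
them against each other distributionally. With one seeded generator per
trial, trajectories are bit-reproducible; experiment drivers derive
per-trial seeds from a master seed via `numpy.random.SeedSequence`.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `alpha` | 3e-6 | per phage per host per step | gives `alpha*B0 = 3e-3`/min, matching coliphage adsorption relative to realistic host densities |
| `beta` | 100 | phage | typical lytic burst |
| `tau` | 15 | steps (min) | typical lysis time |
| `delta` | 0.1 | per step | decay plus turbidostat outflow; sustains a steady state |
| `B0` | 1000 | cells | large enough for weak demographic noise, small enough to simulate millions of invasions |
| inoculum | `2*B0` free phage | | standard initialisation for steady-state runs |

`scaled_census(strain, env, x)` rescales `B0 -> x*B0` and
`alpha -> alpha/x`, preserving every per-phage rate and all steady-state
densities per host; reduced-census experiments (`B0 = 100`) are used where
fixation probabilities would otherwise be ~1e-5.

## Steady-state detection

Running means of V, B and I over consecutive windows of 500 steps must
each change by less than 1% (after a burn-in of at least `10*tau` steps);
the reported values then average a further 5000 steps. Extinction (free
and infected both zero) and non-convergence raise distinct errors. The
steady state is independent of the inoculum size, which the suite checks.

## Neutral dynamics and Ne

A steady-state population is split 50/50 into two parameter-identical
alleles: free phage binomially, infected cells whole (founder plus all
pseudo mass) with probability 1/2 each. The census-weighted allele
frequency counts each infected cell as `beta` phage-equivalents split by
pseudo-population ownership, consistent with `N_T`; a free-phage-only
frequency would ignore the majority of the census (`beta*I/N_T ≈ 0.62` at
defaults). Heterozygosity `H(t) = 2<f(1-f)>` is averaged over independent
replicates (absorbed replicates contribute 0), and `log H` is fitted by
least squares over a late-time window that opens when H first drops below
0.45 of its initial value (clear of the relaxation transient) and closes
when fewer than 20% of replicates remain polymorphic (beyond which H is a
handful of trajectories). `Ne = 2/(Lambda*T)` converts the per-step decay
rate with the generation time `T = tau + 1/(delta + alpha*I_ss)`, derived
from the age-specific survival (decay plus adsorption to infected hosts)
and fertility (adsorption to uninfected hosts, `beta - 1` net offspring
`tau` later) of a free phage. The same `T` serves both strategies: a lone
strain's demography is strategy-independent.

Replicates share one burn-in and are decorrelated by 50 extra steps each;
this trades a negligible correlation for a large constant-factor saving.

## Fitness measures

**Isolated growth.** `0.01*B0` phage are inoculated into `B0` uninfected
hosts; `log V` is fitted per replicate from the time the count clears
`max(50, 10*V0)` — past the decay of the unadsorbed inoculum and the
first-burst sawtooth — until 25% of the strain's mean-field steady state,
then averaged over replicates (default 500). Replicates that die out or
never produce a 10-point window are discarded and counted; at the default
inoculum roughly three quarters survive. Growth rates are
strategy-independent, so grids measure each parameter set once.

**Competition.** From a decorrelated steady-state snapshot, half the
population is relabelled as the mutant; the ensemble-mean
`ln(V_mut/V_res)` is fitted from `2*tau` steps after the split (letting
the relabelled cell generation wash out) for up to 600 steps. For strong
selection the window closes early, once the mean log-ratio has moved 2.0,
because past that point the losing strain's free count is small enough
for discreteness and extinction-conditioning to bend the trajectory —
without this guard, gradients fitted over ±30% burst-size grids are
biased low by ~10%. Replicates losing either strain inside the window are
excluded and reported.

**Sigma.** `s_comp` is regressed through the origin on `s_growth` over
±15% and ±30% single-parameter grids (lysis-time grids truncate to
integer steps: 11, 13, 17, 19). The quoted standard error combines the
regression residuals with the propagated growth-rate errors.

At the defaults the package finds `sigma_beta` slightly above 1 for
superinfecting and slightly below 1 for excluding populations;
`sigma_tau(SX) = 0` exactly — in a turbidostat, cycling faster does not
increase the supply of winnable hosts, so a lysis-time change alone is
competitively neutral under exclusion — while superinfecting lysis-time
mutants retain a reduced but positive gradient through intracellular
competition; and `sigma_alpha` is a few percent below 1 in both
strategies, with adsorption-rate and burst-size changes giving almost
equal growth-rate sensitivity, as the underlying renewal demography
implies.

## Fixation experiments

Each invasion trial adds one free mutant phage to a steady-state snapshot
and runs to absorption. A strain is alive while it has free phage *or*
intracellular pseudo mass — a mutant surviving only inside a cell is not
dead, its progeny may still be released. Snapshots come from a single
burn-in advanced 50 steps between uses (each snapshot reused for 10
trials); trials hitting `max_steps = 1e6` are reported as censored, never
as fixations. `P_fix = n_fix/n` with binomial error
`sqrt(P(1-P)/n)`. The Moran benchmark is parameterised entirely by
measured quantities: `Ne` from heterozygosity decay, `s = sigma *
s_growth`, `f0 = 1/N_T`; it is a small-`s` diffusion result and is only
asserted in that regime.

Strategy-switch invasions need no extra machinery: cell behaviour always
follows the founder's strategy, so an excluding mutant's cells are closed
to the superinfecting resident while the mutant exploits resident cells,
and vice versa.

## The mean-field companion

`meanfield.py` applies the expectation of every engine rule in the same
phase order, with infected cells grouped into cohorts by (age, founder)
carrying aggregate pseudo masses, entered counts and the lysis age
stamped at founding. Founding uses the exact per-cell hit probability
`1 - exp(-sum(alpha_s V_s))`. The only closure is evaluating the
nonlinear per-cell rules on cohort aggregates — exact for single-strain
cohorts, second-order accurate otherwise. It is deterministic, conserves
hosts exactly, and matches the stochastic steady state to well under 1%
at the defaults.

## What the simulations do and do not show

All results are properties of this idealised model: constant host census,
well-mixed encounters, deterministic lysis time, burst-neutral re-entry,
and exclusion that is absolute from the founding step. Real phage
populations have stochastic lysis timing, host physiology and spatial
structure, leaky or delayed exclusion, and intracellular interactions
(recombination, defective particles) that are deliberately absent here —
the package quantifies the baseline effect of superinfection alone.
Reduced-census runs preserve per-host rates but amplify drift and the
early-survival advantage of rare superinfecting mutants; quantities
measured at `B0 = 100` are calibrations of the method, not predictions
for the full-size system.

## Problem sizes used by tests and the acceptance script

Unit and property suites run small systems (`B0` 50–250, tens of steps,
1e4–1e5 Monte-Carlo draws). The acceptance script uses the full default
census for the steady state and sigma gradients (3000 growth replicates
and 200 competitions per grid point) and the one-tenth census for
neutral-invasion calibration (1e6 trials per strategy), sizes at which
every reported quantity's sampling error is a few percent.
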