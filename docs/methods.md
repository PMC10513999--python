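# Methods

## Model

An emotion episode is a pairwise binary Markov random field over `n`
components.  The canonical internal parametrization is the spin coding
`s_i ∈ {−1, +1}`; energy (up to sign convention)

    E(s) = −( Σ_{i<j} w_ij s_i s_j + Σ_i (τ_i + e(t)) s_i ),

with symmetric couplings `w_ij` (connectivity), per-component fields `τ_i`
(thresholds, the disposition to be active), inverse temperature `β`, and a
uniform time-varying external field `e(t)` for the eliciting event.
Intensity is the fraction of components at `+1`.

Spin coding is canonical because only there do *inactive* neighbours
actively suppress activation through positive couplings — the mechanism by
which a densely connected network lowers its own resting intensity.  The
0/1 (binary) coding, natural for logistic-regression estimates, is related
by the exact involution `w_spin = w_bin/4`, `τ_spin = τ_bin/2 + Σ_j w_bin,ij/4`;
the full state distribution is identical under the mapping `s = 2x − 1`
(verified to 1e-10 by enumeration in the tests).  Negative couplings are
allowed; no positivity constraint is imposed.  Networks are dense matrices;
the intended regime is `n ≤ ~30` (component sets are ~10 items).

## Dynamics

Asynchronous Glauber dynamics: one sweep (the unit of time) performs `n`
single-component updates, each resampling component `i` from

    P(s_i = +1 | rest) = 1 / (1 + exp(−2β(Σ_j w_ij s_j + τ_i + e(t)))).

The default update order is a fresh random permutation per sweep
("random sequential"): every component is updated exactly once per time
unit, and each single-site update leaves the Boltzmann distribution
invariant, so at constant field the chain samples the stationary law (the
test suite checks total-variation agreement with exact enumeration on the
full 2^n state space).  A fixed-cycle order is available.  Synchronous
updating is deliberately not offered — it can introduce artificial
oscillations.

Runs start from the all-inactive rest state and equilibrate for a 100-sweep
burn-in at zero field before recording.  A random initial state would seed
the high-intensity basin of bistable networks in a fraction of runs and
contaminate the resting baseline; the all-inactive start confines the
pre-event state to the resting basin, which is the psychologically relevant
condition.  Replicate runs get independent streams spawned from a single
seed (`numpy.random.SeedSequence`), so ensembles are bit-reproducible and no
draw anywhere is unseeded.

The event schedule is: `baseline_sweeps` at field 0, `hold_sweeps` at
`amplitude`, a fade to zero over `fade_sweeps` (linear by default;
exponential with time constant `fade_sweeps/5` optional), then
`post_sweeps` at zero.  Defaults — 100 baseline, amplitude 2, 20 hold,
50 fade, 800 post, β = 1 — define the study conditions used throughout the
tests and the acceptance script.  Amplitude 2 saturates a 10-component
network during the hold without freezing the dynamics, and the 800-sweep
post-event window is long enough for every condition except the doubled-
connectivity fear network, whose stochastic escape can exceed it (censored
episodes then contribute the window length, a lower bound).

## Episode detection

Baseline intensity is the mean over runs × baseline sweeps; its SE is taken
across run-level means (runs are independent; sweeps within a run are not).
The episode end is the *first return to baseline*: scanning from event
onset, the ensemble mean `m_t` must first rise above
`baseline + k·SE_t` (emergence; cross-run SE), and the episode ends at the
first subsequent sweep with `m_t ≤ baseline + k·SE_t`.  The emergence phase
matters: with a wide band (large `k`) the raw condition
"`m_t ≤ baseline + k·SE_t`" is already true at onset, before any episode
exists, and would always report duration zero.  If the mean never emerges
there is no episode (duration 0); if it emerges and never returns within
the window the summary is censored.  The default `k = 1.645` is a one-sided
5% normal criterion; `k` is configurable because the choice is a decision
convention, not part of the model — note that duration is non-increasing in
`k` (a wider band can only end the episode earlier).  A comparison helper
measures durations over independent replicate ensembles (default in the
acceptance material: 12 replicates of 200 runs) so that condition contrasts
carry a standard error; 12 replicates provide adequate power for one-sided
3-SE contrasts even when replicate durations are strongly dispersed, as they
are for bistable networks under a wide band.

Profile statistics: variance of the per-sweep ensemble mean within the
episode and after it, and a decay half-life — sweeps from the end of the
hold until the mean first falls below the midpoint of peak and baseline.
In the calibrated regime the half-life cleanly orders the threshold
mechanism (lower thresholds → faster decay, higher → slower with higher
resting variance).  For the doubled-connectivity network the *ensemble*
half-life instead tracks the dispersion of per-run escape times and is not
a useful abruptness measure; abruptness there shows in the within-episode
variance and the duration/connectivity relation.

## Probable states

The stationary distribution of intensity is computed exactly by enumerating
all `2^n` states (limit `n = 20`, ~10^6 states, chunked with log-sum-exp
normalization so large β or fields cannot overflow) or by a long thinned
Glauber chain; both routes agree within sampling error on test fixtures and
are computed at field 0 (the between-events regime).  Shape statistics:
`low_mass = P(I ≤ 0.2)`, `high_mass = P(I ≥ 0.8)`,
`mid_mass = P(0.4 ≤ I ≤ 0.6)`, a bimodality flag
(`low > mid` and `high > mid`), and the standardized third moment (reported
as 0, flagged degenerate, for near-point distributions).

## Estimation

Nodewise ℓ1-penalized logistic regression (eLasso): each component is
regressed on all others over a 50-point geometric penalty grid from the
node's maximal penalty λ_max = max_j |x_jᵀ(y − ȳ)|/N down by 10^3, the
penalty chosen per node by EBIC
(−2·LL + df·ln N + 2γ·df·ln(n−1), γ = 0.25 by default), edges kept under
the AND rule with mean-of-coefficients weights (OR rule behind a flag),
thresholds from the intercepts.  Fits use scikit-learn's liblinear solver
with a large intercept scaling so the intercept is effectively unpenalized.
Constant or perfectly predictable columns cannot break the pipeline: they
are flagged (penalty floor reached or runaway coefficients) and yield empty
neighbourhoods rather than errors.  Results are reported in binary coding;
`convert_coding` maps them to spin.

Recovery benchmark: balanced random 10-node networks (edge probability 0.4,
spin magnitudes |N(0.25, 0.05)|, 20% negative, thresholds N(0, 0.2)),
N = 3000 exact stationary draws.  Median weight correlation is ≈ 0.99 with
100% sign agreement, improving monotonically over N ∈ {500, 1500, 3000}.
Strongly coupled, rarely-activating networks (like the fear-like fixture)
are harder — their components are nearly constant in cross-section — which
is a property of the design, not the optimizer.

## Synthetic networks

`make_fixture_network` generates the two canonical 10-component study
objects, in spin coding:

| parameter | fear_like | awe_like |
| --- | --- | --- |
| edge probability | 0.5 (22 of 45 pairs) | same |
| edge magnitude | \|N(0.42, 0.10)\| | \|N(0.14, 0.05)\| |
| negative edges | 10% | same |
| thresholds | N(−0.45, 0.1) | same |

Edge count, negative-edge count, and total coupling magnitude are held
fixed per kind; only the topology and the spread of strengths vary with the
seed.  Without this, binomial edge-count variance moves realizations across
the bistability boundary and the two kinds stop discriminating reliably.
These constants are calibration choices of this package — they are not
estimates from any dataset.  They were chosen so that one parameter set
jointly exhibits all the qualitative phenomena: the connectivity and
threshold duration effects, baseline suppression vs. elevation, the awe
rescue (threshold shifts only help once connectivity is doubled), and the
probable-state shapes (bimodality at factor 2 requires couplings strong
enough that the doubled network is genuinely bistable, which in turn is why
its post-event escape is slow).  The bimodality flag holds for generator
seeds 0–5; seeds 6–7 produce topologies whose middle states retain slightly
more mass.  The canonical study objects use seed 0.  The probable-state
"high thresholds" panel uses shift +1.0 (making mean thresholds positive so
components tend active); the duration/baseline contrasts use shift +0.4.

What the generator emulates: realistic scale (10 components), mixed-sign
sparse couplings, dispositionally-off components, and the dense/strong vs.
sparse/weak contrast between a fear-type and an awe-type network.  What it
does not: empirically estimated weights, ordinal rating noise, person-level
heterogeneity, or any structural features (small-worldness, communities) of
real emotion networks.  Passing tests therefore demonstrate the *mechanism*
claims on networks with these coarse properties, not quantitative claims
about any empirical network.

The common-cause comparator is an (n+1)-node star: one latent cause coupled
to every component (loading), no component–component edges, components and
cause dispositionally off (thresholds −1).  Reported intensity excludes the
cause node.  Its defining behaviour — the episode cannot outlive the fading
event, because components cannot reactivate each other — holds at every
loading tested.  One caveat: the *exact* duration retains a small kinetic
dependence on loading (≈ 2 sweeps between loadings 0.3 and 1.0 under the
default schedule) because the loading shifts when during the fade a
component's effective field crosses zero; with thousands of simulated runs
this real effect is resolvable far beyond its practical relevance, so
strict statistical equivalence tests on the two durations fail even though
both end within a few sweeps of the fade end.

## Numerical and design choices

* The Glauber inner loop is a numba-compiled kernel fed with pre-generated
  uniforms and update orders, so all randomness stays in NumPy generators
  and results are bit-stable across runs and machines.
* Exact enumeration uses float64 log-weights with `logsumexp`; probabilities
  are renormalized once to remove residual rounding.
* Weight-matrix symmetry is enforced at 1e-12; file loaders name the
  violated invariant in their error messages.
* Network JSON/CSV writers emit full-precision floats (`repr`) and readers
  parse with round-trip precision, so file round-trips are lossless.
* The experiment driver spawns one sub-seed per grid cell from the top
  seed; a failing cell is logged and skipped without aborting the grid.

## Problem sizes

The shipped tests and the acceptance script use 10-component networks,
ensembles of 200 runs, 12 replicate ensembles per condition, 50,000-sweep
chains (thinned by 10) for sampler-vs-enumeration checks, and N = 3000
observations × 10 seeds for estimator recovery.  The full test suite runs
in a few minutes on one CPU; the acceptance script in about a minute.

## Limitations

* Undirected, pairwise, binary: no directed/acyclic causal structure, no
  higher-order interactions, no continuous component states.
* One episode per simulation; no segmentation of long free-running series
  and no fitting of empirical experience-sampling data.
* The first-return rule operates on the ensemble mean; per-run episode
  definitions (needed for single-subject analyses) are out of scope.
* Enumeration is capped at 20 nodes; larger networks rely on sampling.
* Fixture calibration is one point in a large space; conclusions from the
  fixtures are qualitative orderings, not effect-size estimates.
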