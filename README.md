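# emonet

Stochastic network models of emotion episodes: simulation, episode-duration
analytics, probable-state distributions, and network estimation from
cross-sectional binary data.

## The problem

Emotional episodes vary enormously in how long they last, and many predictors
of duration (neuroticism, rumination, reappraisal, event relevance, ...) have
been catalogued without a mechanism connecting them.  A network view of
emotions offers one: an episode is a set of binary *components* — appraisals,
feelings, action tendencies, physiological changes, expressions — that
causally activate and deactivate each other.  Two global characteristics of
such a network then govern its dynamics:

* **connectivity** — the average strength of the pairwise causal
  relationships, and
* **thresholds** — each component's disposition to be active absent input.

`emonet` implements this model as a pairwise binary Markov random field (an
Ising model).  Components take states s_i ∈ {−1, +1}, couplings live in a
symmetric weight matrix W, and dispositions in a threshold vector τ.  States
evolve by single-component Glauber dynamics,

    P(s_i = +1 | s_-i) = 1 / (1 + exp(−2β(Σ_j w_ij s_j + τ_i + e(t)))),

where e(t) is a uniform external field representing an emotion-eliciting
event that holds and then fades.  Emotion **intensity** at any moment is the
fraction of active components; an episode **ends at the first return to
baseline** — the first post-onset time at which mean intensity is no longer
significantly larger (a configurable k·SE rule) than the pre-event mean.
At constant field the chain's stationary law is the Boltzmann distribution

    P(s) ∝ exp(β(Σ_{i<j} w_ij s_i s_j + Σ_i (τ_i + e) s_i)),

which the package also computes exactly by enumeration for networks up to 20
nodes — the "probable states" a person with that network would visit.

The package ships, as first-class tested code, a synthetic-data module that
generates *fear-like* (strong, dense couplings) and *awe-like* (weak
couplings) 10-component networks plus exact samplers, so every qualitative
phenomenon is reproducible with known ground truth:

* higher connectivity prolongs episodes and *lowers* baseline intensity
  (inactive components keep each other in check);
* higher thresholds prolong episodes and *raise* baseline intensity;
* weakly connected networks need extra connectivity before threshold
  increases can prolong episodes;
* a common-cause comparator (one latent cause, no component–component
  links) cannot outlive the fading event, at any loading strength;
* strongly connected networks occupy especially low and high intensity
  states; high-threshold networks occupy many high states with a skewed
  low tail.

A nodewise estimator (ℓ1-penalized logistic regression per component with
EBIC penalty selection and AND-rule symmetrization — the eLasso approach)
recovers such networks from cross-sectional 0/1 ratings.

## Worked example

```python
import emonet as em

net = em.make_fixture_network("fear_like", seed=0)
sched = em.EventSchedule()  # 100 baseline sweeps, amplitude 2, 20 hold, 50 fade
ens = em.simulate(net, sched, em.SimulationConfig(runs=200, seed=7))
episode = em.first_return_to_baseline(ens)
print(f"baseline intensity: {episode.baseline_mean:.3f} +/- {episode.baseline_se:.4f}")
print(f"episode duration:   {episode.duration_sweeps} sweeps (end at sweep {episode.end_sweep})")

stronger = em.scale_connectivity(net, 2.0)
shape = em.shape_statistics(em.exact_distribution(stronger))
print(f"factor-2 network:   low/mid/high state mass = "
      f"{shape.low_mass:.3f}/{shape.mid_mass:.5f}/{shape.high_mass:.4f}, "
      f"bimodal = {shape.bimodality_flag}")
```

prints

```
baseline intensity: 0.092 +/- 0.0015
episode duration:   95 sweeps (end at sweep 195)
factor-2 network:   low/mid/high state mass = 0.990/0.00013/0.0028, bimodal = True
```

The fear-like network rests at intensity ≈ 0.09; the event (onset at sweep
100) pushes it to saturation, and the ensemble mean first returns to baseline
95 sweeps after onset — 25 sweeps after the external field has fully faded,
because the components keep re-activating each other.  Doubling every
coupling makes the stationary distribution bimodal: virtually all probability
sits at very low or very high intensity, with the middle states a hundred
times rarer than the high ones.

The same operations are exposed on the command line:

```bash
emonet synth --kind fear_like --n-obs 3000 --seed 7 --out ratings.csv
emonet estimate --data ratings.csv --gamma 0.25 --out net.json
emonet simulate --network net.json --runs 200 --seed 1 --out traj.csv
emonet episode --traj traj.csv --k 1.645 --out summary.json
emonet states --network net.json --method exact --out dist.csv
emonet experiment --fixture fear_like --factors 1,2 --shifts 0,0.4 \
    --runs 200 --seed 1 --outdir results/grid
```

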