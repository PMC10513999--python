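"""Episode-duration analytics: baseline, first return to baseline, profile shape.

The end of an emotional episode is operationalized as the *first return to
baseline*: scanning from event onset, the episode ends at the first sweep
whose cross-run mean intensity is no longer significantly larger than the
pre-event baseline.  "Significantly larger" uses a k·SE rule — the mean at
sweep t must exceed ``baseline_mean + k * SE_t``, with SE computed across
replicate runs.  The default k = 1.645 corresponds to a one-sided 5% normal
criterion; k is configurable because the choice of criterion is a display /
decision convention, not part of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .dynamics import EventSchedule, SimulationConfig, TrajectoryEnsemble, simulate
from .network import ComponentNetwork, InvalidParameterError

__all__ = [
    "EpisodeSummary",
    "InsufficientReplicatesError",
    "baseline_intensity",
    "first_return_to_baseline",
    "intensity_profile_stats",
    "replicate_durations",
]

DEFAULT_K = 1.645


class InsufficientReplicatesError(ValueError):
    """Cross-run SE undefined: fewer than two replicate runs."""


@dataclass(frozen=True)
class EpisodeSummary:
    """Summary of one simulated emotional episode (ensemble level).

    ``end_sweep`` / ``duration_sweeps`` are ``None`` when the ensemble mean
    never returned to baseline within the recorded window (``censored``).
    ``decay_halflife_sweeps`` measures how abruptly intensity falls after
    the event: sweeps from the end of the hold phase until the mean first
    drops below halfway between its peak and baseline (NaN if it never does).
    """

    baseline_mean: float
    baseline_se: float
    baseline_window: tuple[int, int]
    onset_sweep: int
    end_sweep: int | None
    duration_sweeps: int | None
    censored: bool
    criterion_multiplier: float
    variance_within_episode: float = float("nan")
    variance_outside_episode: float = float("nan")
    decay_halflife_sweeps: float = float("nan")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["baseline_window"] = list(d["baseline_window"])
        return d


def baseline_intensity(ens: TrajectoryEnsemble) -> tuple[float, float]:
    """Mean and SE of intensity over the pre-event baseline window.

    The mean pools all runs × baseline sweeps; the SE is computed across
    runs from run-level baseline means (runs are independent replicates,
    sweeps within a run are not).
    """
    b = ens.schedule.baseline_sweeps
    if b < 2:
        raise InvalidParameterError("baseline window must span at least 2 sweeps")
    base = ens.intensity[:, :b]
    run_means = base.mean(axis=1)
    mean = float(run_means.mean())
    if ens.runs > 1:
        se = float(run_means.std(ddof=1) / np.sqrt(ens.runs))
    else:
        se = 0.0
    return mean, se


def first_return_to_baseline(
    ens: TrajectoryEnsemble, criterion_multiplier: float = DEFAULT_K
) -> EpisodeSummary:
    """Locate the episode end and duration via the k·SE first-return rule.

    From event onset, the scan first waits for the episode to emerge — the
    first sweep whose cross-run mean ``m_t`` exceeds
    ``baseline_mean + k * SE_t`` — and the episode then ends at the first
    subsequent sweep with ``m_t <= baseline_mean + k * SE_t`` (the first
    intensity no longer significantly larger than baseline).  Duration is
    ``end_sweep - onset``.  If the intensity never emerges above the
    criterion there is no episode (duration 0); if it emerges but never
    returns before the trajectory ends the summary is censored.
    """
    if ens.runs < 2:
        raise InsufficientReplicatesError(
            "first_return_to_baseline needs >= 2 runs to define a cross-run SE"
        )
    k = float(criterion_multiplier)
    if not np.isfinite(k) or k < 0:
        raise InvalidParameterError("criterion multiplier must be finite and >= 0")
    sched = ens.schedule
    onset = sched.onset
    if onset >= ens.sweeps:
        raise InvalidParameterError("schedule has no post-onset sweeps")
    base_mean, base_se = baseline_intensity(ens)
    m = ens.intensity.mean(axis=0)
    se = ens.intensity.std(axis=0, ddof=1) / np.sqrt(ens.runs)
    post = np.arange(onset, ens.sweeps)
    # small absolute tolerance so exact-constant trajectories are not split
    # by one-ulp rounding differences between pooled and per-sweep means
    above = m[post] > base_mean + k * se[post] + 1e-9
    if not above.any():
        end = onset  # never rose above baseline: no episode
    else:
        emerge = int(np.argmax(above))
        returned = ~above[emerge:]
        end = int(post[emerge] + np.argmax(returned)) if returned.any() else None
    if end is not None:
        summary = EpisodeSummary(
            baseline_mean=base_mean,
            baseline_se=base_se,
            baseline_window=(0, sched.baseline_sweeps),
            onset_sweep=onset,
            end_sweep=end,
            duration_sweeps=end - onset,
            censored=False,
            criterion_multiplier=k,
        )
    else:
        summary = EpisodeSummary(
            baseline_mean=base_mean,
            baseline_se=base_se,
            baseline_window=(0, sched.baseline_sweeps),
            onset_sweep=onset,
            end_sweep=None,
            duration_sweeps=None,
            censored=True,
            criterion_multiplier=k,
        )
    return intensity_profile_stats(ens, summary)


def intensity_profile_stats(
    ens: TrajectoryEnsemble, summary: EpisodeSummary
) -> EpisodeSummary:
    """Attach variance-within/outside-episode and decay half-life to a summary.

    ``variance_within`` is the variance of the per-sweep cross-run mean
    intensity between onset and episode end; ``variance_outside`` the same
    over post-end sweeps.  For a censored episode both are undefined (NaN)
    and only the half-life is reported.
    """
    m = ens.intensity.mean(axis=0)
    sched = ens.schedule
    onset = summary.onset_sweep
    hold_end = sched.baseline_sweeps + sched.hold_sweeps

    # decay half-life: from end of hold until m first falls below the midpoint
    peak = float(m[onset:hold_end].max()) if hold_end > onset else float(m[onset])
    halfway = 0.5 * (peak + summary.baseline_mean)
    tail = m[hold_end:]
    below = tail < halfway
    halflife = float(np.argmax(below)) if below.any() else float("nan")

    if summary.censored or summary.end_sweep is None:
        var_in = var_out = float("nan")
    else:
        end = summary.end_sweep
        within = m[onset:end]
        outside = m[end:]
        var_in = float(within.var(ddof=0)) if within.size else 0.0
        var_out = float(outside.var(ddof=0)) if outside.size else 0.0
    import dataclasses

    return dataclasses.replace(
        summary,
        variance_within_episode=var_in,
        variance_outside_episode=var_out,
        decay_halflife_sweeps=halflife,
    )


def replicate_durations(
    net: ComponentNetwork,
    schedule: EventSchedule,
    config: SimulationConfig,
    criterion_multiplier: float = DEFAULT_K,
    replicates: int = 6,
) -> tuple[np.ndarray, int]:
    """Episode durations from independent replicate ensembles.

    Runs ``replicates`` full ensembles (seeds spawned from ``config.seed``)
    and returns one duration per ensemble, giving a mean and standard error
    for condition comparisons.  Censored ensembles contribute the length of
    the recorded post-onset window (a lower bound on the true duration);
    the number of censored replicates is returned alongside.
    """
    import dataclasses

    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(config.seed).spawn(replicates)
    ]
    durations = np.empty(replicates)
    censored = 0
    horizon = schedule.total_sweeps - schedule.onset
    for b, seed in enumerate(seeds):
        cfg = dataclasses.replace(config, seed=seed)
        ens = simulate(net, schedule, cfg)
        summary = first_return_to_baseline(ens, criterion_multiplier)
        if summary.censored:
            durations[b] = horizon
            censored += 1
        else:
            durations[b] = summary.duration_sweeps
    return durations, censored
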