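"""Synthetic cohorts with the statistical structure the method assumes.

The generator emulates a two-group (learner / non-learner), two-trial
(1 and 12) virtual water-maze study:

* **Theta series** are drawn from group x trial specific Gaussian HMMs
  — the exact generative family the downstream HMM fits assume.  By
  default the trial-1 parameters are *identical* across groups (on the
  first exposure neither group has learned anything, so their theta
  dynamics should be statistically indistinguishable), while the
  learner trial-12 parameters differ from the shared baseline in state
  means (by about 2-3 within-state SDs, in a non-affine pattern that
  survives per-series standardisation), state variances and chain
  persistence — emulating the neural signature of successful learning.
* **Trajectories** are biased random walks on a circular arena sampled
  every 0.25 s with a 60 s cap.  Learners on trial 12 head toward the
  hidden goal (and stop on reaching it); all other group x trial cells
  perform an unbiased correlated random walk for the full (time-matched)
  duration.  Non-learner durations are matched to the mean learner
  duration of the same trial, as in the experimental design.

Hidden truths (generating parameters, hidden state paths, true
durations) are always returned so that parameter-recovery tests can use
them as ground truth.  All randomness flows from the single ``seed`` in
:class:`CohortSpec`, fanned out to named substreams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import ThetaSeries, TrajectorySeries, TRAJECTORY_DT, GROUPS
from .errors import ValidationError
from .hmm import GaussianHMMParams

__all__ = [
    "KinematicParams", "CohortSpec", "default_hmm_truth",
    "default_trajectory_truth", "separated_cohort_spec",
    "simulate_hmm_series", "simulate_trajectory", "simulate_cohort",
]


@dataclass
class KinematicParams:
    """Trajectory-generator parameters for one group x trial cell.

    ``approach_bias`` in [0, 1] is the per-step weight pulling the
    heading toward the goal (0 = unbiased random walk); walkers with a
    positive bias stop when they enter the goal region.  ``idle_prob``
    is the per-step probability of not moving; ``speed`` is the walking
    speed in Vm/s (constant across conditions in the task);
    ``heading_noise_sd`` is the SD of the per-step heading increment in
    radians.
    """

    approach_bias: float = 0.0
    idle_prob: float = 0.05
    speed: float = 4.76
    heading_noise_sd: float = 0.8
    goal_xy: tuple = (0.0, 0.0)
    goal_radius: float = 5.0


def default_hmm_truth() -> dict:
    """Per (group, trial) theta-generating HMMs.

    A shared 4-state baseline for every cell except (learner, 12),
    whose means/variances/persistence are shifted to encode learning.
    """
    base = GaussianHMMParams(
        means=[0.6, 1.0, 1.4, 1.8],
        variances=[0.01, 0.01, 0.01, 0.01],
        transition=_persistent_transition(4, 0.80),
        initial=[0.25, 0.25, 0.25, 0.25],
    )
    # each state mean moved by 3 within-state SDs (outward, so the
    # contrast is not an affine shift and survives per-series z-scoring),
    # with state-dependent variances and higher chain persistence
    learner12 = GaussianHMMParams(
        means=[0.3, 0.7, 1.7, 2.1],
        variances=[0.005, 0.01, 0.02, 0.04],
        transition=_persistent_transition(4, 0.92),
        initial=[0.25, 0.25, 0.25, 0.25],
    )
    return {
        ("learner", 1): base,
        ("non_learner", 1): base,
        ("learner", 12): learner12,
        ("non_learner", 12): base,
    }


def default_trajectory_truth(arena_radius: float = 37.5) -> dict:
    """Per (group, trial) kinematics: random search everywhere except
    goal-directed learner trial 12."""
    goal_radius = np.sqrt(0.15) * arena_radius  # goal is 15% of arena area
    search = KinematicParams(goal_radius=goal_radius)
    directed = KinematicParams(approach_bias=0.10, idle_prob=0.02,
                               heading_noise_sd=0.9, goal_radius=goal_radius)
    return {
        ("learner", 1): search,
        ("non_learner", 1): search,
        ("learner", 12): directed,
        ("non_learner", 12): search,
    }


def separated_cohort_spec(seed: int = 0) -> CohortSpec:
    """A cohort whose trial-12 groups are cleanly separated.

    The forced-separation construction used for end-to-end validation:
    trial-1 truths remain group-identical (a pure null), while the
    learner trial-12 HMM moves every state mean outward by several
    within-state SDs, halves/doubles the state variances and raises the
    chain persistence, with a crisper baseline (emission SD 0.05 against
    0.4 state spacing) and a 30 s duration floor so each series supports
    a stable four-state fit.  Under these truths the per-subject feature
    noise is small relative to the group contrast, so a correct pipeline
    should classify trial 12 almost perfectly and trial 1 at chance.
    """
    base = GaussianHMMParams(
        means=[0.6, 1.0, 1.4, 1.8],
        variances=[0.0025] * 4,
        transition=_persistent_transition(4, 0.85),
        initial=[0.25] * 4,
    )
    learner12 = GaussianHMMParams(
        means=[0.3, 0.7, 1.7, 2.1],
        variances=[0.00125, 0.0025, 0.005, 0.01],
        transition=_persistent_transition(4, 0.95),
        initial=[0.25] * 4,
    )
    truth = {
        ("learner", 1): base,
        ("non_learner", 1): base,
        ("non_learner", 12): base,
        ("learner", 12): learner12,
    }
    return CohortSpec(seed=seed, hmm_truth=truth, min_trial_duration=30.0)


def _persistent_transition(M: int, diag: float) -> np.ndarray:
    P = np.full((M, M), (1.0 - diag) / (M - 1))
    np.fill_diagonal(P, diag)
    return P


@dataclass
class CohortSpec:
    """Design of a simulated cohort.

    Defaults mirror the study layout: 25 subjects per group, trials 1
    and 12, a 60 s trial cap, theta sampled at 4 Hz (the extraction
    methods are sampling-rate agnostic), and a 75 Vm-diameter circular
    arena with the hidden goal at the centre.
    """

    n_per_group: int = 25
    trial_labels: tuple = (1, 12)
    series_duration: float = 60.0
    theta_sampling_rate: float = 4.0
    arena_radius: float = 37.5
    min_trial_duration: float = 12.0
    hmm_truth: dict = field(default_factory=default_hmm_truth)
    trajectory_truth: dict = None  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.theta_sampling_rate <= 0:
            raise ValidationError("theta sampling rate must be positive")
        if self.arena_radius <= 0:
            raise ValidationError("arena radius must be positive")
        if self.trajectory_truth is None:
            self.trajectory_truth = default_trajectory_truth(self.arena_radius)
        for kin in self.trajectory_truth.values():
            if np.hypot(*kin.goal_xy) >= self.arena_radius:
                raise ValidationError("goal must lie inside the arena")


def _substream(seed: int, *key) -> np.random.Generator:
    """Named child stream of the master seed (stable across processes)."""
    parts = tuple(zlib.crc32(repr(k).encode()) for k in key)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=parts))


def simulate_hmm_series(params: GaussianHMMParams, length: int,
                        seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw one series from a Gaussian HMM.

    Returns ``(values, states)``; the hidden path is kept for recovery
    tests.  ``seed`` may be an int or a Generator.
    """
    if length < 1:
        raise ValidationError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    M = params.n_states
    states = np.empty(length, dtype=int)
    states[0] = rng.choice(M, p=params.initial)
    for t in range(1, length):
        states[t] = rng.choice(M, p=params.transition[states[t - 1]])
    values = params.means[states] + rng.normal(
        0.0, np.sqrt(params.variances[states])
    )
    return values, states


def simulate_trajectory(group: str, trial: int, spec: CohortSpec,
                        seed=None, subject_id: str = "sim",
                        duration: float = None) -> TrajectorySeries:
    """Simulate one arena path.

    A correlated random walk: the heading receives Gaussian increments
    each step and, when ``approach_bias > 0``, is rotated toward the
    goal by that fraction of the bearing error.  Walkers start on the
    arena rim (fixed start position, as in the task), keep inside the
    arena by turning back at the wall, and either stop on entering the
    goal (biased walkers) or walk for the full ``duration`` (default:
    the 60 s cap).
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    kin = spec.trajectory_truth[(group, trial)]
    if duration is None:
        duration = spec.series_duration
    n_steps = int(round(duration / TRAJECTORY_DT))
    R = spec.arena_radius
    gx, gy = kin.goal_xy
    # fixed start on the southern rim, shared by every subject
    x, y = 0.0, -0.9 * R
    heading = rng.uniform(-np.pi, np.pi)
    xs, ys = [x], [y]
    step = kin.speed * TRAJECTORY_DT
    for _ in range(n_steps):
        if rng.uniform() < kin.idle_prob:
            xs.append(x); ys.append(y)
            continue
        heading += rng.normal(0.0, kin.heading_noise_sd)
        if kin.approach_bias > 0:
            bearing = np.arctan2(gy - y, gx - x)
            err = np.angle(np.exp(1j * (bearing - heading)))
            heading += kin.approach_bias * err
        nx = x + step * np.cos(heading)
        ny = y + step * np.sin(heading)
        if np.hypot(nx, ny) > R:  # turn back toward the centre at the wall
            heading = np.arctan2(-y, -x) + rng.normal(0.0, 0.3)
            nx = x + step * np.cos(heading)
            ny = y + step * np.sin(heading)
            if np.hypot(nx, ny) > R:
                nx, ny = x, y
        x, y = nx, ny
        xs.append(x); ys.append(y)
        if kin.approach_bias > 0 and np.hypot(x - gx, y - gy) <= kin.goal_radius:
            break
    times = np.arange(len(xs)) * TRAJECTORY_DT
    return TrajectorySeries(
        subject_id=subject_id, group=group, trial=trial,
        times=times, xs=np.array(xs), ys=np.array(ys),
        total_time=float(times[-1]),
    )


def simulate_cohort(spec: CohortSpec):
    """Simulate the full two-group, two-trial cohort.

    Returns ``(theta_list, trajectory_list, truth)`` where ``truth``
    maps ``(subject_id, trial)`` to a dict holding the generating HMM
    parameters, the hidden state path and the trial duration.
    Deterministic given ``spec.seed``.
    """
    theta_list, traj_list = [], []
    truth: dict = {"spec": spec, "series": {}}
    subject_ids = {
        g: [f"{'L' if g == 'learner' else 'N'}{i + 1:03d}"
            for i in range(spec.n_per_group)]
        for g in GROUPS
    }
    for trial in spec.trial_labels:
        # learners first: their mean duration time-matches the non-learners
        durations: dict[str, float] = {}
        for g in ("learner", "non_learner"):
            if g == "learner":
                dur_arg = [None] * spec.n_per_group
            else:
                learner_durs = [durations[s] for s in subject_ids["learner"]]
                matched = float(np.mean(learner_durs))
                matched = round(matched / TRAJECTORY_DT) * TRAJECTORY_DT
                dur_arg = [matched] * spec.n_per_group
            for sid, dur in zip(subject_ids[g], dur_arg):
                rng_t = _substream(spec.seed, "trajectory", sid, trial)
                traj = simulate_trajectory(
                    g, trial, spec, seed=rng_t, subject_id=sid, duration=dur
                )
                # enforce a floor so theta series stay fittable
                if traj.total_time < spec.min_trial_duration:
                    extra = spec.min_trial_duration - traj.total_time
                    n_extra = int(np.ceil(extra / TRAJECTORY_DT))
                    times = np.arange(len(traj) + n_extra) * TRAJECTORY_DT
                    traj = TrajectorySeries(
                        subject_id=sid, group=g, trial=trial, times=times,
                        xs=np.concatenate([traj.xs,
                                           np.full(n_extra, traj.xs[-1])]),
                        ys=np.concatenate([traj.ys,
                                           np.full(n_extra, traj.ys[-1])]),
                        total_time=float(times[-1]),
                    )
                durations[sid] = traj.total_time
                traj_list.append(traj)

                hmm_params = spec.hmm_truth[(g, trial)]
                n_samples = max(3, int(round(traj.total_time
                                             * spec.theta_sampling_rate)))
                rng_e = _substream(spec.seed, "theta", sid, trial)
                values, states = simulate_hmm_series(
                    hmm_params, n_samples, seed=rng_e
                )
                times = np.arange(n_samples) / spec.theta_sampling_rate
                theta_list.append(ThetaSeries(
                    subject_id=sid, group=g, trial=trial,
                    times=times, values=values,
                ))
                truth["series"][(sid, trial)] = {
                    "group": g,
                    "hmm_params": hmm_params,
                    "states": states,
                    "duration": traj.total_time,
                }
    return theta_list, traj_list, truth


def with_identical_groups(spec: CohortSpec) -> CohortSpec:
    """Copy of ``spec`` whose trial-12 truths equal the trial-1 truths
    (a null cohort with no group signal at all)."""
    hmm_truth = dict(spec.hmm_truth)
    traj_truth = dict(spec.trajectory_truth)
    for g in GROUPS:
        hmm_truth[(g, 12)] = hmm_truth[(g, 1)]
        traj_truth[(g, 12)] = traj_truth[(g, 1)]
    return replace(spec, hmm_truth=hmm_truth, trajectory_truth=traj_truth)
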