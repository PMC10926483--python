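"""Ground-truthed synthetic trackball trajectories and cohorts.

The generator emulates tethered walking under rotational optic flow with a
three-archetype kinematic model of the observed response phenotypes:

* ``FOLLOWER`` — robust, symmetric stimulus-following: high optomotor gain,
  negligible direction-independent turn bias.
* ``BIASED_TURNER`` — fast-walking, highly asymmetric: a strong signed turn
  bias dominates a weak gain, so one stimulus direction is followed and the
  other is not.
* ``SHALLOW_WALKER`` — low-magnitude responses: small gain, shallow bias,
  noise-dominated meandering.

Per frame the yaw rate is ``direction(t - latency) * gain + bias +
Brownian noise`` (Euler integration; noise scaled by sqrt(dt) so feature
statistics are frame-rate invariant); the direction signal follows the
schedule's epochs (0 during inter-stimulus intervals and static gratings)
and latency is a pure delay of that signal.  The forward-rolling component
is chosen so the *total* ball rotation magnitude matches the archetype's
walking pace: pace is the animal's overall substrate speed, of which turning
consumes a share.

Cohorts mix archetypes in treatment-dependent proportions and are written in
the trackball-log dialect, so every upstream stage is testable without any
recorded data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .fictrac import Trajectory, write_trackball_log
from .stimuli import Schedule, build_schedule, default_battery, schedule_to_yaml

__all__ = [
    "Archetype",
    "ArchetypeParams",
    "TreatmentGroup",
    "CohortDesign",
    "CohortResult",
    "DEFAULT_ARCHETYPES",
    "simulate_trajectory",
    "simulate_cohort",
    "default_design",
]


class Archetype(enum.Enum):
    FOLLOWER = "FOLLOWER"
    BIASED_TURNER = "BIASED_TURNER"
    SHALLOW_WALKER = "SHALLOW_WALKER"


@dataclass(frozen=True)
class ArchetypeParams:
    """Generative parameters of one behavioral phenotype.

    optomotor_gain : rad/s of stimulus-following turning.
    reaction_latency : s; pure delay of the direction signal.
    bias_rate : rad/s of direction-independent (signed) turning.
    forward_pace : cm/s; total substrate walking speed.
    rotational_noise_sd : rad/sqrt(s) Brownian yaw noise.
    """

    archetype: Archetype
    optomotor_gain: float
    reaction_latency: float
    bias_rate: float
    forward_pace: float
    rotational_noise_sd: float

    def __post_init__(self) -> None:
        if self.reaction_latency < 0:
            raise ValueError("reaction_latency must be >= 0")
        if self.forward_pace < 0:
            raise ValueError("forward_pace must be >= 0")
        if self.rotational_noise_sd < 0:
            raise ValueError("rotational_noise_sd must be >= 0")


# Free synthetic choices, set so the three phenotypes are separable at the
# feature level (gain/bias in rad/s, latency s, pace cm/s, noise rad/sqrt(s)).
DEFAULT_ARCHETYPES: dict[Archetype, ArchetypeParams] = {
    Archetype.FOLLOWER: ArchetypeParams(Archetype.FOLLOWER, 0.50, 0.30, 0.02, 2.0, 0.10),
    Archetype.BIASED_TURNER: ArchetypeParams(Archetype.BIASED_TURNER, 0.10, 0.60, 0.70, 3.2, 0.15),
    Archetype.SHALLOW_WALKER: ArchetypeParams(Archetype.SHALLOW_WALKER, 0.06, 0.80, 0.06, 1.2, 0.18),
}


def _direction_signal(schedule: Schedule, t: np.ndarray, t0: float) -> np.ndarray:
    sig = np.zeros_like(t)
    for spec, epoch in schedule.iter_epochs():
        if spec.static:
            continue
        mask = (t >= t0 + epoch.onset) & (t < t0 + epoch.offset)
        sig[mask] = epoch.direction.sign
    return sig


def simulate_trajectory(
    params: ArchetypeParams,
    schedule: Schedule,
    frame_rate: float = 50.0,
    ball_diameter: float = 5.0,
    seed: int | np.random.SeedSequence = 0,
    t0: float = 2.0,
    tail: float = 2.0,
) -> Trajectory:
    """Simulate one animal's session as a trackball trajectory.

    The session runs from time 0 to ``t0 + schedule.duration + tail``.
    The output satisfies all trajectory invariants and round-trips through
    the trackball-log reader/writer.
    """
    if not frame_rate > 0:
        raise ValueError("frame_rate must be > 0")
    dt = 1.0 / frame_rate
    n = int(np.ceil((t0 + schedule.duration + tail) * frame_rate)) + 1
    t = np.arange(n) * dt
    rng = np.random.default_rng(seed)

    sig = _direction_signal(schedule, t - params.reaction_latency, t0)
    yaw_rate = sig * params.optomotor_gain + params.bias_rate
    dheading = yaw_rate * dt + rng.normal(0.0, params.rotational_noise_sd * np.sqrt(dt), size=n)
    dheading[0] = 0.0
    heading = np.cumsum(dheading)

    radius = ball_diameter / 2.0
    budget = params.forward_pace / radius  # total rotation rate, rad/s
    inst_yaw = dheading / dt
    forward_rate = np.sqrt(np.maximum(budget**2 - inst_yaw**2, 0.0))
    increments = np.column_stack([forward_rate * dt, np.zeros(n), dheading])
    speed = np.linalg.norm(increments, axis=1)

    return Trajectory(
        frame_index=np.arange(n),
        time=t,
        integrated_heading=heading,
        rotation_increment=increments,
        movement_speed=speed,
        ball_diameter=ball_diameter,
        frame_rate=frame_rate,
    )


@dataclass(frozen=True)
class TreatmentGroup:
    name: str
    n_animals: int
    mixture: dict[Archetype, float]  # archetype probabilities, sum to 1

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture for {self.name} sums to {total}, not 1")


@dataclass(frozen=True)
class CohortDesign:
    treatments: tuple[TreatmentGroup, ...]
    schedule: Schedule
    frame_rate: float = 50.0
    ball_diameter: float = 5.0
    t0: float = 2.0
    seed: int = 0
    parameter_jitter: float = 0.10  # lognormal sd of animal-level variation

    @property
    def n_animals(self) -> int:
        return sum(g.n_animals for g in self.treatments)


@dataclass
class CohortResult:
    design: CohortDesign
    trajectories: dict[str, Trajectory]
    metadata: pd.DataFrame  # animal_id, treatment, t0 (+ file path when written)
    labels: pd.DataFrame  # animal_id, archetype (+ generative parameters)


def _sample_params(base: ArchetypeParams, rng: np.random.Generator, jitter: float) -> ArchetypeParams:
    """Animal-level variation: multiplicative lognormal jitter on magnitudes;
    the turn-bias sign is random per animal (left- and right-biased animals
    are equally likely)."""

    def lj(x: float, s: float) -> float:
        return float(x * rng.lognormal(0.0, s)) if x > 0 else float(x)

    sign = rng.choice([-1.0, 1.0])
    return replace(
        base,
        optomotor_gain=lj(base.optomotor_gain, jitter),
        reaction_latency=lj(base.reaction_latency, jitter),
        bias_rate=sign * lj(abs(base.bias_rate), 1.5 * jitter),
        forward_pace=lj(base.forward_pace, jitter),
    )


def simulate_cohort(
    design: CohortDesign,
    out_dir: str | Path | None = None,
    archetypes: dict[Archetype, ArchetypeParams] = DEFAULT_ARCHETYPES,
) -> CohortResult:
    """Simulate every animal of a cohort design, fully seeded.

    With ``out_dir`` set, writes one trackball-log file per animal plus
    ``metadata.csv`` (animal_id, treatment, t0, file), the ground-truth
    ``labels.csv`` (kept separate so recovery tests cannot leak it into the
    pipeline inputs), and ``schedule.yaml``.  The same design and seed give
    byte-identical files.
    """
    root = np.random.SeedSequence(design.seed)
    trajectories: dict[str, Trajectory] = {}
    meta_rows, label_rows = [], []
    animal_seeds = iter(root.spawn(design.n_animals))
    for group in design.treatments:
        arch_names = sorted(group.mixture, key=lambda a: a.value)
        probs = np.array([group.mixture[a] for a in arch_names])
        for i in range(group.n_animals):
            ss = next(animal_seeds)
            rng = np.random.default_rng(ss)
            archetype = arch_names[int(rng.choice(len(arch_names), p=probs))]
            params = _sample_params(archetypes[archetype], rng, design.parameter_jitter)
            animal_id = f"{group.name}_{i:02d}"
            trajectories[animal_id] = simulate_trajectory(
                params,
                design.schedule,
                frame_rate=design.frame_rate,
                ball_diameter=design.ball_diameter,
                seed=rng,
                t0=design.t0,
            )
            meta_rows.append({"animal_id": animal_id, "treatment": group.name, "t0": design.t0})
            label_rows.append(
                {
                    "animal_id": animal_id,
                    "treatment": group.name,
                    "archetype": archetype.value,
                    "optomotor_gain": params.optomotor_gain,
                    "reaction_latency": params.reaction_latency,
                    "bias_rate": params.bias_rate,
                    "forward_pace": params.forward_pace,
                    "rotational_noise_sd": params.rotational_noise_sd,
                }
            )
    metadata = pd.DataFrame(meta_rows)
    labels = pd.DataFrame(label_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for animal_id, traj in trajectories.items():
            path = out_dir / f"{animal_id}.dat"
            write_trackball_log(traj, path)
            paths.append(path.name)
        metadata = metadata.assign(file=paths)
        metadata.to_csv(out_dir / "metadata.csv", index=False)
        labels.to_csv(out_dir / "labels.csv", index=False)
        (out_dir / "schedule.yaml").write_text(schedule_to_yaml(design.schedule))
    return CohortResult(design=design, trajectories=trajectories, metadata=metadata, labels=labels)


def default_design(seed: int = 0, isi: float = 180.0) -> CohortDesign:
    """The default study-like cohort: 4 treatment groups of 6 animals on the
    12-grating battery (10 s epochs x 4 repeats), 288 responses in total.

    The control group is dominated by the FOLLOWER phenotype while the three
    exposure groups carry elevated BIASED_TURNER / SHALLOW_WALKER fractions
    across stimuli.  The mixture probabilities are synthetic choices that
    reproduce the qualitative treatment contrast, not measured values.
    """
    schedule = build_schedule(default_battery(), epoch_duration=10.0, repeats=4, isi=isi, order_seed=seed)
    F, T, S = Archetype.FOLLOWER, Archetype.BIASED_TURNER, Archetype.SHALLOW_WALKER
    treatments = (
        TreatmentGroup("CTL", 6, {F: 0.75, T: 0.10, S: 0.15}),
        TreatmentGroup("IMD", 6, {F: 0.35, T: 0.35, S: 0.30}),
        TreatmentGroup("SFX", 6, {F: 0.25, T: 0.40, S: 0.35}),
        TreatmentGroup("MIX", 6, {F: 0.30, T: 0.35, S: 0.35}),
    )
    return CohortDesign(treatments=treatments, schedule=schedule, seed=seed)
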