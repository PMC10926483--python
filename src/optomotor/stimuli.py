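"""Open-loop rotational optic-flow stimulation protocols.

A protocol is a battery of translating sine-wave gratings, each defined by a
spatial frequency (cycles per degree, cpd) and a temporal frequency (Hz).
Within one stimulus the grating translates leftward for a fixed epoch, then
instantly reverses to rightward, alternating for a fixed number of repeats
(the default protocol: 4 x (10 s left + 10 s right) = 80 s of stimulation).
Stimuli are presented in a seeded pseudo-random order separated by an
inter-stimulus interval.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Direction",
    "StimulusSpec",
    "Epoch",
    "Schedule",
    "build_schedule",
    "angular_velocity",
    "default_battery",
    "schedule_to_yaml",
    "schedule_from_yaml",
    "DEFAULT_TEMPORAL_FREQUENCIES_HZ",
    "DEFAULT_SPATIAL_FREQUENCIES_CPD",
]


class Direction(enum.Enum):
    """Grating translation direction; LEFT carries positive rotation sign."""

    LEFT = 1
    RIGHT = -1

    @property
    def sign(self) -> int:
        return self.value


@dataclass(frozen=True)
class StimulusSpec:
    """A translating vertical sine-wave grating.

    Parameters
    ----------
    spatial_frequency : float
        Cycles per degree (cpd); smaller values mean wider bars.
    temporal_frequency : float
        Hz; cycles passing a fixed point per second. Must be positive
        unless ``static`` is set, in which case it must be 0 (a stationary
        grating used as a no-optic-flow control).
    label : str
        Free-text identifier; auto-generated when empty.
    static : bool
        Marks the stationary-grating control condition.
    """

    spatial_frequency: float
    temporal_frequency: float
    label: str = ""
    static: bool = False

    def __post_init__(self) -> None:
        if not self.spatial_frequency > 0:
            raise ValueError(f"spatial_frequency must be > 0, got {self.spatial_frequency}")
        if self.static:
            if self.temporal_frequency != 0:
                raise ValueError("static stimulus must have temporal_frequency == 0")
        elif not self.temporal_frequency > 0:
            raise ValueError(f"temporal_frequency must be > 0, got {self.temporal_frequency}")
        if not self.label:
            tag = "static" if self.static else f"{self.temporal_frequency:g}Hz"
            object.__setattr__(self, "label", f"{tag}_{self.spatial_frequency:g}cpd")


def angular_velocity(spec: StimulusSpec) -> float:
    """Grating angular velocity in deg/s: temporal / spatial frequency."""
    return spec.temporal_frequency / spec.spatial_frequency


@dataclass(frozen=True)
class Epoch:
    """One constant-direction stimulation interval."""

    direction: Direction
    onset: float  # s from schedule start
    duration: float  # s

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Schedule:
    """Ordered stimulus battery with direction-alternating epochs."""

    stimuli: tuple[tuple[StimulusSpec, tuple[Epoch, ...]], ...]
    inter_stimulus_interval: float
    epoch_duration: float
    repeats: int
    order_seed: int

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    @property
    def epochs_per_stimulus(self) -> int:
        return 2 * self.repeats

    @property
    def stimulation_time_per_stimulus(self) -> float:
        """Total stimulated time per stimulus (s) = 2 * repeats * epoch_duration."""
        return self.epochs_per_stimulus * self.epoch_duration

    @property
    def duration(self) -> float:
        """Time from schedule start to the end of the last epoch (s)."""
        if not self.stimuli:
            return 0.0
        return self.stimuli[-1][1][-1].offset

    def iter_epochs(self):
        for spec, epochs in self.stimuli:
            for epoch in epochs:
                yield spec, epoch


def build_schedule(
    specs: list[StimulusSpec],
    epoch_duration: float = 10.0,
    repeats: int = 4,
    isi: float = 180.0,
    order_seed: int = 0,
) -> Schedule:
    """Assemble a schedule: seeded pseudo-random stimulus order, alternating
    LEFT-first epochs, consecutive stimuli separated by ``isi`` seconds.

    Raises
    ------
    ValueError
        On an empty spec list or non-positive epoch duration / repeats.
    """
    if not specs:
        raise ValueError("cannot build a schedule from an empty stimulus list")
    if repeats < 1:
        raise ValueError(f"repeats must be >= 1, got {repeats}")
    if not epoch_duration > 0:
        raise ValueError(f"epoch_duration must be > 0, got {epoch_duration}")

    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(specs))

    stimuli: list[tuple[StimulusSpec, tuple[Epoch, ...]]] = []
    t = 0.0
    for i in order:
        epochs = []
        for j in range(2 * repeats):
            direction = Direction.LEFT if j % 2 == 0 else Direction.RIGHT
            epochs.append(Epoch(direction, onset=t, duration=epoch_duration))
            t += epoch_duration
        stimuli.append((specs[i], tuple(epochs)))
        t += isi
    return Schedule(
        stimuli=tuple(stimuli),
        inter_stimulus_interval=isi,
        epoch_duration=epoch_duration,
        repeats=repeats,
        order_seed=order_seed,
    )


# Default battery spanning the tested ranges: temporal frequencies 4-48 Hz at
# a constant 0.0625 cpd, and spatial frequencies 0.5-0.0039 cpd at a constant
# 16 Hz (12 gratings total).  Configurable: pass any spec list to
# build_schedule.
DEFAULT_TEMPORAL_FREQUENCIES_HZ = (4.0, 8.0, 16.0, 24.0, 32.0, 40.0, 48.0)
DEFAULT_SPATIAL_FREQUENCIES_CPD = (0.5, 0.25, 0.125, 0.0313, 0.0039)


def default_battery(
    temporal_frequencies: tuple[float, ...] = DEFAULT_TEMPORAL_FREQUENCIES_HZ,
    spatial_frequencies: tuple[float, ...] = DEFAULT_SPATIAL_FREQUENCIES_CPD,
    fixed_spatial: float = 0.0625,
    fixed_temporal: float = 16.0,
) -> list[StimulusSpec]:
    """The 12-grating default battery: a temporal-frequency sweep at a fixed
    spatial frequency plus a spatial-frequency sweep at a fixed temporal
    frequency."""
    specs = [StimulusSpec(fixed_spatial, tf) for tf in temporal_frequencies]
    specs += [StimulusSpec(sf, fixed_temporal) for sf in spatial_frequencies]
    return specs


def schedule_to_yaml(schedule: Schedule) -> str:
    """Serialize a Schedule to a plain-text YAML document."""
    doc = {
        "epoch_duration": schedule.epoch_duration,
        "repeats": schedule.repeats,
        "inter_stimulus_interval": schedule.inter_stimulus_interval,
        "order_seed": schedule.order_seed,
        "stimuli": [
            {
                "label": spec.label,
                "spatial_frequency": spec.spatial_frequency,
                "temporal_frequency": spec.temporal_frequency,
                "static": spec.static,
                "onset": epochs[0].onset,
            }
            for spec, epochs in schedule.stimuli
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def schedule_from_yaml(text: str) -> Schedule:
    """Inverse of :func:`schedule_to_yaml`."""
    doc = yaml.safe_load(text)
    epoch_duration = float(doc["epoch_duration"])
    repeats = int(doc["repeats"])
    stimuli = []
    for item in doc["stimuli"]:
        spec = StimulusSpec(
            spatial_frequency=float(item["spatial_frequency"]),
            temporal_frequency=float(item["temporal_frequency"]),
            label=item.get("label", ""),
            static=bool(item.get("static", False)),
        )
        t = float(item["onset"])
        epochs = []
        for j in range(2 * repeats):
            direction = Direction.LEFT if j % 2 == 0 else Direction.RIGHT
            epochs.append(Epoch(direction, onset=t, duration=epoch_duration))
            t += epoch_duration
        stimuli.append((spec, tuple(epochs)))
    return Schedule(
        stimuli=tuple(stimuli),
        inter_stimulus_interval=float(doc["inter_stimulus_interval"]),
        epoch_duration=epoch_duration,
        repeats=repeats,
        order_seed=int(doc["order_seed"]),
    )
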