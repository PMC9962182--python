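"""Synthetic multi-IMU fall / ADL signal generator.

Emulates the structure of a five-sensor body network (left ankle, right
trouser pocket, waist, neck, left wrist) recording 3-axis acceleration (g)
and angular velocity (deg/s) at ~18 Hz, for eleven activities: five fall
types performed once within a 10 s trial, and six activities of daily
living with their conventional recording durations (walking / standing /
sitting / lying 60 s, jumping 30 s, picking up an object 10 s).

Falls follow the classic three-phase signature: an upright (or seated, for
the chair fall) lead-in, a free-fall phase where acceleration magnitude
drops well below 1 g, a short impact spike of several g — strongest at the
sensor nearest the impact side — and a rest phase with the gravity vector
reoriented to a fall-type-specific lying attitude, accompanied by a
rotation burst on the gyroscope. ADLs are periodic (walking, jumping),
static (standing, lying), or single-transition (sitting, picking up an
object) recipes.

The recipes are stylized, not biomechanically validated: they reproduce the
statistical structure a window classifier exploits (phase events,
orientation changes, periodicity, per-node amplitude gradients), with
per-subject amplitude/frequency jitter and configurable sensor noise. A
fixed seed reproduces the full dataset byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .windowing import SensorSequence

__all__ = [
    "ACTIVITIES",
    "FALL_IDS",
    "ADL_IDS",
    "SyntheticConfig",
    "generate_fall",
    "generate_adl",
    "generate_trial",
    "generate_dataset",
]

#: activity id -> (name, category, duration in seconds)
ACTIVITIES = {
    1: ("falling_forward_hands", "fall", 10.0),
    2: ("falling_forward_knees", "fall", 10.0),
    3: ("falling_backwards", "fall", 10.0),
    4: ("falling_sideways", "fall", 10.0),
    5: ("falling_from_chair", "fall", 10.0),
    6: ("walking", "adl", 60.0),
    7: ("standing", "adl", 60.0),
    8: ("sitting", "adl", 60.0),
    9: ("picking_up_object", "adl", 10.0),
    10: ("jumping", "adl", 30.0),
    11: ("lying", "adl", 60.0),
}
FALL_IDS = tuple(i for i, v in ACTIVITIES.items() if v[1] == "fall")
ADL_IDS = tuple(i for i, v in ACTIVITIES.items() if v[1] == "adl")

# node order: ankle, pocket/thigh, waist, neck, wrist
_N_NODES = 5

_STANDING = np.tile([0.0, 0.0, 1.0], (_N_NODES, 1))
_SITTING = np.array(
    [
        [0.0, 0.0, 1.0],  # ankle stays vertical
        [0.90, 0.0, 0.44],  # thigh near horizontal
        [0.17, 0.0, 0.985],  # slight trunk recline
        [0.17, 0.0, 0.985],
        [0.0, 0.0, 1.0],
    ]
)
_LYING = np.tile([0.0, -1.0, 0.0], (_N_NODES, 1))

# per fall type: final lying attitude, impact direction, per-node impact
# emphasis (1 at the sensor nearest the impact side), gyro rotation axis
_FALL_FINAL = {
    1: np.array([1.0, 0.0, 0.0]),
    2: np.array([0.8, 0.0, 0.6]),
    3: np.array([-1.0, 0.0, 0.0]),
    4: np.array([0.0, 1.0, 0.0]),
    5: np.array([-0.70, 0.0, 0.71]),
}
_FALL_IMPACT_DIR = {
    1: np.array([1.0, 0.0, 0.0]),
    2: np.array([0.95, 0.0, 0.31]),
    3: np.array([-1.0, 0.0, 0.0]),
    4: np.array([0.0, 1.0, 0.0]),
    5: np.array([-0.70, 0.0, 0.70]),
}
_FALL_IMPACT_WEIGHT = {
    1: np.array([0.4, 0.5, 0.6, 0.5, 1.0]),  # hands -> wrist
    2: np.array([1.0, 0.9, 0.5, 0.4, 0.4]),  # knees -> ankle/thigh
    3: np.array([0.4, 0.5, 0.9, 1.0, 0.4]),  # back -> waist/neck
    4: np.array([0.5, 0.6, 1.0, 0.7, 0.6]),  # side -> waist
    5: np.array([0.5, 1.0, 0.9, 0.5, 0.4]),  # chair -> thigh/waist
}
_FALL_GYRO_AXIS = {
    1: np.array([0.0, 1.0, 0.0]),
    2: np.array([0.0, 1.0, 0.0]),
    3: np.array([0.0, -1.0, 0.0]),
    4: np.array([1.0, 0.0, 0.0]),
    5: np.array([0.0, -1.0, 0.0]),
}

# walking oscillation amplitude gradient: extremities move most
_WALK_ACC_AMP = np.array([0.60, 0.40, 0.15, 0.10, 0.30])  # g
_WALK_GYRO_AMP = np.array([120.0, 80.0, 30.0, 20.0, 60.0])  # deg/s
_WALK_PHASE = np.array([0.0, np.pi, 0.3, 0.3, np.pi / 2])
_JUMP_WEIGHT = np.array([1.0, 0.85, 0.70, 0.60, 0.65])


@dataclass(frozen=True)
class SyntheticConfig:
    """Dataset layout and noise/separability knobs.

    Defaults emulate the canonical collection protocol: 17 subjects, three
    trials of each of the 11 activities, ~18 Hz sampling. ``noise_sd_accel``
    is white accelerometer noise in g, ``noise_sd_gyro`` in deg/s;
    ``separability`` scales all class-distinctive signal components (1.0 =
    nominal, 0 collapses everything onto an upright static posture);
    ``subject_jitter`` is the half-width of the per-subject uniform
    amplitude/frequency scaling.
    """

    subjects: int = 17
    trials: int = 3
    rate_hz: float = 18.0
    noise_sd_accel: float = 0.05
    noise_sd_gyro: float = 5.0
    separability: float = 1.0
    subject_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.subjects, self.trials) < 1 or self.rate_hz <= 0:
            raise ValueError("subjects, trials and rate_hz must be positive")
        if self.noise_sd_accel < 0 or self.noise_sd_gyro < 0:
            raise ValueError("noise levels must be non-negative")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / np.where(n > 0, n, 1.0)


def _trial_rng(cfg: SyntheticConfig, subject: int, activity: int, trial: int):
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, subject, activity, trial])
    )


def _subject_jitter(cfg: SyntheticConfig, subject: int) -> tuple[float, float]:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 10_000 + subject]))
    j = cfg.subject_jitter
    return float(rng.uniform(1 - j, 1 + j)), float(rng.uniform(1 - j, 1 + j))


def _finish(accel, gyro, activity_id, cfg, rng, meta):
    accel = accel + rng.normal(0.0, cfg.noise_sd_accel, accel.shape)
    gyro = gyro + rng.normal(0.0, cfg.noise_sd_gyro, gyro.shape)
    values = np.concatenate([accel, gyro], axis=2).astype(np.float32)
    labels = np.full(values.shape[0], activity_id, dtype=np.int64)
    return SensorSequence(values, labels, rate_hz=cfg.rate_hz, trial_meta=meta)


def generate_fall(
    activity_id: int,
    cfg: SyntheticConfig,
    rng=None,
    jitter: tuple[float, float] = (1.0, 1.0),
    meta: dict | None = None,
) -> SensorSequence:
    """One 10 s fall trial with free-fall, impact and rest phases."""
    if activity_id not in FALL_IDS:
        raise ValueError(f"{activity_id} is not a fall activity id {FALL_IDS}")
    if rng is None:
        rng = _trial_rng(cfg, 0, activity_id, 0)
    amp_j, _ = jitter
    sep = cfg.separability
    rate = cfg.rate_hz
    frames = max(1, round(ACTIVITIES[activity_id][2] * rate))
    t = np.arange(frames) / rate

    pre_posture = _SITTING if activity_id == 5 else _STANDING
    final_dir = _unit(
        (1.0 - min(sep, 1.0)) * pre_posture
        + min(sep, 1.0) * _FALL_FINAL[activity_id][None, :]
    )

    i_fall = int(round(rng.uniform(1.5, 2.5) * rate))  # fall onset
    n_ff = max(2, int(round(0.4 * rate)))  # free-fall frames
    i_imp = i_fall + n_ff
    spike_shape = np.array([0.5, 1.0, 0.6, 0.3])
    n_settle = max(2, int(round(0.5 * rate)))
    i_rest = min(frames, i_imp + len(spike_shape) + n_settle)

    # gravity direction per frame: pre posture -> final attitude
    direction = np.repeat(pre_posture[None, :, :], frames, axis=0)
    direction[i_imp:] = final_dir[None, :, :]
    settle_span = slice(i_imp, i_rest)
    w = np.linspace(0.0, 1.0, i_rest - i_imp)[:, None, None]
    direction[settle_span] = _unit(
        (1 - w) * pre_posture[None, :, :] + w * final_dir[None, :, :]
    )

    # magnitude envelope: 1 g, dropping toward ~0.15 g in free fall,
    # recovering to 1 g once the body is at rest
    mag = np.ones(frames)
    mag[i_fall:i_imp] = np.linspace(1.0, 0.15, n_ff)
    mag[settle_span] = np.linspace(0.3, 1.0, i_rest - i_imp)

    accel = direction * mag[:, None, None]
    # loss-of-balance sway in the lead-in: noticeably larger and faster than
    # quiet standing, as postural control degrades before the fall
    pre = t[:i_fall]
    accel[:i_fall, :, 0] += (0.10 * sep * np.sin(2 * np.pi * 0.6 * pre))[:, None]
    accel[:i_fall, :, 1] += (0.06 * sep * np.sin(2 * np.pi * 0.45 * pre + 1.0))[:, None]
    # impact spike, node-weighted, several g
    peak = rng.uniform(3.2, 6.0) * amp_j * sep
    weights = _FALL_IMPACT_WEIGHT[activity_id]
    imp_dir = _FALL_IMPACT_DIR[activity_id]
    for k, s in enumerate(spike_shape):
        f = i_imp + k
        if f < frames:
            accel[f] += s * peak * weights[:, None] * imp_dir[None, :]
    # post-impact tremor dying out
    tremor = 0.03 * np.exp(-(t[i_rest:] - t[min(i_rest, frames - 1)]) / 1.5)
    accel[i_rest:, :, 2] += tremor[:, None] * np.sin(2 * np.pi * 1.1 * t[i_rest:])[:, None]

    # rotation burst spanning fall + impact + settle, with a pre-fall wobble
    gyro = np.zeros((frames, _N_NODES, 3))
    gyro[:i_fall, :, 1] += (20.0 * sep * np.sin(2 * np.pi * 0.6 * pre))[:, None]
    burst = slice(i_fall, i_rest)
    phase = np.linspace(0.0, np.pi, i_rest - i_fall)
    gpeak = rng.uniform(180.0, 300.0) * amp_j * sep
    gyro[burst] += (
        np.sin(phase)[:, None, None]
        * gpeak
        * weights[None, :, None]
        * _FALL_GYRO_AXIS[activity_id][None, None, :]
    )
    return _finish(accel, gyro, activity_id, cfg, rng, meta or {"activity": activity_id})


def generate_adl(
    activity_id: int,
    cfg: SyntheticConfig,
    rng=None,
    jitter: tuple[float, float] = (1.0, 1.0),
    meta: dict | None = None,
) -> SensorSequence:
    """One ADL trial (walking, standing, sitting, picking up, jumping, lying)."""
    if activity_id not in ADL_IDS:
        raise ValueError(f"{activity_id} is not an ADL id {ADL_IDS}")
    if rng is None:
        rng = _trial_rng(cfg, 0, activity_id, 0)
    amp_j, freq_j = jitter
    sep = cfg.separability
    rate = cfg.rate_hz
    frames = max(1, round(ACTIVITIES[activity_id][2] * rate))
    t = np.arange(frames) / rate

    accel = np.repeat(_STANDING[None, :, :], frames, axis=0).astype(np.float64)
    gyro = np.zeros((frames, _N_NODES, 3))

    if activity_id == 6:  # walking: limb-phased oscillation, extremities largest
        f = 1.8 * freq_j
        osc = np.sin(2 * np.pi * f * t[:, None] + _WALK_PHASE[None, :])
        accel[:, :, 0] += sep * amp_j * _WALK_ACC_AMP[None, :] * osc
        accel[:, :, 2] += 0.4 * sep * amp_j * _WALK_ACC_AMP[None, :] * np.sin(
            4 * np.pi * f * t[:, None] + _WALK_PHASE[None, :]
        )
        gyro[:, :, 1] += sep * amp_j * _WALK_GYRO_AMP[None, :] * osc
    elif activity_id == 7:  # standing: static upright + slow sway
        accel[:, :, 0] += 0.02 * np.sin(2 * np.pi * 0.3 * t)[:, None]
    elif activity_id == 8:  # sitting: one smooth posture transition, then static
        t_s = rng.uniform(3.0, 6.0)
        ramp = np.clip((t - t_s) / 1.0, 0.0, 1.0)
        ramp = 0.5 - 0.5 * np.cos(np.pi * ramp)  # cosine ease
        target = _unit((1 - min(sep, 1.0)) * _STANDING + min(sep, 1.0) * _SITTING)
        accel = _unit(
            (1 - ramp)[:, None, None] * _STANDING[None, :, :]
            + ramp[:, None, None] * target[None, :, :]
        )
        dramp = np.gradient(ramp) * rate
        gyro[:, 1:4, 1] += 45.0 * sep * dramp[:, None]
    elif activity_id == 9:  # picking up an object: one slow bend-hold-return
        tc = rng.uniform(3.5, 4.5)  # instant the object is reached

        def _cos_ramp(u):  # 0 -> 1 raised cosine on clipped argument
            return 0.5 - 0.5 * np.cos(np.pi * np.clip(u, 0.0, 1.0))

        bump = _cos_ramp((t - (tc - 2.5)) / 2.5) * _cos_ramp(((tc + 3.5) - t) / 2.5)
        pick = _unit(np.array([0.94, 0.0, 0.34]))
        for node in (1, 2, 3):  # thigh + trunk pitch forward
            mix = sep * 0.9 * bump[:, None]
            accel[:, node, :] = _unit(
                (1 - mix) * accel[:, node, :] + mix * pick[None, :]
            )
        accel[:, 4, 2] -= 0.35 * sep * bump  # wrist reaches down
        dbump = np.gradient(bump) * rate
        gyro[:, 1:4, 1] += 90.0 * sep * dbump[:, None]
    elif activity_id == 10:  # jumping: periodic flight dips + landing spikes
        f = 1.0 * freq_j
        s = np.sin(2 * np.pi * f * t)
        spike = np.maximum(s, 0.0) ** 3
        flight = np.maximum(-s, 0.0) ** 1.5
        profile = 1.8 * spike - 0.8 * flight
        accel[:, :, 2] += sep * amp_j * _JUMP_WEIGHT[None, :] * profile[:, None]
        gyro[:, :, 1] += 30.0 * sep * amp_j * _JUMP_WEIGHT[None, :] * s[:, None]
    elif activity_id == 11:  # lying: gravity rotated to horizontal, static
        target = _unit((1 - min(sep, 1.0)) * _STANDING + min(sep, 1.0) * _LYING)
        accel = np.repeat(target[None, :, :], frames, axis=0)
    return _finish(accel, gyro, activity_id, cfg, rng, meta or {"activity": activity_id})


def generate_trial(
    activity_id: int,
    cfg: SyntheticConfig,
    rng=None,
    jitter: tuple[float, float] = (1.0, 1.0),
    meta: dict | None = None,
) -> SensorSequence:
    if activity_id in FALL_IDS:
        return generate_fall(activity_id, cfg, rng, jitter, meta)
    return generate_adl(activity_id, cfg, rng, jitter, meta)


def generate_dataset(cfg: SyntheticConfig) -> list[SensorSequence]:
    """subjects x 11 activities x trials labelled sequences, seed-deterministic.

    Each trial gets an independent random stream keyed on (seed, subject,
    activity, trial), and each subject a fixed amplitude/frequency jitter, so
    any subset of the dataset can be regenerated without the rest.
    """
    out = []
    for subject in range(1, cfg.subjects + 1):
        jitter = _subject_jitter(cfg, subject)
        for activity in sorted(ACTIVITIES):
            for trial in range(1, cfg.trials + 1):
                rng = _trial_rng(cfg, subject, activity, trial)
                meta = {"subject": subject, "activity": activity, "trial": trial}
                out.append(generate_trial(activity, cfg, rng, jitter, meta))
    return out
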