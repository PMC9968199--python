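"""Synthetic parkinsonian gait cohorts for testing the scoring pipeline.

The clinical motion-capture data this pipeline targets are not publicly
distributable, so this module generates labeled timed-up-and-go-like
marker trajectories whose phenotype motifs follow the clinical
descriptions of freezing of gait severity:

* score 0 — normal stepping: periodic heel lifts at the step frequency;
* score 1 — reduced step length: smaller, shorter heel lifts;
* score 2 — festination: step rate speeding up while amplitude decays;
* scores 3-4 — freezing/akinesia: intervals where the heel stays at the
  floor apart from band-limited trembling in the classical 3-8 Hz
  "freeze band", covering a growing fraction of the trial.

Levodopa ON state scales amplitudes and cadence up and freeze fraction
down.  Arm swing shrinks, and a 4-6 Hz hand tremor grows, with overall
motor severity (MDS-UPDRS-III minus the FOG item), so the regression
task is learnable.  The left body side expresses the phenotype slightly
more strongly than the right, mimicking the left-turn test asymmetry.

Cohort label marginals are shaped like the study tables: session counts
per (medication state x FOG score) and group-wise MDS-UPDRS-III means
and SDs are configurable, defaulting to the published cohort values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .data_model import LabelSet, MarkerSequence, SkeletonGraph

# ---------------------------------------------------------------------- #
# default skeleton: 21-marker reduced clinical gait set
# ---------------------------------------------------------------------- #
_MARKERS = [
    "HEAD", "CHEST", "PELVIS",
    "LSHO", "LELB", "LWRI", "LHAN",
    "RSHO", "RELB", "RWRI", "RHAN",
    "LHIP", "LKNE", "LANK", "LHEEL", "LTOE",
    "RHIP", "RKNE", "RANK", "RHEEL", "RTOE",
]

_EDGES_BY_NAME = [
    ("HEAD", "CHEST"), ("CHEST", "PELVIS"),
    ("CHEST", "LSHO"), ("LSHO", "LELB"), ("LELB", "LWRI"), ("LWRI", "LHAN"),
    ("CHEST", "RSHO"), ("RSHO", "RELB"), ("RELB", "RWRI"), ("RWRI", "RHAN"),
    ("PELVIS", "LHIP"), ("LHIP", "LKNE"), ("LKNE", "LANK"),
    ("LANK", "LHEEL"), ("LANK", "LTOE"),
    ("PELVIS", "RHIP"), ("RHIP", "RKNE"), ("RKNE", "RANK"),
    ("RANK", "RHEEL"), ("RANK", "RTOE"),
]


def default_skeleton() -> SkeletonGraph:
    """21-marker synthetic skeleton with the pelvis as hip-center root."""
    idx = {m: i for i, m in enumerate(_MARKERS)}
    return SkeletonGraph(
        marker_names=list(_MARKERS),
        edges=[(idx[a], idx[b]) for a, b in _EDGES_BY_NAME],
        root="PELVIS",
    )


# resting marker positions (mm) used to give raw CSVs anatomical offsets
_BASE_POS = {
    "HEAD": (0, 0, 1650), "CHEST": (0, 0, 1350), "PELVIS": (0, 0, 950),
    "LSHO": (0, 190, 1420), "LELB": (0, 230, 1150), "LWRI": (0, 250, 900),
    "LHAN": (0, 260, 810),
    "RSHO": (0, -190, 1420), "RELB": (0, -230, 1150), "RWRI": (0, -250, 900),
    "RHAN": (0, -260, 810),
    "LHIP": (0, 110, 920), "LKNE": (0, 120, 500), "LANK": (0, 130, 100),
    "LHEEL": (-60, 130, 40), "LTOE": (120, 130, 40),
    "RHIP": (0, -110, 920), "RKNE": (0, -120, 500), "RANK": (0, -130, 100),
    "RHEEL": (-60, -130, 40), "RTOE": (120, -130, 40),
}


# ---------------------------------------------------------------------- #
# configuration
# ---------------------------------------------------------------------- #
# Published cohort session counts per FOG score, by medication state.
DEFAULT_SESSION_TABLE = {
    "OFF": (21, 15, 9, 8, 7),
    "ON": (38, 11, 7, 3, 1),
}

# Published MDS-UPDRS-III (minus FOG item) means +/- SD per group x state.
DEFAULT_UPDRS_PARAMS = {
    ("PD-FOG", "OFF"): (34.0, 10.6),
    ("PD-FOG", "ON"): (20.7, 8.7),
    ("PD-NoFOG", "OFF"): (30.8, 13.2),
    ("PD-NoFOG", "ON"): (18.4, 14.5),
    ("PP-FOG", "OFF"): (39.4, 7.8),
    ("PP-FOG", "ON"): (31.6, 9.0),
}


@dataclass
class PhenotypeParams:
    """Waveform parameters of the simulated gait motifs."""

    step_frequency: float = 1.8  # Hz, OFF-state cadence of heel lifts
    step_amplitude: float = 120.0  # mm, peak heel lift height
    festination_rate: float = 0.15  # fractional step-rate growth per second
    freeze_fraction_by_score: tuple = (0.0, 0.0, 0.0, 0.5, 0.8)
    tremble_band: tuple = (3.0, 8.0)  # Hz, freeze-band trembling
    tremble_amplitude: float = 6.0  # mm
    arm_swing_amplitude: float = 60.0  # mm at zero motor severity
    tremor_gain: float = 0.5  # mm of 4-6 Hz hand tremor per UPDRS point
    on_amplitude_gain: float = 1.3  # ON-state amplitude scaling
    on_frequency_gain: float = 1.15  # ON-state cadence scaling
    on_freeze_factor: float = 0.6  # ON-state freeze-fraction scaling
    left_gain: float = 1.15  # left-side phenotype expression (left-turn task)

    def __post_init__(self):
        if self.step_amplitude < 0 or self.tremble_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if any(not 0.0 <= f <= 1.0 for f in self.freeze_fraction_by_score):
            raise ValueError("freeze fractions must lie in [0, 1]")


@dataclass
class SyntheticConfig:
    """Study-shaped cohort configuration."""

    skeleton: SkeletonGraph = field(default_factory=default_skeleton)
    fs: float = 120.0
    trial_seconds: float = 10.0
    trials_per_state: int = 3
    session_table: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_SESSION_TABLE.items()}
    )
    updrs_params: dict = field(default_factory=lambda: dict(DEFAULT_UPDRS_PARAMS))
    updrs_fog_shift: float = 2.5  # UPDRS points added per FOG score level
    noise_sd: float = 4.0  # mm, additive marker noise
    difficulty: float = 1.0  # <1 widens phenotype separation, >1 narrows
    phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.difficulty <= 0:
            raise ValueError("difficulty must be > 0")
        for state, counts in self.session_table.items():
            if len(counts) != 5 or any(c < 0 for c in counts):
                raise ValueError(f"bad session counts for state {state}")


# small demonstration cohort: 12 subjects per state with all scores present
DEMO_SESSION_TABLE = {
    "OFF": (3, 3, 2, 2, 2),
    "ON": (4, 3, 2, 2, 1),
}


def demo_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Default scaled-down cohort used in examples and end-to-end checks."""
    kw = dict(session_table={k: tuple(v) for k, v in DEMO_SESSION_TABLE.items()},
              seed=seed)
    kw.update(overrides)
    return SyntheticConfig(**kw)


# ---------------------------------------------------------------------- #
# heel-height motif generator
# ---------------------------------------------------------------------- #
def _bump_train(phase: np.ndarray, duty: float) -> np.ndarray:
    """Unit-amplitude heel-lift train: one raised-sine bump per cycle."""
    p = np.mod(phase, 1.0)
    lift = np.sin(np.pi * p / duty) ** 2
    return np.where(p < duty, lift, 0.0)


def _band_noise(n: int, fs: float, band: tuple, rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise normalized to unit peak amplitude."""
    x = rng.standard_normal(n)
    ny = fs / 2.0
    lo, hi = band[0] / ny, min(band[1] / ny, 0.99)
    b, a = sp_signal.butter(3, [lo, hi], btype="band")
    y = sp_signal.filtfilt(b, a, x)
    peak = np.max(np.abs(y))
    return y / peak if peak > 0 else y


def _freeze_mask(
    n: int, fs: float, freeze_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Alternating walk/freeze episodes covering `freeze_fraction` of the trial.

    Episodes are short (~1.2 s walking bouts) so that every 4 s analysis
    window of a freezing trial contains freezing behaviour.
    """
    if freeze_fraction <= 0:
        return np.zeros(n, dtype=bool)
    walk_len = int(1.2 * fs)
    freeze_len = max(int(walk_len * freeze_fraction / (1.0 - freeze_fraction)), 1)
    mask = np.zeros(n, dtype=bool)
    pos = int(rng.uniform(0.0, 0.4) * walk_len)  # jittered first bout length
    freezing = False
    while pos < n:
        length = freeze_len if freezing else walk_len
        length = max(int(length * rng.uniform(0.85, 1.15)), 1)
        if freezing:
            mask[pos : pos + length] = True
        pos += length
        freezing = not freezing
    # trim or extend to match the requested fraction exactly enough
    excess = mask.sum() - int(round(freeze_fraction * n))
    if excess > 0:
        on = np.flatnonzero(mask)
        mask[on[-excess:]] = False
    elif excess < 0:
        off = np.flatnonzero(~mask)
        mask[off[: -excess]] = True
    return mask


def phenotype_heel_trajectory(
    fog_score: int,
    med_state: str,
    duration_s: float,
    params: PhenotypeParams | None = None,
    seed: int = 0,
    fs: float = 120.0,
    side_gain: float = 1.0,
    phase_offset: float = 0.0,
):
    """Heel height above the floor (mm) for one trial.

    Returns `(trace, envelope, freeze_mask)`: the non-negative height
    trace, the stepping envelope (peak lift height per sample, used to
    advance the pelvis), and the boolean freeze mask.
    """
    if not 0 <= fog_score <= 4:
        raise ValueError(f"fog_score must be in 0..4, got {fog_score}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    params = params or PhenotypeParams()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    freq = params.step_frequency
    amp = params.step_amplitude * side_gain
    duty = 0.45
    if med_state == "ON":
        amp *= params.on_amplitude_gain
        freq *= params.on_frequency_gain
        duty = min(duty * 1.05, 0.9)

    if fog_score == 0:
        phase = freq * t + phase_offset
        env = amp * np.ones(n)
    elif fog_score == 1:
        freq *= 0.95
        amp *= 0.5
        duty *= 0.30 / 0.45
        phase = freq * t + phase_offset
        env = amp * np.ones(n)
    elif fog_score == 2:
        inst = freq * (1.0 + params.festination_rate * t)
        phase = np.cumsum(inst) / fs + phase_offset
        env = amp * (1.0 - 0.6 * t / duration_s)
        duty *= 0.35 / 0.45
    else:  # 3 and 4: partial / predominant freezing
        amp *= 0.45 if fog_score == 3 else 0.30
        duty *= (0.25 if fog_score == 3 else 0.20) / 0.45
        phase = freq * t + phase_offset
        env = amp * np.ones(n)

    ff = params.freeze_fraction_by_score[fog_score]
    if med_state == "ON":
        ff *= params.on_freeze_factor
    mask = _freeze_mask(n, fs, ff, rng)

    trace = env * _bump_train(phase, duty)
    env_eff = np.where(mask, 0.0, env)
    trace = np.where(mask, 0.0, trace)
    if mask.any():
        tremble = _band_noise(n, fs, params.tremble_band, rng)
        tremble = 0.45 * params.tremble_amplitude * (1.0 + tremble)
        trace = np.where(mask, tremble, trace)
    trace = np.maximum(trace, 0.0)
    return trace, env_eff, mask


# ---------------------------------------------------------------------- #
# whole-body trial synthesis
# ---------------------------------------------------------------------- #
def _smooth(x: np.ndarray, fs: float, cutoff_hz: float = 6.0) -> np.ndarray:
    b, a = sp_signal.butter(2, cutoff_hz / (fs / 2.0), btype="low")
    return sp_signal.filtfilt(b, a, x)


def simulate_trial(
    labels: LabelSet,
    cfg: SyntheticConfig,
    seed: int,
    subject_id: str = "S00",
    trial_id: str = "T0",
) -> MarkerSequence:
    """Generate one whole-body TUG-like trial for the given label set.

    Left/right heel traces carry the FOG phenotype (right phase-shifted
    by half a cycle); toe/ankle/knee/hip are smoothed, attenuated
    copies; the pelvis advances at a speed proportional to stepping
    activity, pausing during freezes; arms swing anti-phase with an
    amplitude shrinking as motor severity grows, plus a severity-scaled
    4-6 Hz hand tremor; the head and chest carry small oscillations.
    Additive Gaussian marker noise (SD `cfg.noise_sd` mm) is applied to
    every channel.
    """
    from dataclasses import replace as dc_replace

    skel = cfg.skeleton
    fs = cfg.fs
    n = int(round(cfg.trial_seconds * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=4)
    sep = 1.0 / cfg.difficulty  # difficulty>1 narrows phenotype separation

    # bradykinesia: cadence slows as overall motor severity grows
    sev = labels.updrs_minus_fog / 120.0
    p = dc_replace(
        cfg.phenotype,
        step_frequency=cfg.phenotype.step_frequency * (1.0 - 0.35 * sev * sep),
    )

    common = dict(
        fog_score=labels.fog_score,
        med_state=labels.med_state,
        duration_s=cfg.trial_seconds,
        params=p,
        fs=fs,
    )
    lheel, lenv, lmask = phenotype_heel_trajectory(
        seed=int(sub_seeds[0]), side_gain=p.left_gain * sep, phase_offset=0.0, **common
    )
    rheel, renv, _ = phenotype_heel_trajectory(
        seed=int(sub_seeds[1]), side_gain=1.0 * sep, phase_offset=0.5, **common
    )

    freq = p.step_frequency * (p.on_frequency_gain if labels.med_state == "ON" else 1.0)
    activity = _smooth(0.5 * (lenv + renv), fs, 2.0)
    speed = 8.0 * activity / max(p.step_amplitude, 1.0)  # mm/sample at full stepping
    forward = np.cumsum(speed)

    arm_amp = p.arm_swing_amplitude * max(1.0 - 0.8 * sev * sep, 0.05)
    arm_phase = 2 * np.pi * freq * t
    larm = arm_amp * np.sin(arm_phase + np.pi)  # anti-phase with left leg
    rarm = arm_amp * np.sin(arm_phase)
    tremor_f = 5.0
    tremor = p.tremor_gain * sep * labels.updrs_minus_fog * np.sin(
        2 * np.pi * tremor_f * t + rng.uniform(0, 2 * np.pi)
    )

    bob = 12.0 * np.sin(2 * np.pi * 2 * freq * t) * (activity / max(p.step_amplitude, 1.0))
    sway = 15.0 * np.sin(2 * np.pi * freq * t / 2.0)

    coords = np.zeros((skel.n_markers, 3, n))
    for m, name in enumerate(skel.marker_names):
        bx, by, bz = _BASE_POS[name]
        coords[m, 0] = bx + forward
        coords[m, 1] = by + 0.3 * sway
        coords[m, 2] = bz

    def add(name, chan, sig):
        coords[skel.index(name), chan] += sig

    lsm, rsm = _smooth(lheel, fs), _smooth(rheel, fs)
    add("LHEEL", 2, lheel)
    add("RHEEL", 2, rheel)
    add("LTOE", 2, 0.8 * np.roll(lheel, -int(0.05 * fs)))
    add("RTOE", 2, 0.8 * np.roll(rheel, -int(0.05 * fs)))
    add("LANK", 2, 0.55 * lsm)
    add("RANK", 2, 0.55 * rsm)
    add("LKNE", 2, 0.25 * lsm)
    add("RKNE", 2, 0.25 * rsm)
    add("LHIP", 2, 0.08 * lsm)
    add("RHIP", 2, 0.08 * rsm)
    # stride oscillation of the feet about the pelvis in the direction of travel
    stride = 1.6 * _smooth(lenv + renv, fs, 2.0)
    add("LHEEL", 0, stride * np.sin(2 * np.pi * freq * t))
    add("LTOE", 0, stride * np.sin(2 * np.pi * freq * t))
    add("LANK", 0, 0.8 * stride * np.sin(2 * np.pi * freq * t))
    add("RHEEL", 0, stride * np.sin(2 * np.pi * freq * t + np.pi))
    add("RTOE", 0, stride * np.sin(2 * np.pi * freq * t + np.pi))
    add("RANK", 0, 0.8 * stride * np.sin(2 * np.pi * freq * t + np.pi))
    for name, sig in (("LWRI", larm), ("LHAN", larm), ("LELB", 0.5 * larm),
                      ("RWRI", rarm), ("RHAN", rarm), ("RELB", 0.5 * rarm)):
        add(name, 0, sig)
    for name in ("LWRI", "LHAN", "RWRI", "RHAN"):
        add(name, 2, tremor)
        add(name, 0, 0.6 * tremor)
    add("PELVIS", 2, bob)
    add("CHEST", 2, 1.1 * bob)
    add("HEAD", 2, 1.2 * bob)
    add("CHEST", 0, 5.0 * np.sin(2 * np.pi * freq * t))
    add("HEAD", 0, 7.0 * np.sin(2 * np.pi * freq * t))

    if cfg.noise_sd > 0:
        coords += rng.normal(0.0, cfg.noise_sd, size=coords.shape)

    return MarkerSequence(
        subject_id=subject_id,
        med_state=labels.med_state,
        trial_id=trial_id,
        coords=coords,
        labels=labels,
        fs=fs,
    )


# ---------------------------------------------------------------------- #
# cohort synthesis
# ---------------------------------------------------------------------- #
def _sample_updrs(
    group: str, state: str, fog_score: int, cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> int:
    mean, sd = cfg.updrs_params[(group, state)]
    mean = mean + cfg.updrs_fog_shift * fog_score
    a, b = (0.0 - mean) / sd, (120.0 - mean) / sd
    val = sp_stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)
    return int(round(float(val)))


def simulate_cohort(cfg: SyntheticConfig):
    """Generate a full labeled cohort.

    Sessions are drawn to match `cfg.session_table` exactly: each state's
    score counts are expanded into per-subject session assignments (OFF
    and ON sessions paired by subject index), each session yielding
    `cfg.trials_per_state` trials.  Motor severity labels are sampled
    from truncated normals with the configured group x state means/SDs
    plus a monotone shift increasing with FOG score, clipped to [0, 120].
    Deterministic given `cfg.seed`.
    """
    total = {s: sum(c) for s, c in cfg.session_table.items()}
    if sum(total.values()) <= 0:
        raise ValueError("session_table counts sum to zero")
    n_subjects = max(total.values())
    rng = np.random.default_rng(cfg.seed)

    # per-state score assignment lists, shuffled so pairing is arbitrary
    score_lists = {}
    for state, counts in cfg.session_table.items():
        scores = np.repeat(np.arange(5), counts)
        rng.shuffle(scores)
        score_lists[state] = list(scores)

    trials: list[MarkerSequence] = []
    for si in range(n_subjects):
        sid = f"S{si:03d}"
        sess_scores = {
            state: score_lists[state][si]
            for state in cfg.session_table
            if si < len(score_lists[state])
        }
        any_fog = any(s > 0 for s in sess_scores.values())
        if any_fog:
            group = "PP-FOG" if rng.random() < 0.09 else "PD-FOG"
        else:
            group = "PD-NoFOG"
        age = float(np.clip(rng.normal(68.0, 8.0), 40.0, 90.0))
        sex = "M" if rng.random() < 0.75 else "F"
        for state, fog in sess_scores.items():
            updrs = _sample_updrs(group, state, int(fog), cfg, rng)
            for ti in range(cfg.trials_per_state):
                labels = LabelSet(
                    med_state=state,
                    fog_score=int(fog),
                    updrs_minus_fog=updrs,
                    group=group,
                    age_years=age,
                    sex=sex,
                )
                seed = int(rng.integers(0, 2**31 - 1))
                trials.append(
                    simulate_trial(labels, cfg, seed, subject_id=sid,
                                   trial_id=f"T{ti}")
                )

    sidecar = [
        {
            "subject_id": tr.subject_id,
            "med_state": tr.med_state,
            "trial_id": tr.trial_id,
            "fog_score": tr.labels.fog_score,
            "updrs_minus_fog": tr.labels.updrs_minus_fog,
            "group": tr.labels.group,
            "age_years": tr.labels.age_years,
            "sex": tr.labels.sex,
        }
        for tr in trials
    ]
    return trials, sidecar
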