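"""Synthetic three-channel pressure signals standing in for the wristband.

The generator emulates the structure the pipeline assumes rather than any
particular patient: per-subject resting baselines in AD counts, four
action-specific pressure morphologies that start and end at the resting
level and complete within 30 samples (2 s at 15 Hz), additive Gaussian
sensor noise in ratio units, linear posture-switch ramps, and hysteretic
calibration sweeps.  Each action is a sum of raised-sine bumps per channel
with a distinct channel-weight signature:

1 stretching-and-making-a-fist   — two sequential bumps (stretch, fist) on
                                   all channels, palmar strongest;
2 separating-and-merging-fingers — two moderate bumps carried mainly by the
                                   radial and dorsal channels;
3 palm-flexion-and-dorsiflexion  — biphasic: palmar bump first, dorsal
                                   bump second;
4 ulnar-deviation                — one asymmetric bump dominated by the
                                   radial channel.

Every template rises by at least ~0.2 ratio units within the first ten
samples (so the pre-detection peak rule fires) and returns to baseline at
both ends (so the head-tail rule passes).  All draws are bit-reproducible
under an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationSweep, LOADING, UNLOADING
from .detect import DEFAULT_T2
from .errors import InputError
from .signals import (
    N_CHANNELS,
    WINDOW_SIZE,
    RawSample,
    RestingReference,
    compute_reference,
    flatten,
    normalize,
)

#: bump = (channel, start_sample, end_sample, amplitude in ratio units)
_TEMPLATE_BUMPS: dict[int, list[tuple[int, int, int, float]]] = {
    1: [
        (0, 2, 14, 0.30), (0, 13, 28, 0.45),
        (1, 2, 14, 0.22), (1, 13, 28, 0.32),
        (2, 2, 14, 0.12), (2, 13, 28, 0.22),
    ],
    2: [
        (0, 2, 14, 0.10), (0, 14, 28, 0.16),
        (1, 2, 14, 0.35), (1, 14, 28, 0.30),
        (2, 2, 14, 0.30), (2, 14, 28, 0.26),
    ],
    3: [
        (0, 2, 14, 0.45), (0, 16, 28, 0.15),
        (1, 2, 16, 0.10), (1, 14, 28, 0.18),
        (2, 14, 28, 0.45),
    ],
    4: [
        (0, 10, 28, 0.16),
        (1, 2, 16, 0.50), (1, 14, 28, 0.20),
        (2, 8, 28, 0.15),
    ],
}

DEFAULT_BASELINE_RANGE = (800.0, 1600.0)
DEFAULT_NOISE_SD = 0.01
DEFAULT_AMP_JITTER = 0.2
DEFAULT_TIME_JITTER = 2


@dataclass
class SubjectProfile:
    """Per-subject acquisition conditions: baselines, scale, jitters, noise."""

    baseline: np.ndarray
    amplitude_scale: float = 1.0
    amplitude_jitter: float = DEFAULT_AMP_JITTER
    timing_jitter: int = DEFAULT_TIME_JITTER
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float).ravel()
        if self.baseline.shape != (N_CHANNELS,) or np.any(self.baseline <= 0):
            raise InputError(f"baseline must be {N_CHANNELS} positive AD counts")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")


def make_subject_profile(rng: np.random.Generator, **overrides) -> SubjectProfile:
    """Draw a subject: baselines U(800, 1600) AD, amplitude scale U(0.85, 1.15)."""
    fields = {
        "baseline": rng.uniform(*DEFAULT_BASELINE_RANGE, size=N_CHANNELS),
        "amplitude_scale": float(rng.uniform(0.85, 1.15)),
    }
    fields.update(overrides)
    return SubjectProfile(**fields)


def _bump(n: int, start: float, end: float, amp: float) -> np.ndarray:
    """Raised-sine bump confined to [start, end]; exactly zero outside."""
    t = np.arange(n, dtype=float)
    y = np.zeros(n)
    m = (t >= start) & (t <= end)
    y[m] = amp * np.sin(np.pi * (t[m] - start) / (end - start)) ** 2
    return y


def action_template(label: int, time_shift: int = 0, amp_factors=None) -> np.ndarray:
    """Noise-free (3, 30) deviation-from-baseline template for one action.

    ``time_shift`` moves every bump by an integer number of samples
    (clamped so the curve still starts and ends at baseline);
    ``amp_factors`` scales each channel's amplitude.
    """
    if label not in _TEMPLATE_BUMPS:
        raise InputError(f"unknown action label {label}; valid labels are 1..4")
    amp_factors = np.ones(N_CHANNELS) if amp_factors is None else np.asarray(amp_factors, dtype=float)
    dev = np.zeros((N_CHANNELS, WINDOW_SIZE))
    for ch, start, end, amp in _TEMPLATE_BUMPS[label]:
        s = min(max(start + time_shift, 0), WINDOW_SIZE - 2)
        e = min(max(end + time_shift, s + 2), WINDOW_SIZE - 1)
        dev[ch] += _bump(WINDOW_SIZE, s, e, amp * amp_factors[ch])
    return dev


def generate_action_sample(
    label: int, subject: SubjectProfile, seed: int | np.random.Generator = 0
) -> RawSample:
    """One jittered, noisy action window in AD counts for the given subject.

    Amplitude jitter is one multiplicative factor per sample (uniform
    within +/- ``amplitude_jitter``), timing jitter an integer shift of the
    whole template, and noise i.i.d. Gaussian in ratio units; the deviation
    track is then scaled by the subject baseline back to AD counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shift = int(rng.integers(-subject.timing_jitter, subject.timing_jitter + 1)) if subject.timing_jitter else 0
    amp = subject.amplitude_scale * (1.0 + rng.uniform(-subject.amplitude_jitter, subject.amplitude_jitter))
    dev = action_template(label, time_shift=shift) * amp
    dev += rng.normal(0.0, subject.noise_sd, size=dev.shape)
    head_tail = np.abs(dev[:, [0, -1]])
    if head_tail.min(axis=0).max() >= DEFAULT_T2:
        warnings.warn(
            "noise pushed the sample's head/tail beyond the head-tail threshold; "
            "the pre-detection gate may reject it",
            stacklevel=2,
        )
    return RawSample(ch=subject.baseline[:, None] * (1.0 + dev))


def generate_resting_sample(subject: SubjectProfile, rng: np.random.Generator) -> RawSample:
    noise = rng.normal(0.0, subject.noise_sd, size=(N_CHANNELS, WINDOW_SIZE))
    return RawSample(ch=subject.baseline[:, None] * (1.0 + noise), role="resting")


@dataclass
class SyntheticDataset:
    """Labeled action windows plus the per-(subject, round) references."""

    raw: np.ndarray            # (n, 3, 30) AD counts
    features: np.ndarray       # (n, 90) normalized, flattened
    labels: np.ndarray         # (n,) 1..4
    subjects: np.ndarray       # (n,) subject index
    rounds: np.ndarray         # (n,) round index
    references: dict[tuple[int, int], RestingReference]
    profiles: dict[int, SubjectProfile] = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.labels.size)


def generate_dataset(
    n_subjects: int = 5,
    reps_per_action: int = 50,
    seed: int = 0,
    n_rounds: int = 1,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> SyntheticDataset:
    """Full labeled acquisition: per subject, a resting sample (from which the
    session reference is computed) then ``reps_per_action`` windows per action."""
    if n_subjects < 1 or reps_per_action < 1 or n_rounds < 1:
        raise InputError("counts must be positive")
    rng = np.random.default_rng(seed)
    raws, feats, labels, subjects, rounds = [], [], [], [], []
    references: dict[tuple[int, int], RestingReference] = {}
    profiles: dict[int, SubjectProfile] = {}
    for s in range(n_subjects):
        profile = make_subject_profile(rng, noise_sd=noise_sd)
        profiles[s] = profile
        for r in range(n_rounds):
            ref = compute_reference(generate_resting_sample(profile, rng))
            references[(s, r)] = ref
            for label in (1, 2, 3, 4):
                for _ in range(reps_per_action):
                    sample = generate_action_sample(label, profile, rng)
                    raws.append(sample.ch)
                    feats.append(flatten(normalize(sample, ref)))
                    labels.append(label)
                    subjects.append(s)
                    rounds.append(r)
    return SyntheticDataset(
        raw=np.stack(raws),
        features=np.stack(feats),
        labels=np.asarray(labels, dtype=int),
        subjects=np.asarray(subjects, dtype=int),
        rounds=np.asarray(rounds, dtype=int),
        references=references,
        profiles=profiles,
    )


# ---------------------------------------------------------------------------
# continuous sessions
# ---------------------------------------------------------------------------

def generate_session(
    subject: SubjectProfile,
    schedule: list,
    seed: int = 0,
    switch_duration: int = 20,
) -> tuple[np.ndarray, list[dict]]:
    """Concatenated 15 Hz AD stream plus the ground-truth event list.

    ``schedule`` entries: ``("rest", n_samples)``, ``("action", label)`` or
    ``("switch", new_offset)`` — a linear ramp of the resting posture level
    to ``new_offset`` (ratio units, applied to all channels) over
    ``switch_duration`` samples.  Actions superimpose their template on the
    current posture level.  Ground truth records each action's onset sample
    (the first sample of its 30-sample segment) and label.
    """
    if not schedule:
        raise InputError("schedule must be non-empty")
    rng = np.random.default_rng(seed)
    segments: list[np.ndarray] = []
    truth: list[dict] = []
    cursor = 0
    level = 0.0
    for entry in schedule:
        kind = entry[0]
        if kind == "rest":
            n = int(entry[1])
            seg = np.full((N_CHANNELS, n), level)
        elif kind == "action":
            label = int(entry[1])
            shift = int(rng.integers(-subject.timing_jitter, subject.timing_jitter + 1)) if subject.timing_jitter else 0
            amp = subject.amplitude_scale * (1.0 + rng.uniform(-subject.amplitude_jitter, subject.amplitude_jitter))
            seg = action_template(label, time_shift=shift) * amp + level
            truth.append({"onset": cursor, "label": label})
        elif kind == "switch":
            target = float(entry[1])
            seg = np.tile(np.linspace(level, target, switch_duration), (N_CHANNELS, 1))
            level = target
        else:
            raise InputError(f"unknown schedule entry kind {kind!r}")
        segments.append(seg)
        cursor += seg.shape[1]
    dev = np.concatenate(segments, axis=1)
    dev = dev + rng.normal(0.0, subject.noise_sd, size=dev.shape)
    stream = (subject.baseline[:, None] * (1.0 + dev)).T  # (n_samples, 3)
    return stream, truth


def rest_action_schedule(labels, rest_len: int = 45, lead_in: int = 45) -> list:
    """Convenience schedule: lead-in rest, then each action separated by rest."""
    sched: list = [("rest", lead_in)]
    for lab in labels:
        sched.append(("action", int(lab)))
        sched.append(("rest", rest_len))
    return sched


# ---------------------------------------------------------------------------
# calibration sweeps
# ---------------------------------------------------------------------------

def generate_calibration_sweep(
    true_up_curve,
    true_down_curve,
    n_points: int = 300,
    ad_range: tuple[float, float] = (200.0, 3800.0),
    noise_gf: float = 0.0,
    seed: int = 0,
) -> tuple[CalibrationSweep, CalibrationSweep]:
    """Loading/unloading sweep pair sampled from two generating force(AD) curves."""
    rng = np.random.default_rng(seed)
    ad_up = np.linspace(ad_range[0], ad_range[1], n_points)
    ad_down = ad_up[::-1].copy()
    f_up = np.clip(np.asarray(true_up_curve(ad_up), dtype=float) + rng.normal(0, noise_gf, n_points), 0, None)
    f_down = np.clip(np.asarray(true_down_curve(ad_down), dtype=float) + rng.normal(0, noise_gf, n_points), 0, None)
    return (
        CalibrationSweep(ad=ad_up, force=f_up, direction=LOADING),
        CalibrationSweep(ad=ad_down, force=f_down, direction=UNLOADING),
    )
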