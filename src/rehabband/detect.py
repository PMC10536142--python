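"""Two-rule pre-detection gate for the sliding action window.

The detector slides a 30-sample window (step 1) over the normalized
three-channel stream and forwards a window to the classifier only when it
plausibly holds one *complete* action:

rule 1 (peak): the largest per-channel range (max - min) over the oldest
    ``prefix_len`` samples exceeds ``t1`` — the action's onset has travelled
    far enough into the window that the whole action is inside;
rule 2 (head-tail): the smallest per-channel |first - last| distance is
    below ``t2`` — the window starts and ends near the same posture, which
    rejects the monotone ramps produced by switching initial gestures.

Both rules operate on normalized ratios, so the thresholds are
dimensionless and subject independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .signals import N_CHANNELS

#: Default thresholds in ratio units.  With the default generator noise
#: (sigma = 0.01) the quiescent per-channel prefix range stays well below
#: 8 sigma, while every action template rises by >= 0.2 within the prefix,
#: so t1 = 0.08 separates the two regimes with about a 3x margin on each
#: side.  t2 = 0.03 (3 sigma on the head-tail difference of a single
#: channel) keeps complete actions while rejecting posture-switch ramps.
DEFAULT_T1 = 0.08
DEFAULT_T2 = 0.03


@dataclass
class DetectionConfig:
    """Gate thresholds and window geometry (all sizes in samples at 15 Hz)."""

    t1: float = DEFAULT_T1
    t2: float = DEFAULT_T2
    window_size: int = 30
    step: int = 1
    prefix_len: int = 10
    refractory: int = 30
    classify_delay: int = 3

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise InputError("thresholds t1 and t2 must be positive")
        if self.prefix_len > self.window_size:
            raise InputError("prefix_len cannot exceed window_size")
        if self.window_size < 1 or self.step < 1 or self.refractory < 0 or self.classify_delay < 0:
            raise InputError("window_size/step must be >= 1; refractory and classify_delay >= 0")

    def to_dict(self) -> dict:
        return {
            "t1": self.t1,
            "t2": self.t2,
            "window_size": self.window_size,
            "step": self.step,
            "prefix_len": self.prefix_len,
            "refractory": self.refractory,
            "classify_delay": self.classify_delay,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionConfig":
        return cls(**d)


def _check_window(w: np.ndarray, window_size: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (N_CHANNELS, window_size):
        raise InputError(f"window must have shape ({N_CHANNELS}, {window_size}), got {w.shape}")
    return w


def peak_rule(window: np.ndarray, t1: float = DEFAULT_T1, prefix_len: int = 10) -> bool:
    """True when the max per-channel range over the oldest ``prefix_len`` samples exceeds t1."""
    w = np.asarray(window, dtype=float)
    prefix = w[:, :prefix_len]
    ranges = prefix.max(axis=1) - prefix.min(axis=1)
    return bool(ranges.max() > t1)


def headtail_rule(window: np.ndarray, t2: float = DEFAULT_T2) -> bool:
    """True when the min per-channel |head - tail| distance is below t2."""
    w = np.asarray(window, dtype=float)
    dist = np.abs(w[:, 0] - w[:, -1])
    return bool(dist.min() < t2)


def is_action(window: np.ndarray, cfg: DetectionConfig | None = None) -> bool:
    """Both gate rules together: admit the window only as a complete action."""
    cfg = cfg or DetectionConfig()
    w = _check_window(window, cfg.window_size)
    return peak_rule(w, cfg.t1, cfg.prefix_len) and headtail_rule(w, cfg.t2)


def rule_outcomes(window: np.ndarray, cfg: DetectionConfig | None = None) -> dict:
    """Diagnostic per-window record of both rule outcomes (for verbose streaming logs)."""
    cfg = cfg or DetectionConfig()
    w = _check_window(window, cfg.window_size)
    r1 = peak_rule(w, cfg.t1, cfg.prefix_len)
    r2 = headtail_rule(w, cfg.t2)
    return {"rule1": r1, "rule2": r2, "decision": r1 and r2}
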