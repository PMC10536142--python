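"""Resting-reference normalization and flattening of three-channel windows.

Every action sample is a 3x30 matrix of AD counts ``ch_i(j)`` (channels:
palmar, radial, dorsal; 30 samples at 15 Hz, i.e. 2 s).  A session binds a
per-channel resting reference ``Ref_i`` — the mean of a 30-sample relaxed
recording — and all subsequent windows are expressed as dimensionless
ratios ``u_i(j) = ch_i(j) / Ref_i``, which absorbs the band-tightness
variation between wearings.  The classifier consumes the window flattened
channel-interleaved into a 90-vector ``x(k) = u_a(b)`` with
``a = ((k-1) mod 3) + 1`` and ``b = ceil(k/3)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError

N_CHANNELS = 3
WINDOW_SIZE = 30
FEATURE_DIM = N_CHANNELS * WINDOW_SIZE
CHANNEL_NAMES = ("palmar", "radial", "dorsal")


def _as_window(values, name: str, n_samples: int = WINDOW_SIZE) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_CHANNELS, n_samples):
        raise InputError(f"{name} must have shape ({N_CHANNELS}, {n_samples}), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


@dataclass
class RawSample:
    """One 3x30 window of AD counts; ``role`` tags action vs resting recordings."""

    ch: np.ndarray
    role: str = "action"

    def __post_init__(self) -> None:
        self.ch = _as_window(self.ch, "RawSample.ch")


@dataclass
class RestingReference:
    """Per-channel baseline AD counts ``Ref_i`` from a resting recording."""

    ref: np.ndarray

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=float).ravel()
        if self.ref.shape != (N_CHANNELS,):
            raise InputError(f"reference must have {N_CHANNELS} entries")
        if np.any(self.ref <= 0) or not np.all(np.isfinite(self.ref)):
            raise DegenerateInputError("reference values must be positive and finite")


@dataclass
class NormalizedSample:
    """A 3x30 window of dimensionless ratios ``u_i(j)``."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = _as_window(self.u, "NormalizedSample.u")


def compute_reference(resting: RawSample) -> RestingReference:
    """``Ref_i`` = arithmetic mean of channel i over the 30 resting samples."""
    means = resting.ch.mean(axis=1)
    if np.any(means <= 0):
        raise DegenerateInputError("a resting channel mean is non-positive; cannot form a reference")
    return RestingReference(ref=means)


def normalize(raw: RawSample, ref: RestingReference) -> NormalizedSample:
    """Elementwise ratio ``u_i(j) = ch_i(j) / Ref_i``."""
    return NormalizedSample(u=raw.ch / ref.ref[:, None])


def flatten(u: NormalizedSample | np.ndarray) -> np.ndarray:
    """Channel-interleaved, time-major flattening to the 90-vector ``x``.

    ``x = [u_1(1), u_2(1), u_3(1), u_1(2), ..., u_3(30)]`` — column-major
    traversal of the 3x30 matrix.
    """
    mat = u.u if isinstance(u, NormalizedSample) else _as_window(u, "window")
    return mat.ravel(order="F").copy()


def unflatten(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten`: 90-vector back to the 3x30 matrix."""
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size != FEATURE_DIM:
        raise InputError(f"feature vector must have length {FEATURE_DIM}, got {arr.size}")
    return arr.reshape((N_CHANNELS, WINDOW_SIZE), order="F").copy()


# ---------------------------------------------------------------------------
# CSV dataset layout: one row per sample,
#   subject, round, label, ch1_1..ch1_30, ch2_1..ch2_30, ch3_1..ch3_30
# plus a companion reference table: subject, round, ref1, ref2, ref3.
# ---------------------------------------------------------------------------

def _sample_columns() -> list[str]:
    return [f"ch{i + 1}_{j + 1}" for i in range(N_CHANNELS) for j in range(WINDOW_SIZE)]


def samples_to_frame(raw: np.ndarray, labels, subjects, rounds) -> pd.DataFrame:
    """Pack an (n, 3, 30) array of raw windows into the flat CSV layout."""
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3 or raw.shape[1:] != (N_CHANNELS, WINDOW_SIZE):
        raise InputError(f"raw must have shape (n, {N_CHANNELS}, {WINDOW_SIZE})")
    n = raw.shape[0]
    df = pd.DataFrame(
        {"subject": np.asarray(subjects), "round": np.asarray(rounds), "label": np.asarray(labels)}
    )
    flat = raw.reshape(n, FEATURE_DIM)  # row-major: ch1 block then ch2 then ch3
    for k, col in enumerate(_sample_columns()):
        df[col] = flat[:, k]
    return df


def frame_to_samples(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unpack the flat CSV layout into (raw (n,3,30), labels, subjects, rounds)."""
    cols = _sample_columns()
    missing = [c for c in ("subject", "round", "label", *cols) if c not in df.columns]
    if missing:
        raise InputError(f"dataset frame is missing columns: {missing[:5]}...")
    raw = df[cols].to_numpy(dtype=float).reshape(-1, N_CHANNELS, WINDOW_SIZE)
    return (
        raw,
        df["label"].to_numpy(dtype=int),
        df["subject"].to_numpy(),
        df["round"].to_numpy(),
    )


def references_to_frame(refs: dict[tuple, RestingReference]) -> pd.DataFrame:
    rows = [
        {"subject": subj, "round": rnd, "ref1": r.ref[0], "ref2": r.ref[1], "ref3": r.ref[2]}
        for (subj, rnd), r in refs.items()
    ]
    return pd.DataFrame(rows)


def frame_to_references(df: pd.DataFrame) -> dict[tuple, RestingReference]:
    refs = {}
    for _, row in df.iterrows():
        key = (row["subject"], row["round"])
        refs[key] = RestingReference(ref=np.array([row["ref1"], row["ref2"], row["ref3"]]))
    return refs
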