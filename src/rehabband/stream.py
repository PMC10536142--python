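"""Streaming sliding-window detection and pipeline-bundle persistence.

Mirrors the deployed firmware loop: initialize the resting reference from
the first 30 quiet samples, then slide a 30-sample normalized FIFO window
over the stream with step 1, gate each full window with the two-rule
pre-detector and classify accepted windows with the autoencoder +
pairwise-SVM ensemble.  After an accepted detection, further detections
are suppressed for ``refractory`` samples so one physical action yields
one event.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autoencoder import AEConfig, AutoencoderModel, train_autoencoder
from .calibration import CalibrationCurve
from .detect import DetectionConfig, is_action
from .ensemble import SVMEnsemble, train_pairwise, vote
from .errors import BundleLoadError, InputError, StateError
from .signals import N_CHANNELS, RestingReference, flatten

logger = logging.getLogger(__name__)

BUNDLE_FORMAT_VERSION = 1


@dataclass
class DetectionEvent:
    """One accepted window: index of its newest sample, label, vote tallies."""

    sample_index: int
    label: int
    tallies: list[int]
    pressures_gf: list[float] | None = None

    def to_dict(self) -> dict:
        d = {"sample_index": self.sample_index, "label": self.label, "tallies": self.tallies}
        if self.pressures_gf is not None:
            d["pressures_gf"] = self.pressures_gf
        return d


@dataclass
class PipelineBundle:
    """Everything the detector needs, serializable to one JSON file."""

    autoencoder: AutoencoderModel
    ensemble: SVMEnsemble
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    reference: RestingReference | None = None
    calibration: CalibrationCurve | None = None
    seed: int | None = None
    version: int = BUNDLE_FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.autoencoder.config.code_dim != self.ensemble.code_dim:
            raise BundleLoadError(
                f"autoencoder code_dim {self.autoencoder.config.code_dim} does not match "
                f"ensemble dimension {self.ensemble.code_dim}"
            )


def train_pipeline(
    features: np.ndarray,
    labels: np.ndarray,
    ae_config: AEConfig | None = None,
    detection: DetectionConfig | None = None,
    seed: int = 0,
) -> PipelineBundle:
    """Train autoencoder then SVM ensemble on normalized 90-d feature vectors."""
    cfg = ae_config or AEConfig(seed=seed)
    ae = train_autoencoder(features, cfg)
    codes = ae.encode(features)
    ens = train_pairwise(codes, labels)
    return PipelineBundle(
        autoencoder=ae, ensemble=ens, detection=detection or DetectionConfig(), seed=seed
    )


def initialize_reference(stream: np.ndarray, n_samples: int = 30) -> RestingReference:
    """Per-channel mean of the first ``n_samples`` stream triplets."""
    arr = np.asarray(stream, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != N_CHANNELS:
        raise InputError(f"stream must be (n, {N_CHANNELS})")
    if arr.shape[0] < n_samples:
        raise InputError(f"stream too short for reference: need {n_samples}, got {arr.shape[0]}")
    return RestingReference(ref=arr[:n_samples].mean(axis=0))


def run_detector(
    bundle: PipelineBundle,
    stream: np.ndarray,
    init_samples: int = 30,
    emit_pressures: bool = False,
) -> list[DetectionEvent]:
    """Single-pass streaming detection over an (n, 3) AD stream.

    When the bundle carries no reference, the first ``init_samples``
    samples are consumed to compute one (they must be quiet); the sliding
    window then starts filling with the samples that follow.  Event sample
    indices are absolute positions in the input stream.

    Because the head-tail rule opens the gate as soon as the last channel's
    tail settles, the first accepted window systematically leads the
    best-aligned one by a few samples.  After the gate opens the detector
    therefore slides ``classify_delay`` further samples before classifying
    (classifying the final window if the stream ends first), which centers
    the classified window on the action the way training windows are.
    """
    if bundle.autoencoder is None or bundle.ensemble is None:
        raise StateError("bundle is missing fitted components")
    arr = np.asarray(stream, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != N_CHANNELS:
        raise InputError(f"stream must be (n, {N_CHANNELS})")

    cfg = bundle.detection
    if bundle.reference is not None:
        ref = bundle.reference
        start = 0
    else:
        ref = initialize_reference(arr, init_samples)
        start = init_samples
        logger.info("reference initialized from first %d samples: %s", init_samples, ref.ref)

    W = cfg.window_size
    window = np.empty((N_CHANNELS, 0))
    events: list[DetectionEvent] = []
    refractory = 0
    pending: int | None = None  # countdown from gate-open to classification
    buf = arr[start:] / ref.ref  # normalized, (n, 3)

    def classify(idx: int) -> None:
        nonlocal refractory, pending
        code = bundle.autoencoder.encode(flatten(window))
        res = vote(bundle.ensemble, code)
        pressures = None
        if emit_pressures and bundle.calibration is not None:
            pressures = [float(bundle.calibration.predict(v)) for v in arr[start + idx]]
        events.append(
            DetectionEvent(
                sample_index=start + idx,
                label=res.winner,
                tallies=res.tallies.tolist(),
                pressures_gf=pressures,
            )
        )
        refractory = cfg.refractory
        pending = None

    last_idx = buf.shape[0] - 1
    for idx in range(buf.shape[0]):
        col = buf[idx][:, None]
        window = np.concatenate([window, col], axis=1)
        if window.shape[1] > W:
            window = window[:, -W:]
        if window.shape[1] < W:
            continue
        if pending is not None:
            pending -= 1
            if pending <= 0 or idx == last_idx:
                classify(idx)
            continue
        if refractory > 0:
            refractory -= 1
            continue
        if is_action(window, cfg):
            if cfg.classify_delay == 0 or idx == last_idx:
                classify(idx)
            else:
                pending = cfg.classify_delay
    return events


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_bundle(bundle: PipelineBundle, path) -> None:
    payload = {
        "format_version": bundle.version,
        "seed": bundle.seed,
        "detection": bundle.detection.to_dict(),
        "autoencoder": bundle.autoencoder.to_dict(),
        "ensemble": bundle.ensemble.to_dict(),
        "reference": None if bundle.reference is None else bundle.reference.ref.tolist(),
        "calibration": None if bundle.calibration is None else bundle.calibration.to_dict(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_bundle(path) -> PipelineBundle:
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise BundleLoadError(f"cannot read bundle {path}: {exc}") from exc
    try:
        version = payload["format_version"]
        if version != BUNDLE_FORMAT_VERSION:
            raise BundleLoadError(f"unsupported bundle format version {version}")
        bundle = PipelineBundle(
            autoencoder=AutoencoderModel.from_dict(payload["autoencoder"]),
            ensemble=SVMEnsemble.from_dict(payload["ensemble"]),
            detection=DetectionConfig.from_dict(payload["detection"]),
            reference=None
            if payload.get("reference") is None
            else RestingReference(ref=np.asarray(payload["reference"])),
            calibration=None
            if payload.get("calibration") is None
            else CalibrationCurve.from_dict(payload["calibration"]),
            seed=payload.get("seed"),
            version=version,
        )
    except BundleLoadError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise BundleLoadError(f"bundle {path} is truncated or inconsistent: {exc}") from exc
    return bundle


# ---------------------------------------------------------------------------
# stream CSV dialect: header t,ch1,ch2,ch3 with t in sample indices (15 Hz)
# ---------------------------------------------------------------------------

def write_stream_csv(path, stream: np.ndarray) -> None:
    arr = np.asarray(stream, dtype=float)
    df = pd.DataFrame({"t": np.arange(arr.shape[0]), "ch1": arr[:, 0], "ch2": arr[:, 1], "ch3": arr[:, 2]})
    df.to_csv(path, index=False)


def read_stream_csv(path, strict: bool = False) -> tuple[np.ndarray, int]:
    """Parse a stream CSV; malformed rows are skipped (or fatal in strict mode).

    Returns the (n, 3) array and the number of skipped rows.
    """
    rows: list[list[float]] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header[:4] != ["t", "ch1", "ch2", "ch3"]:
            raise InputError(f"stream CSV must start with header t,ch1,ch2,ch3, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                if len(parts) < 4:
                    raise ValueError("short row")
                rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                if strict:
                    raise InputError(f"malformed stream row at line {lineno}: {line!r}") from exc
                skipped += 1
                logger.warning("skipping malformed stream row at line %d: %r", lineno, line)
    if skipped:
        logger.warning("stream parse summary: %d malformed rows skipped", skipped)
    return np.asarray(rows, dtype=float), skipped
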