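"""Continuous-EMG conditioning and trial epoching.

Filtering (50 Hz notch + 10-1000 Hz band-pass, zero phase), rejection of
the ground-reference channel by its minimal standard deviation, cursor
based movement-onset detection (2 % of the final displacement),
anti-aliased downsampling to 50 Hz, extraction of 25-sample trial
windows spanning [-0.2, 0.3) s around onset, and relabelling of
direction classes between extrinsic (screen) and intrinsic (forearm)
coordinate frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "TrialSet",
    "clamp_band",
    "apply_filters",
    "select_ground_reference",
    "detect_onset",
    "downsample",
    "epoch",
    "relabel_frame",
]

EPOCH_WINDOW_S = (-0.2, 0.3)
TARGET_FS = 50.0
N_DIRECTIONS = 8


@dataclass(frozen=True)
class FilterSpec:
    """Notch + band-pass design used on raw EMG."""

    notch_hz: float = 50.0
    band_hz: tuple = (10.0, 1000.0)
    order: int = 4
    notch_q: float = 35.0


@dataclass
class TrialSet:
    """Epoched trials: ``data`` is trials x signals x time (25 samples
    at 50 Hz by default), with per-trial direction (1..8) and posture
    labels and a coordinate-frame tag."""

    data: np.ndarray
    direction: np.ndarray
    posture: np.ndarray
    frame: str = "extrinsic"
    fs: float = TARGET_FS
    input_type: str | None = None

    def __post_init__(self) -> None:
        if self.frame not in ("extrinsic", "intrinsic"):
            raise ValueError(f"unknown frame tag {self.frame!r}")
        if not (len(self.data) == self.direction.size == self.posture.size):
            raise ValueError("labels must match trial count")

    @property
    def n_trials(self) -> int:
        return len(self.data)


def clamp_band(band_hz: tuple, fs: float) -> tuple:
    """Clamp the upper band edge to 0.45 fs so the stated design intent
    remains valid at reduced sampling rates; reject invalid bands."""
    lo, hi = band_hz
    if hi >= 0.45 * fs:
        hi = 0.45 * fs
    if not 0 < lo < hi:
        raise ValueError(f"invalid band ({lo}, {hi}) Hz at fs={fs} Hz")
    if hi >= fs / 2:
        raise ValueError("band edge at or above Nyquist")
    return (lo, hi)


def apply_filters(emg: np.ndarray, fs: float,
                  spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase notch + Butterworth band-pass, channel-wise.

    Forward-backward application doubles the effective order and removes
    phase distortion; DC is eliminated by the band-pass high edge.
    """
    spec = FilterSpec() if spec is None else spec
    band = clamp_band(spec.band_hz, fs)
    sos = signal.butter(spec.order, band, btype="bandpass", fs=fs,
                        output="sos")
    out = signal.sosfiltfilt(sos, emg, axis=-1)
    if spec.notch_hz < fs / 2:
        b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


def select_ground_reference(emg: np.ndarray) -> tuple[int, np.ndarray]:
    """Identify and drop the ground-reference channel.

    The ground is the least-vibrating electrode, i.e. the channel with
    the minimum standard deviation (ties broken toward the lowest
    index). Returns its index and the remaining channels.
    """
    if emg.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    idx = int(np.argmin(emg.std(axis=-1)))
    kept = np.delete(emg, idx, axis=0)
    return idx, kept


def detect_onset(cursor: np.ndarray, fs_cursor: float,
                 threshold: float = 0.02) -> float:
    """Movement onset: first time the cursor's Euclidean displacement
    from its trial-start position exceeds ``threshold`` times the final
    displacement magnitude."""
    cursor = np.atleast_2d(cursor)
    disp = np.linalg.norm(cursor - cursor[:, :1], axis=0)
    final = disp[-1]
    if final <= 0:
        raise ValueError("no movement: zero final displacement")
    above = np.nonzero(disp > threshold * final)[0]
    if above.size == 0:
        raise ValueError("displacement never exceeds onset threshold")
    return float(above[0] / fs_cursor)


def downsample(x: np.ndarray, fs: float,
               target_hz: float = TARGET_FS) -> np.ndarray:
    """Anti-aliased resampling to ``target_hz`` along the last axis.

    Polyphase resampling with the rational rate ratio; non-integer
    decimation factors are handled exactly.
    """
    if target_hz >= fs:
        raise ValueError("target rate must be below the input rate")
    ratio = Fraction(target_hz / fs).limit_denominator(10000)
    return signal.resample_poly(x, ratio.numerator, ratio.denominator,
                                axis=-1)


def epoch(
    sig: np.ndarray,
    fs: float,
    onsets_s: np.ndarray,
    direction: np.ndarray,
    posture: np.ndarray,
    window_s: tuple = EPOCH_WINDOW_S,
    input_type: str | None = None,
) -> TrialSet:
    """Cut fixed-length windows around each onset.

    The default half-open [-0.2, 0.3) s window at 50 Hz yields exactly
    25 samples. Trials whose window would exceed the signal bounds are
    dropped with a logged warning.
    """
    sig = np.atleast_2d(sig)
    n_samp = sig.shape[-1]
    w0, w1 = window_s
    n_win = int(round((w1 - w0) * fs))
    data, keep = [], []
    for i, t in enumerate(np.asarray(onsets_s, dtype=float)):
        start = int(round((t + w0) * fs))
        if start < 0 or start + n_win > n_samp:
            logger.warning("trial %d dropped: window [%d, %d) out of bounds",
                           i, start, start + n_win)
            continue
        data.append(sig[:, start:start + n_win])
        keep.append(i)
    if not data:
        raise ValueError("no trial window fits inside the signal")
    keep = np.asarray(keep)
    return TrialSet(
        data=np.stack(data),
        direction=np.asarray(direction)[keep].astype(np.int64),
        posture=np.asarray(posture)[keep].astype(float),
        frame="extrinsic",
        fs=fs,
        input_type=input_type,
    )


def rotate_labels(direction: np.ndarray, posture: np.ndarray,
                  rotation_sign: int = -1) -> np.ndarray:
    """Direction labels in the intrinsic (forearm) frame.

    Elbow-90 trials' screen directions are rotated 90 degrees clockwise,
    i.e. shifted by ``rotation_sign * 2`` index steps (45 degrees each)
    modulo 8; Elbow-0 labels are unchanged. The sign is configurable
    because the screen numbering convention fixes it only up to
    reflection.
    """
    d = np.asarray(direction).astype(np.int64)
    out = d.copy()
    rot = np.asarray(posture) != 0
    out[rot] = (d[rot] - 1 + 2 * rotation_sign) % N_DIRECTIONS + 1
    return out


def relabel_frame(trialset: TrialSet, frame: str,
                  rotation_sign: int = -1) -> TrialSet:
    """Return the trial set tagged with ``frame``-coordinate labels.

    Intrinsic relabelling must start from extrinsic labels (guarded by
    the frame tag, so the rotation can never be applied twice).
    """
    if frame not in ("extrinsic", "intrinsic"):
        raise ValueError(f"unknown frame {frame!r}")
    if trialset.frame == frame:
        return trialset
    if trialset.frame != "extrinsic":
        raise ValueError("relabelling must start from extrinsic labels")
    direction = rotate_labels(trialset.direction, trialset.posture,
                              rotation_sign)
    return replace(trialset, direction=direction, frame="intrinsic")
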