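"""Synthetic multi-channel forearm EMG with planted direction-tuned sources.

Generates recordings that emulate a high-density (96-electrode) forearm
grid during centre-out index-finger movements: 8 target directions at
45 degree spacing, two elbow postures (0 and 90 degrees), repeated
trials with inter-trial rest. Muscle sources are either *superficial*
(localized electrode footprint, short spatial length constant) or
*deep* (footprint spread around the forearm cross-section, long
circumferential length constant); both are cosine-tuned to movement
direction. Noise sources (broadband artifact, 50 Hz line) and additive
sensor noise complete the mixture. All ground truth (lead field,
per-source envelopes, labels) is returned so downstream estimators can
be validated in closed loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "Montage",
    "SourceSpec",
    "SimConfig",
    "SimulatedDataset",
    "build_montage",
    "default_sources",
    "make_leadfield",
    "source_envelope",
    "simulate_trial",
    "simulate_dataset",
]

DIRECTION_ANGLES_DEG = np.arange(8) * 45.0  # direction d (1..8) -> (d-1)*45 deg


@dataclass(frozen=True)
class Montage:
    """Electrode layout on a cylindrical forearm surface.

    ``axial_mm`` runs along the forearm, ``circ_deg`` around it. The
    ground electrode sits at a distinct position on the hand dorsum and
    couples to no muscle source.
    """

    axial_mm: np.ndarray
    circ_deg: np.ndarray
    ground_index: int
    radius_mm: float = 40.0

    @property
    def n_channels(self) -> int:
        return self.axial_mm.size

    def grid_mask(self) -> np.ndarray:
        m = np.ones(self.n_channels, dtype=bool)
        m[self.ground_index] = False
        return m


@dataclass(frozen=True)
class SourceSpec:
    """One planted source: a tuned muscle or a structured noise generator.

    ``kind`` is ``superficial`` (depth ~ 0, local footprint), ``deep``
    (depth > 0, cross-sectional footprint) or ``noise`` (untuned,
    ``w == 0``). ``frame`` says whether the source's tuning follows the
    screen (extrinsic) or rotates with the elbow (intrinsic). ``carrier``
    selects the fast signal the envelope modulates: band-limited Gaussian
    noise (``emg``), a 50 Hz sinusoid (``line``) or spectrally white
    noise (``white``, used for artifact sources). Noise sources with
    ``wander_hz > 0`` get a slow random amplitude envelope spanning the
    whole recording instead of a constant level (movement-artifact
    behaviour: it does not respect trial boundaries).
    """

    kind: str
    axial_mm: float
    circ_deg: float
    depth_mm: float
    a0: float
    w: float
    pd_deg: float
    frame: str = "intrinsic"
    carrier: str = "emg"
    wander_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("superficial", "deep", "noise"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.w < 0:
            raise ValueError("tuning weight must be non-negative")
        if self.kind == "deep" and self.depth_mm <= 0:
            raise ValueError("deep sources need depth_mm > 0")
        if self.kind == "noise" and self.w != 0:
            raise ValueError("noise sources must have zero tuning weight")
        if self.frame not in ("intrinsic", "extrinsic"):
            raise ValueError(f"unknown frame {self.frame!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of one synthetic recording session.

    Defaults are the full-scale design: 2048 Hz EMG, 100 Hz cursor,
    2 s movement trials, 80 repetitions of each direction x posture
    cell. ``reduced()`` returns the desk-scale variant (1024 Hz, 10
    repetitions) used throughout the test-suite.
    """

    fs_emg: float = 2048.0
    fs_cursor: float = 100.0
    trial_duration_s: float = 2.0
    gap_s: float = 0.5
    onset_latency_s: float = 0.4
    ramp_rise_s: float = 0.15
    n_reps: int = 80
    directions_deg: tuple = tuple(DIRECTION_ANGLES_DEG)
    postures_deg: tuple = (0.0, 90.0)
    snr_db: float | None = 0.0
    baseline_snr_db: float | None = 0.0
    baseline_mod_hz: float = 1.0
    carrier_band_hz: tuple = (20.0, 450.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for level in (self.snr_db, self.baseline_snr_db):
            if level is not None and np.isneginf(level):
                raise ValueError("-inf dB is not a valid noise level")
        if self.fs_emg <= 2 * self.carrier_band_hz[0]:
            raise ValueError("fs_emg too low for the carrier band")

    @staticmethod
    def reduced(**overrides) -> "SimConfig":
        base = dict(fs_emg=1024.0, n_reps=10)
        base.update(overrides)
        return SimConfig(**base)

    def carrier_band(self) -> tuple[float, float]:
        lo, hi = self.carrier_band_hz
        return lo, min(hi, 0.45 * self.fs_emg)


@dataclass
class SimulatedDataset:
    """A continuous synthetic recording plus its generating ground truth."""

    emg: np.ndarray  # channels x samples, float32
    fs_emg: float
    cursor: np.ndarray  # 2 x cursor samples
    fs_cursor: float
    montage: Montage
    trial_start_s: np.ndarray  # per-trial movement-phase start time
    direction: np.ndarray  # per-trial direction index 1..8 (screen frame)
    posture: np.ndarray  # per-trial elbow angle, deg
    A_true: np.ndarray  # channels x sources lead field
    envelopes: np.ndarray  # sources x samples, float32
    sources: list = field(default_factory=list)
    config: SimConfig = field(default_factory=SimConfig)

    @property
    def n_trials(self) -> int:
        return self.direction.size


def build_montage(
    n_rings: int = 12,
    per_ring: int = 8,
    axial_spacing_mm: float = 20.0,
    radius_mm: float = 40.0,
    n_channels: int | None = None,
) -> Montage:
    """Lay electrodes on a regular cylindrical grid plus a hand ground.

    The default 12 x 8 grid provides 96 slots; the first ``n_channels - 1``
    are used as recording electrodes and one ground electrode on the hand
    dorsum completes the montage (96 channels total by default, matching
    a ground-referenced high-density forearm setup where only 95 channels
    carry muscle signal).
    """
    if n_rings < 1 or per_ring < 1:
        raise ValueError("n_rings and per_ring must be positive")
    if n_channels is None:
        n_channels = n_rings * per_ring
    if n_channels < 1 or n_channels > n_rings * per_ring + 1:
        raise ValueError("n_channels out of range for this grid")
    ring_idx, slot_idx = np.divmod(np.arange(n_rings * per_ring), per_ring)
    axial = ring_idx * axial_spacing_mm
    circ = slot_idx * (360.0 / per_ring)
    n_grid = n_channels - 1
    # ground on the hand dorsum: beyond the wrist end of the grid
    axial = np.append(axial[:n_grid], -3.0 * axial_spacing_mm)
    circ = np.append(circ[:n_grid], 0.0)
    return Montage(
        axial_mm=axial,
        circ_deg=circ,
        ground_index=n_grid,
        radius_mm=radius_mm,
    )


def default_sources() -> list[SourceSpec]:
    """The standard planted-source set: 4 superficial + 3 deep tuned
    muscles (all intrinsic-frame) plus a broadband artifact and 50 Hz
    line noise."""
    sup = [
        SourceSpec("superficial", 40.0, 0.0, 0.0, 0.5, 0.40, 0.0),
        SourceSpec("superficial", 90.0, 90.0, 0.0, 0.5, 0.40, 90.0),
        SourceSpec("superficial", 140.0, 180.0, 0.0, 0.5, 0.40, 180.0),
        SourceSpec("superficial", 190.0, 270.0, 0.0, 0.5, 0.40, 270.0),
    ]
    deep = [
        SourceSpec("deep", 60.0, 45.0, 15.0, 0.5, 0.40, 45.0),
        SourceSpec("deep", 120.0, 200.0, 15.0, 0.5, 0.40, 165.0),
        SourceSpec("deep", 170.0, 315.0, 15.0, 0.5, 0.40, 285.0),
    ]
    noise = [
        SourceSpec("noise", 100.0, 120.0, 20.0, 0.6, 0.0, 0.0,
                   frame="extrinsic", carrier="emg"),
        SourceSpec("noise", 110.0, 300.0, 25.0, 0.5, 0.0, 0.0,
                   frame="extrinsic", carrier="line"),
    ]
    return sup + deep + noise


def _wrap_deg(angle: np.ndarray | float) -> np.ndarray:
    """Wrap angle(s) to (-180, 180]."""
    return -(np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0)


def make_leadfield(montage: Montage, sources: list[SourceSpec]) -> np.ndarray:
    """Channels x sources mixing matrix from electrode/source geometry.

    Coupling decays exponentially with axial and circumferential surface
    distance. Superficial sources use one inter-electrode spacing as the
    length constant in both directions (local footprint); deep sources
    use roughly half the forearm circumference circumferentially, which
    spreads their footprint over the whole ring at their axial position.
    Columns are scaled to unit maximum; the ground channel couples to
    nothing.
    """
    if not sources:
        raise ValueError("empty source list")
    grid = montage.grid_mask()
    ax = montage.axial_mm
    spacing = _grid_spacing(montage)
    half_circ = np.pi * montage.radius_mm
    A = np.zeros((montage.n_channels, len(sources)))
    for k, src in enumerate(sources):
        d_ax = np.abs(ax - src.axial_mm)
        d_phi = np.abs(_wrap_deg(montage.circ_deg - src.circ_deg))
        d_circ = np.deg2rad(d_phi) * montage.radius_mm
        if src.kind == "superficial":
            lam_ax = lam_circ = 1.2 * spacing
        else:  # deep and structured-noise sources spread cross-sectionally
            lam_ax, lam_circ = 2.0 * spacing, half_circ
        col = np.exp(-d_ax / lam_ax - d_circ / lam_circ)
        col[~grid] = 0.0
        A[:, k] = col / col.max()
    return A


def _grid_spacing(montage: Montage) -> float:
    ax = np.unique(montage.axial_mm[montage.grid_mask()])
    if ax.size < 2:
        return 20.0
    return float(np.min(np.diff(np.sort(ax))))


def effective_direction_deg(direction_deg: float, posture_deg: float,
                            frame: str) -> float:
    """Direction a source sees: intrinsic-frame sources see the screen
    direction rotated by the elbow angle (clockwise for Elbow 90)."""
    if frame == "intrinsic":
        return float(np.mod(direction_deg - posture_deg, 360.0))
    return float(direction_deg)


def source_envelope(
    src: SourceSpec,
    direction_deg: float,
    posture_deg: float,
    t_s: np.ndarray,
    config: SimConfig,
) -> np.ndarray:
    """Per-sample activation envelope of one source within a trial.

    Tuned sources: ``max(0, a0 + w cos(theta_eff - pd))`` gated by a
    smooth ramp that rises after the onset latency. Noise sources are
    on at amplitude ``a0`` for the whole trial.
    """
    if src.kind == "noise":
        return np.full(t_s.shape, src.a0)
    theta = effective_direction_deg(direction_deg, posture_deg, src.frame)
    amp = max(0.0, src.a0 + src.w * np.cos(np.deg2rad(theta - src.pd_deg)))
    x = (t_s - config.onset_latency_s) / config.ramp_rise_s
    ramp = np.clip(x, 0.0, 1.0)
    ramp = ramp * ramp * (3.0 - 2.0 * ramp)  # smoothstep
    return amp * ramp


def _carrier(src: SourceSpec, n: int, fs: float, rng: np.random.Generator,
             band: tuple[float, float], t0: float = 0.0) -> np.ndarray:
    if src.carrier == "line":
        t = t0 + np.arange(n) / fs
        return np.sqrt(2.0) * np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    white = rng.standard_normal(n)
    if src.carrier == "white":
        return white
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    return x / max(x.std(), 1e-12)


def _wander_envelope(src: SourceSpec, n: int, fs: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Slow random amplitude wander for artifact sources, RMS-scaled to
    the source's ``a0`` level."""
    sos = signal.butter(2, src.wander_hz, btype="lowpass", fs=fs,
                        output="sos")
    env = np.abs(signal.sosfiltfilt(sos, rng.standard_normal(n)))
    return src.a0 * env / max(np.sqrt(np.mean(env**2)), 1e-12)


def _cursor_trial(direction_deg: float, n: int, fs: float,
                  config: SimConfig) -> np.ndarray:
    """2 x n cursor path: rest at origin, then a smooth reach of unit
    amplitude toward the target after the onset latency."""
    t = np.arange(n) / fs
    x = (t - config.onset_latency_s) / 0.8  # 0.8 s reach duration
    prog = np.clip(x, 0.0, 1.0)
    prog = prog * prog * (3.0 - 2.0 * prog)
    u = np.array([np.cos(np.deg2rad(direction_deg)),
                  np.sin(np.deg2rad(direction_deg))])
    return u[:, None] * prog[None, :]


def _sensor_noise_scale(clean: np.ndarray, snr_db: float | None) -> float:
    if snr_db is None:
        return 0.0
    p_sig = float(np.mean(clean**2))
    return float(np.sqrt(p_sig / 10.0 ** (snr_db / 10.0)))


def _add_sensor_noise(emg: np.ndarray, scale: float, montage: Montage,
                      rng: np.random.Generator) -> None:
    if scale == 0.0:
        return
    noise = rng.standard_normal(emg.shape) * scale
    noise[montage.ground_index] *= 0.1  # ground electrode is quietest
    emg += noise


def _add_baseline_noise(emg: np.ndarray, clean_power: float,
                        config: SimConfig, montage: Montage,
                        rng: np.random.Generator) -> None:
    """Per-channel baseline/movement-artifact noise: broadband carriers
    with independent slow amplitude wander (it survives the band-pass
    filter, unlike pure drift), calibrated to ``baseline_snr_db``."""
    if config.baseline_snr_db is None:
        return
    n_ch, n = emg.shape
    fs = config.fs_emg
    sos = signal.butter(2, config.baseline_mod_hz, btype="lowpass", fs=fs,
                        output="sos")
    env = signal.sosfiltfilt(sos, rng.standard_normal((n_ch, n)), axis=-1)
    env = np.abs(env)
    env /= np.sqrt(np.mean(env**2, axis=-1, keepdims=True))
    art = env * rng.standard_normal((n_ch, n))
    art /= np.sqrt(np.mean(art**2))
    scale = np.sqrt(clean_power / 10.0 ** (config.baseline_snr_db / 10.0))
    art *= scale
    art[montage.ground_index] *= 0.1
    emg += art


def simulate_trial(
    direction_deg: float,
    posture_deg: float,
    sources: list[SourceSpec],
    A_true: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    montage: Montage | None = None,
    return_truth: bool = False,
):
    """Simulate a single trial: (emg channels x samples, cursor 2 x m).

    With ``return_truth=True`` also returns the per-source signal and
    envelope arrays.
    """
    if float(direction_deg) not in [float(d) for d in config.directions_deg]:
        raise ValueError(f"direction {direction_deg} not in configured set")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = int(round(config.trial_duration_s * config.fs_emg))
    t = np.arange(n) / config.fs_emg
    band = config.carrier_band()
    envs = np.stack([
        _wander_envelope(s, n, config.fs_emg, rng)
        if (s.kind == "noise" and s.wander_hz > 0)
        else source_envelope(s, direction_deg, posture_deg, t, config)
        for s in sources
    ])
    sigs = np.stack([
        envs[k] * _carrier(src, n, config.fs_emg, rng, band)
        for k, src in enumerate(sources)
    ])
    emg = A_true @ sigs
    if montage is not None:
        clean_power = float(np.mean(emg**2))
        _add_sensor_noise(emg, _sensor_noise_scale(emg, config.snr_db),
                          montage, rng)
        _add_baseline_noise(emg, clean_power, config, montage, rng)
    n_c = int(round(config.trial_duration_s * config.fs_cursor))
    cursor = _cursor_trial(direction_deg, n_c, config.fs_cursor, config)
    if return_truth:
        return emg, cursor, sigs, envs
    return emg, cursor


def simulate_dataset(
    config: SimConfig,
    sources: list[SourceSpec] | None = None,
    montage: Montage | None = None,
) -> SimulatedDataset:
    """Generate the full session: 8 directions x 2 postures x n_reps
    movement trials separated by rest gaps, as one continuous recording.

    Trials are blocked by posture with direction order shuffled inside
    each posture block; direction numbering is identical across postures
    (screen/extrinsic labels). Sensor noise is calibrated so the realized
    mixed-signal-to-noise power ratio equals ``config.snr_db``.
    """
    rng = np.random.default_rng(config.seed)
    montage = build_montage() if montage is None else montage
    sources = default_sources() if sources is None else sources
    A = make_leadfield(montage, sources)

    # trial order: per-posture blocks, shuffled balanced directions
    dirs, posts = [], []
    for p in config.postures_deg:
        block = np.repeat(np.arange(1, 9), config.n_reps)
        rng.shuffle(block)
        dirs.append(block)
        posts.append(np.full(block.size, p))
    direction = np.concatenate(dirs)
    posture = np.concatenate(posts)
    n_trials = direction.size

    fs, fsc = config.fs_emg, config.fs_cursor
    n_trial = int(round(config.trial_duration_s * fs))
    n_gap = int(round(config.gap_s * fs))
    n_total = n_gap + n_trials * (n_trial + n_gap)
    n_src = len(sources)
    band = config.carrier_band()

    envelopes = np.zeros((n_src, n_total), dtype=np.float64)
    trial_start = np.empty(n_trials)
    t_trial = np.arange(n_trial) / fs
    for i in range(n_trials):
        s0 = n_gap + i * (n_trial + n_gap)
        trial_start[i] = s0 / fs
        ang = DIRECTION_ANGLES_DEG[direction[i] - 1]
        for k, src in enumerate(sources):
            envelopes[k, s0:s0 + n_trial] = source_envelope(
                src, ang, posture[i], t_trial, config)
    for k, src in enumerate(sources):
        if src.kind == "noise" and src.wander_hz > 0:
            envelopes[k] = _wander_envelope(src, n_total, fs, rng)

    sigs = np.empty_like(envelopes)
    for k, src in enumerate(sources):
        sigs[k] = envelopes[k] * _carrier(src, n_total, fs, rng, band)
    emg = A @ sigs
    clean_power = float(np.mean(emg**2))
    _add_sensor_noise(emg, _sensor_noise_scale(emg, config.snr_db),
                      montage, rng)
    _add_baseline_noise(emg, clean_power, config, montage, rng)

    n_total_c = int(round(n_total / fs * fsc))
    cursor = np.zeros((2, n_total_c))
    n_trial_c = int(round(config.trial_duration_s * fsc))
    for i in range(n_trials):
        c0 = int(round(trial_start[i] * fsc))
        ang = DIRECTION_ANGLES_DEG[direction[i] - 1]
        cursor[:, c0:c0 + n_trial_c] = _cursor_trial(
            ang, n_trial_c, fsc, config)

    return SimulatedDataset(
        emg=emg.astype(np.float32),
        fs_emg=fs,
        cursor=cursor.astype(np.float32),
        fs_cursor=fsc,
        montage=montage,
        trial_start_s=trial_start,
        direction=direction.astype(np.int64),
        posture=posture.astype(np.float64),
        A_true=A,
        envelopes=envelopes.astype(np.float32),
        sources=list(sources),
        config=config,
    )
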